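"""Numba kernels for the structured-coalescent simulator.

One genealogy per locus (unlinked sites).  Backward in time, lineages
coalesce within populations at rate k(k-1)/(4N) per generation, migrate at
the per-generation probabilities in ``mig`` (treated as continuous-time
rates; rates here are tiny), and pass through scheduled events: size
changes, joins (with redirection through already-merged populations) and
admixture pulses.

Branch lengths are recorded per lineage at death (a lineage's subtended
sample configuration is fixed at its creation), which yields the expected
SFS in branch mode and a one-segregating-site-per-locus sampler in mutation
mode.  A third kernel keeps child pointers to emit carrier-level genotypes.
"""

import numpy as np
from numba import njit

# ev_type codes (must match demography.EV_*)
_EV_SIZE, _EV_JOIN, _EV_PULSE = 0, 1, 2


@njit(cache=False)
def _resolve(pop, active, merged):
    """Follow merge redirections to the current representative population."""
    p = pop
    for _ in range(64):
        if active[p] or merged[p] < 0:
            return p
        p = merged[p]
    return p


@njit(cache=False)
def _simulate_records(
    init_pop, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
    axis_of_pop, strides,
    lin_pop, lin_idx, lin_desc, rec_idx, rec_len, sizes, active, merged, kpop,
):
    """Simulate one genealogy; fill (rec_idx, rec_len) lineage records.

    Returns the number of records (2n-2: every lineage except the root).
    lin_desc rows hold per-axis descendant counts; lin_idx the flattened SFS
    index.  Scratch arrays are caller-allocated and reused across loci.
    """
    n = init_pop.shape[0]
    P = sizes0.shape[0]
    d = strides.shape[0]
    for p in range(P):
        sizes[p] = sizes0[p]
        active[p] = True
        merged[p] = -1
        kpop[p] = 0
    for i in range(n):
        lin_pop[i] = init_pop[i]
        kpop[init_pop[i]] += 1
        for a in range(d):
            lin_desc[i, a] = 0
        ax = axis_of_pop[init_pop[i]]
        lin_desc[i, ax] = 1
        lin_idx[i] = strides[ax]
    # birth times tracked in rec_len temporarily (rec filled at death)
    birth = np.zeros(2 * n, dtype=np.float64)
    k = n
    nrec = 0
    t = 0.0
    ei = 0
    ne = ev_time.shape[0]
    # lineage slots 0..k-1 are live; swap-remove on merge
    while k > 1:
        # rates
        coal_tot = 0.0
        for p in range(P):
            if kpop[p] >= 2:
                coal_tot += kpop[p] * (kpop[p] - 1.0) / (4.0 * sizes[p])
        mig_tot = 0.0
        for p in range(P):
            if kpop[p] > 0:
                out = 0.0
                for q in range(P):
                    if q != p and active[q]:
                        out += mig[p, q]
                mig_tot += kpop[p] * out
        lam = coal_tot + mig_tot
        t_next = ev_time[ei] if ei < ne else 1.0e300
        if lam <= 0.0:
            w = 1.0e300
        else:
            w = np.random.exponential(1.0 / lam)
        if t + w >= t_next and ei < ne:
            # scheduled event
            t = t_next
            typ = ev_type[ei]
            a = ev_a[ei]
            if typ == _EV_SIZE:
                sizes[a] = ev_x[ei]
            elif typ == _EV_JOIN:
                if active[a]:
                    tgt = _resolve(ev_b[ei], active, merged)
                    if tgt != a:
                        active[a] = False
                        merged[a] = ev_b[ei]
                        if kpop[a] > 0:
                            for i in range(k):
                                if lin_pop[i] == a:
                                    lin_pop[i] = tgt
                            kpop[tgt] += kpop[a]
                            kpop[a] = 0
            else:  # pulse
                if active[a] and kpop[a] > 0 and ev_x[ei] > 0.0:
                    dn = _resolve(ev_b[ei], active, merged)
                    if dn != a:
                        for i in range(k):
                            if lin_pop[i] == a and np.random.random() < ev_x[ei]:
                                lin_pop[i] = dn
                                kpop[a] -= 1
                                kpop[dn] += 1
            ei += 1
            continue
        if lam <= 0.0:
            # nothing can happen and no events left: inconsistent model
            return -1
        t = t + w
        u = np.random.random() * lam
        if u < coal_tot:
            # choose population proportional to its pair rate
            acc = 0.0
            cp = -1
            for p in range(P):
                if kpop[p] >= 2:
                    acc += kpop[p] * (kpop[p] - 1.0) / (4.0 * sizes[p])
                    if u < acc:
                        cp = p
                        break
            if cp < 0:
                cp = P - 1
            # choose two distinct lineages in cp
            r1 = int(np.random.random() * kpop[cp])
            r2 = int(np.random.random() * (kpop[cp] - 1))
            if r2 >= r1:
                r2 += 1
            i1 = -1
            i2 = -1
            seen = 0
            for i in range(k):
                if lin_pop[i] == cp:
                    if seen == r1:
                        i1 = i
                    if seen == r2:
                        i2 = i
                    seen += 1
            # record both children
            rec_idx[nrec] = lin_idx[i1]
            rec_len[nrec] = t - birth[i1]
            nrec += 1
            rec_idx[nrec] = lin_idx[i2]
            rec_len[nrec] = t - birth[i2]
            nrec += 1
            # parent occupies slot i1
            idx = 0
            for a in range(d):
                lin_desc[i1, a] += lin_desc[i2, a]
                idx += lin_desc[i1, a] * strides[a]
            lin_idx[i1] = idx
            birth[i1] = t
            # swap-remove i2
            k -= 1
            kpop[cp] -= 1
            if i2 != k:
                lin_pop[i2] = lin_pop[k]
                lin_idx[i2] = lin_idx[k]
                birth[i2] = birth[k]
                for a in range(d):
                    lin_desc[i2, a] = lin_desc[k, a]
        else:
            # migration: choose lineage proportional to its out-rate
            u -= coal_tot
            acc = 0.0
            done = False
            for p in range(P):
                if kpop[p] == 0 or done:
                    continue
                out = 0.0
                for q in range(P):
                    if q != p and active[q]:
                        out += mig[p, q]
                if out <= 0.0:
                    continue
                if u < acc + kpop[p] * out:
                    # lineage in p migrates; choose destination
                    r = int((u - acc) / out)
                    if r >= kpop[p]:
                        r = kpop[p] - 1
                    il = -1
                    seen = 0
                    for i in range(k):
                        if lin_pop[i] == p:
                            if seen == r:
                                il = i
                                break
                            seen += 1
                    v = np.random.random() * out
                    acc2 = 0.0
                    dest = -1
                    for q in range(P):
                        if q != p and active[q]:
                            acc2 += mig[p, q]
                            if v < acc2:
                                dest = q
                                break
                    if dest >= 0 and il >= 0:
                        lin_pop[il] = dest
                        kpop[p] -= 1
                        kpop[dest] += 1
                    done = True
                acc += kpop[p] * out
    return nrec


@njit(cache=False)
def branch_sfs(
    n_loci, seed,
    init_pop, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
    axis_of_pop, strides, sfs_size,
):
    """Accumulated branch lengths per SFS entry over ``n_loci`` genealogies."""
    n = init_pop.shape[0]
    P = sizes0.shape[0]
    d = strides.shape[0]
    out = np.zeros(sfs_size, dtype=np.float64)
    lin_pop = np.zeros(n, dtype=np.int32)
    lin_idx = np.zeros(n, dtype=np.int64)
    lin_desc = np.zeros((n, d), dtype=np.int32)
    rec_idx = np.zeros(2 * n, dtype=np.int64)
    rec_len = np.zeros(2 * n, dtype=np.float64)
    sizes = np.zeros(P, dtype=np.float64)
    active = np.zeros(P, dtype=np.bool_)
    merged = np.zeros(P, dtype=np.int32)
    kpop = np.zeros(P, dtype=np.int32)
    for l in range(n_loci):
        np.random.seed((seed + 1000003 * l) % 2147483647)
        nrec = _simulate_records(
            init_pop, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
            axis_of_pop, strides,
            lin_pop, lin_idx, lin_desc, rec_idx, rec_len, sizes, active, merged, kpop,
        )
        for r in range(nrec):
            out[rec_idx[r]] += rec_len[r]
    return out


@njit(cache=False)
def mutation_sfs(
    n_sites, seed,
    init_pop, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
    axis_of_pop, strides, sfs_size,
):
    """Sampled SFS with exactly ``n_sites`` segregating sites.

    Mutations are dropped as a Poisson process proportional to each
    genealogy's total branch length (infinite sites, one mutation per
    site), so site configurations follow E[L_e] — genealogies with longer
    trees carry proportionally more sites.  The per-genealogy rate is
    calibrated from a pilot batch so the expected yield is ~0.25 sites per
    genealogy; simulation proceeds until the requested count is reached.
    """
    n = init_pop.shape[0]
    P = sizes0.shape[0]
    d = strides.shape[0]
    out = np.zeros(sfs_size, dtype=np.float64)
    lin_pop = np.zeros(n, dtype=np.int32)
    lin_idx = np.zeros(n, dtype=np.int64)
    lin_desc = np.zeros((n, d), dtype=np.int32)
    rec_idx = np.zeros(2 * n, dtype=np.int64)
    rec_len = np.zeros(2 * n, dtype=np.float64)
    sizes = np.zeros(P, dtype=np.float64)
    active = np.zeros(P, dtype=np.bool_)
    merged = np.zeros(P, dtype=np.int32)
    kpop = np.zeros(P, dtype=np.int32)
    # pilot: mean total branch length
    pilot = 100
    lsum = 0.0
    for l in range(pilot):
        np.random.seed((seed + 2000003 + 1000003 * l) % 2147483647)
        nrec = _simulate_records(
            init_pop, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
            axis_of_pop, strides,
            lin_pop, lin_idx, lin_desc, rec_idx, rec_len, sizes, active, merged, kpop,
        )
        for r in range(nrec):
            lsum += rec_len[r]
    mean_l = lsum / pilot
    if mean_l <= 0.0:
        return out
    rate = 0.25 / mean_l
    filled = 0
    g = 0
    max_g = 400 * n_sites + 10000
    while filled < n_sites and g < max_g:
        np.random.seed((seed + 1000003 * g) % 2147483647)
        g += 1
        nrec = _simulate_records(
            init_pop, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
            axis_of_pop, strides,
            lin_pop, lin_idx, lin_desc, rec_idx, rec_len, sizes, active, merged, kpop,
        )
        tot = 0.0
        for r in range(nrec):
            tot += rec_len[r]
        if tot <= 0.0:
            continue
        n_mut = np.random.poisson(rate * tot)
        for j in range(n_mut):
            if filled >= n_sites:
                break
            u = np.random.random() * tot
            acc = 0.0
            pick = nrec - 1
            for r in range(nrec):
                acc += rec_len[r]
                if u < acc:
                    pick = r
                    break
            out[rec_idx[pick]] += 1.0
            filled += 1
    return out


@njit(cache=False)
def _simulate_tree(
    anc_weights, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
    init_pop, lin_pop, lin_node, birth, node_len, node_c1, node_c2,
    sizes, active, merged, kpop,
):
    """Simulate one genealogy with per-copy ancestry draws; fill the node
    arrays (children, edge lengths) and return the number of nodes."""
    n = anc_weights.shape[0]
    P = sizes0.shape[0]
    ne = ev_time.shape[0]
    for p in range(P):
        sizes[p] = sizes0[p]
        active[p] = True
        merged[p] = -1
        kpop[p] = 0
    for i in range(n):
        u = np.random.random()
        acc = 0.0
        src = P - 1
        for p in range(P):
            acc += anc_weights[i, p]
            if u < acc:
                src = p
                break
        init_pop[i] = src
        lin_pop[i] = src
        lin_node[i] = i
        kpop[src] += 1
    for v in range(2 * n):
        node_c1[v] = -1
        node_c2[v] = -1
        node_len[v] = 0.0
        birth[v] = 0.0
    k = n
    nxt = n  # next internal node id
    t = 0.0
    ei = 0
    while k > 1:
        coal_tot = 0.0
        for p in range(P):
            if kpop[p] >= 2:
                coal_tot += kpop[p] * (kpop[p] - 1.0) / (4.0 * sizes[p])
        mig_tot = 0.0
        for p in range(P):
            if kpop[p] > 0:
                outr = 0.0
                for q in range(P):
                    if q != p and active[q]:
                        outr += mig[p, q]
                mig_tot += kpop[p] * outr
        lam = coal_tot + mig_tot
        t_next = ev_time[ei] if ei < ne else 1.0e300
        w = np.random.exponential(1.0 / lam) if lam > 0.0 else 1.0e300
        if t + w >= t_next and ei < ne:
            t = t_next
            typ = ev_type[ei]
            a = ev_a[ei]
            if typ == _EV_SIZE:
                sizes[a] = ev_x[ei]
            elif typ == _EV_JOIN:
                if active[a]:
                    tgt = _resolve(ev_b[ei], active, merged)
                    if tgt != a:
                        active[a] = False
                        merged[a] = ev_b[ei]
                        if kpop[a] > 0:
                            for i in range(k):
                                if lin_pop[i] == a:
                                    lin_pop[i] = tgt
                            kpop[tgt] += kpop[a]
                            kpop[a] = 0
            else:
                if active[a] and kpop[a] > 0 and ev_x[ei] > 0.0:
                    dn = _resolve(ev_b[ei], active, merged)
                    if dn != a:
                        for i in range(k):
                            if lin_pop[i] == a and np.random.random() < ev_x[ei]:
                                lin_pop[i] = dn
                                kpop[a] -= 1
                                kpop[dn] += 1
            ei += 1
            continue
        if lam <= 0.0:
            break
        t = t + w
        u = np.random.random() * lam
        if u < coal_tot:
            acc = 0.0
            cp = -1
            for p in range(P):
                if kpop[p] >= 2:
                    acc += kpop[p] * (kpop[p] - 1.0) / (4.0 * sizes[p])
                    if u < acc:
                        cp = p
                        break
            if cp < 0:
                cp = P - 1
            r1 = int(np.random.random() * kpop[cp])
            r2 = int(np.random.random() * (kpop[cp] - 1))
            if r2 >= r1:
                r2 += 1
            i1 = -1
            i2 = -1
            seen = 0
            for i in range(k):
                if lin_pop[i] == cp:
                    if seen == r1:
                        i1 = i
                    if seen == r2:
                        i2 = i
                    seen += 1
            v1 = lin_node[i1]
            v2 = lin_node[i2]
            node_len[v1] = t - birth[v1]
            node_len[v2] = t - birth[v2]
            node_c1[nxt] = v1
            node_c2[nxt] = v2
            birth[nxt] = t
            lin_node[i1] = nxt
            nxt += 1
            k -= 1
            kpop[cp] -= 1
            if i2 != k:
                lin_pop[i2] = lin_pop[k]
                lin_node[i2] = lin_node[k]
        else:
            u -= coal_tot
            acc = 0.0
            done = False
            for p in range(P):
                if kpop[p] == 0 or done:
                    continue
                outr = 0.0
                for q in range(P):
                    if q != p and active[q]:
                        outr += mig[p, q]
                if outr <= 0.0:
                    continue
                if u < acc + kpop[p] * outr:
                    r = int((u - acc) / outr)
                    if r >= kpop[p]:
                        r = kpop[p] - 1
                    il = -1
                    seen = 0
                    for i in range(k):
                        if lin_pop[i] == p:
                            if seen == r:
                                il = i
                                break
                            seen += 1
                    v = np.random.random() * outr
                    acc2 = 0.0
                    dest = -1
                    for q in range(P):
                        if q != p and active[q]:
                            acc2 += mig[p, q]
                            if v < acc2:
                                dest = q
                                break
                    if dest >= 0 and il >= 0:
                        lin_pop[il] = dest
                        kpop[p] -= 1
                        kpop[dest] += 1
                    done = True
                acc += kpop[p] * outr
    return nxt


@njit(cache=False)
def genotype_sim(
    n_sites, seed,
    anc_weights,  # (n_haploids, P) per-copy source probabilities, rows sum to 1
    sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
    missing_rate,
):
    """Carrier-level simulation: diploid dosage matrix (n_ind, n_sites).

    Haploid copies 2i and 2i+1 belong to individual i.  Each copy draws its
    source population per genealogy from ``anc_weights`` (one-hot rows for
    unadmixed individuals).  Mutations are dropped as a Poisson process
    proportional to total branch length (rate calibrated by a pilot batch,
    ~0.25 sites per genealogy) and placed branch-length-uniformly, so site
    configurations follow E[L_e]; genealogies are simulated until
    ``n_sites`` segregating sites are collected.  Missingness is i.i.d.
    per genotype.
    """
    n = anc_weights.shape[0]
    P = sizes0.shape[0]
    n_ind = n // 2
    geno = np.zeros((n_ind, n_sites), dtype=np.int8)
    init_pop = np.zeros(n, dtype=np.int32)
    lin_pop = np.zeros(n, dtype=np.int32)
    lin_node = np.zeros(n, dtype=np.int32)
    birth = np.zeros(2 * n, dtype=np.float64)
    node_len = np.zeros(2 * n, dtype=np.float64)
    node_c1 = np.full(2 * n, -1, dtype=np.int32)
    node_c2 = np.full(2 * n, -1, dtype=np.int32)
    stack = np.zeros(2 * n, dtype=np.int32)
    sizes = np.zeros(P, dtype=np.float64)
    active = np.zeros(P, dtype=np.bool_)
    merged = np.zeros(P, dtype=np.int32)
    kpop = np.zeros(P, dtype=np.int32)
    # pilot batch: mean total branch length sets the per-genealogy rate
    pilot = 100
    lsum = 0.0
    for l in range(pilot):
        np.random.seed((seed + 2000003 + 1000003 * l) % 2147483647)
        nxt = _simulate_tree(
            anc_weights, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
            init_pop, lin_pop, lin_node, birth, node_len, node_c1, node_c2,
            sizes, active, merged, kpop,
        )
        for v in range(nxt):
            lsum += node_len[v]
    mean_l = lsum / pilot
    if mean_l <= 0.0:
        return geno
    rate = 0.25 / mean_l
    filled = 0
    g = 0
    max_g = 400 * n_sites + 10000
    while filled < n_sites and g < max_g:
        np.random.seed((seed + 1000003 * g) % 2147483647)
        g += 1
        nxt = _simulate_tree(
            anc_weights, sizes0, mig, ev_time, ev_type, ev_a, ev_b, ev_x,
            init_pop, lin_pop, lin_node, birth, node_len, node_c1, node_c2,
            sizes, active, merged, kpop,
        )
        tot = 0.0
        for v in range(nxt):
            tot += node_len[v]
        if tot <= 0.0:
            continue
        n_mut = np.random.poisson(rate * tot)
        for j in range(n_mut):
            if filled >= n_sites:
                break
            u = np.random.random() * tot
            acc = 0.0
            mut = -1
            for v in range(nxt):
                acc += node_len[v]
                if u < acc:
                    mut = v
                    break
            if mut < 0:
                mut = 0
            sp = 0
            stack[sp] = mut
            sp += 1
            while sp > 0:
                sp -= 1
                v = stack[sp]
                if v < n:
                    geno[v // 2, filled] += 1
                else:
                    stack[sp] = node_c1[v]
                    sp += 1
                    stack[sp] = node_c2[v]
                    sp += 1
            if missing_rate > 0.0:
                for i in range(n_ind):
                    if np.random.random() < missing_rate:
                        geno[i, filled] = -1
            filled += 1
    return geno
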