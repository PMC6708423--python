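"""Composite-likelihood demographic inference on joint SFS.

The estimation scheme mirrors fastsimcoal-style SFS fitting: the expected
spectrum under a candidate parameter vector is obtained from the coalescent
simulator in branch mode (common random numbers — the same per-locus seed
streams at every evaluation — make the objective deterministic and smooth
in the parameters), and parameters maximize the multinomial composite
log10-likelihood over unmasked SFS entries.  Goodness of fit uses the
likelihood-ratio G-statistic CLR = CL_O − CL_E in log10 units (the
saturated minus the model-maximized composite log-likelihood); confidence
intervals come from a parametric bootstrap; model choice uses Akaike
weights computed from the composite likelihood (not a true AIC under
linked sites — reported with that caveat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .sfs import JointSFS
from .simulate import simulate_sfs

LOG10_EPS_MASS = 1e-20  # floor for zero expected cells, as a fraction of total mass


def composite_log_likelihood(obs: JointSFS, expected: JointSFS) -> float:
    """Multinomial composite log10-likelihood Σ n_e · log10 p_e.

    ``expected`` entries are renormalized over the unmasked cells shared
    with ``obs``; zero expected cells are floored at 1e-20 of the mass.
    The multinomial constant is omitted throughout (it cancels in CLR and
    model comparisons).
    """
    if obs.data.shape != expected.data.shape:
        raise ValueError("observed/expected SFS shape mismatch")
    mask = obs.mask | expected.mask
    n = np.where(mask, 0.0, obs.data)
    p = np.where(mask, 0.0, expected.data)
    tot = p.sum()
    if tot <= 0:
        raise ValueError("expected SFS has no unmasked mass")
    p = p / tot
    p = np.maximum(p, LOG10_EPS_MASS)
    return float((n * np.log10(p)).sum())


def saturated_log_likelihood(obs: JointSFS) -> float:
    """CL_O: the composite log10-likelihood with p̂ = observed proportions."""
    n = np.where(obs.mask, 0.0, obs.data)
    N = n.sum()
    if N <= 0:
        raise ValueError("empty observed spectrum")
    nz = n > 0
    return float((n[nz] * np.log10(n[nz] / N)).sum())


@dataclass
class FitResult:
    """Point estimates and composite-likelihood summaries of one fit."""

    template: str
    free_names: list
    estimates: dict
    bounds: dict
    cl_e: float                      # maximized composite log10-likelihood
    cl_o: float                      # saturated composite log10-likelihood
    clr: float                       # CL_O − CL_E (log10 units)
    n_sites: float
    seed: int
    trace: list = field(default_factory=list)
    at_bound: dict = field(default_factory=dict)
    bootstrap_ci: dict = field(default_factory=dict)
    bootstrap_flags: dict = field(default_factory=dict)
    # retained so bootstrap/GOF can resimulate under the fitted model
    builder: Callable = None
    fixed: dict = field(default_factory=dict)
    sample_config: dict = field(default_factory=dict)
    n_genealogies: int = 100_000

    def fitted_model(self):
        return self.builder(**{**self.fixed, **self.estimates})


def expected_sfs(
    builder: Callable,
    params: dict,
    sample_config: dict,
    n_genealogies: int = 100_000,
    seed: int = 0,
    fold: bool = False,
) -> JointSFS:
    """Branch-mode expected SFS under ``builder(**params)``."""
    from .sfs import fold_sfs

    model = builder(**params)
    S = simulate_sfs(model, sample_config, n_genealogies, mode="branch", seed=seed)
    return fold_sfs(S) if fold else S


def _golden_refine(f, xs, fs, lo, hi, xtol, trace):
    """Golden-section maximization seeded by the best grid point."""
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    i = int(np.argmax(fs))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, len(xs) - 1)]
    if a == b:
        return xs[i], fs[i]
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = f(c), f(d)
    trace.extend([(c, fc), (d, fd)])
    best_x, best_f = xs[i], fs[i]
    while abs(b - a) > xtol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(c)
            trace.append((c, fc))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(d)
            trace.append((d, fd))
    for x, fx in ((c, fc), (d, fd)):
        if fx > best_f:
            best_x, best_f = x, fx
    return best_x, best_f


def fit_model(
    obs: JointSFS,
    builder: Callable,
    free: dict,
    sample_config: dict,
    fixed: dict | None = None,
    n_genealogies: int = 100_000,
    seed: int = 0,
    starts: int = 20,
    grid_points: int = 13,
    xtol_log10: float = 5e-4,
    template: str = "custom",
) -> FitResult:
    """Maximize the composite likelihood over ``free`` parameters.

    ``builder(**kwargs)`` must return a :class:`DemographicModel`; ``free``
    maps parameter name → (lower, upper) bounds (positive, finite).  The
    search works in log10 parameter space.  With one free parameter a
    deterministic coarse-grid + golden-section refinement is used; with
    several, multi-start Nelder–Mead (``starts`` starts, uniform in the
    log-bounds).  Every objective evaluation re-simulates the expected SFS
    with the same genealogy seed (common random numbers), so repeated runs
    with the same seed are identical.
    """
    fixed = dict(fixed or {})
    if not free:
        raise ValueError("at least one free parameter required")
    for name, (lo, hi) in free.items():
        if not (0 < lo < hi < math.inf):
            raise ValueError(f"bounds for {name} must be finite, positive, ordered")
    names = list(free)
    lo = np.log10([free[n][0] for n in names])
    hi = np.log10([free[n][1] for n in names])
    cl_o = saturated_log_likelihood(obs)
    fold = obs.polarity == "minor"
    cache: dict = {}
    trace: list = []

    def objective(logx: np.ndarray) -> float:
        key = tuple(np.round(logx, 10))
        if key in cache:
            return cache[key]
        params = {n: 10.0 ** v for n, v in zip(names, logx)}
        try:
            exp = expected_sfs(builder, {**fixed, **params}, sample_config,
                               n_genealogies, seed, fold=fold)
            cl = composite_log_likelihood(obs, exp)
        except (ValueError, KeyError):
            cl = -math.inf
        cache[key] = cl
        return cl

    if len(names) == 1:
        xs = np.linspace(lo[0], hi[0], grid_points)
        fs = [objective(np.array([x])) for x in xs]
        trace.extend(zip(xs, fs))
        f1 = lambda x: objective(np.array([x]))
        best_x, best_f = _golden_refine(f1, xs, fs, lo[0], hi[0], xtol_log10, trace)
        best = np.array([best_x])
    else:
        rng = np.random.default_rng(seed)
        best, best_f = None, -math.inf
        for s in range(starts):
            x0 = lo + rng.random(len(names)) * (hi - lo)
            res = minimize(
                lambda x: -objective(np.clip(x, lo, hi)),
                x0,
                method="Nelder-Mead",
                options={"xatol": xtol_log10, "fatol": 1e-3, "maxfev": 200 * len(names)},
            )
            x = np.clip(res.x, lo, hi)
            fx = objective(x)
            trace.append((tuple(x), fx))
            if fx > best_f:
                best, best_f = x, fx
    if best is None or not np.isfinite(best_f):
        raise RuntimeError("optimizer failed to find a finite composite likelihood")
    estimates = {n: 10.0 ** v for n, v in zip(names, best)}
    at_bound = {
        n: bool(np.isclose(v, free[n][0], rtol=1e-3) or np.isclose(v, free[n][1], rtol=1e-3))
        for n, v in estimates.items()
    }
    return FitResult(
        template=template,
        free_names=names,
        estimates=estimates,
        bounds=dict(free),
        cl_e=best_f,
        cl_o=cl_o,
        clr=cl_o - best_f,
        n_sites=float(obs.total()),
        seed=seed,
        trace=trace,
        at_bound=at_bound,
        builder=builder,
        fixed=fixed,
        sample_config=dict(sample_config),
        n_genealogies=n_genealogies,
    )


def parametric_bootstrap(
    fit: FitResult,
    n_boot: int = 100,
    seed: int = 0,
    n_genealogies: int | None = None,
    fold: bool | None = None,
) -> dict:
    """Percentile 95% CIs from re-fitting spectra resimulated under the fit.

    Each replicate draws an observed SFS (mutation mode, same site count)
    from the fitted model and re-runs the same fit.  CIs are the 2.5/97.5
    percentiles per parameter; if more than 20% of replicate fits fail the
    CI is flagged unreliable.  The fitted point may fall outside its CI;
    this is flagged, not hidden.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n_gen = n_genealogies or fit.n_genealogies
    if fold is None:
        fold = False
    estimates = {n: [] for n in fit.free_names}
    failures = 0
    from .sfs import fold_sfs

    for b in range(n_boot):
        rep_seed = (seed + 7919 * (b + 1)) % 2147483647
        model = fit.fitted_model()
        S = simulate_sfs(model, fit.sample_config, int(fit.n_sites), mode="mutation", seed=rep_seed)
        if fold:
            S = fold_sfs(S)
        try:
            r = fit_model(
                S, fit.builder, fit.bounds, fit.sample_config, fixed=fit.fixed,
                n_genealogies=n_gen, seed=rep_seed + 1, template=fit.template,
            )
        except RuntimeError:
            failures += 1
            continue
        for n in fit.free_names:
            estimates[n].append(r.estimates[n])
    out = {}
    unreliable = failures > 0.2 * n_boot
    for n, vals in estimates.items():
        vals = np.array(vals)
        lo_ci, hi_ci = np.percentile(vals, [2.5, 97.5]) if len(vals) else (np.nan, np.nan)
        point = fit.estimates[n]
        out[n] = {
            "ci": (float(lo_ci), float(hi_ci)),
            "point_inside": bool(lo_ci <= point <= hi_ci) if len(vals) else False,
            "n_ok": len(vals),
            "unreliable": unreliable,
        }
    fit.bootstrap_ci = {n: out[n]["ci"] for n in out}
    fit.bootstrap_flags = {n: {k: v for k, v in out[n].items() if k != "ci"} for n in out}
    return out


def gof_test(obs: JointSFS, fit: FitResult, n_sim: int = 100, seed: int = 0,
             fold: bool = False) -> tuple[float, float, dict]:
    """Likelihood-ratio G-statistic goodness of fit.

    CLR = CL_O − CL_E from the fit; the null distribution of CLR is built
    by simulating ``n_sim`` datasets of the same size under the fitted
    model and computing each replicate's CLR against its own saturated
    likelihood (no re-fit; the fitted expected spectrum is the model).
    p = fraction of null CLRs ≥ the observed CLR; a nonsignificant p means
    the observed SFS is well explained.
    """
    flags = {"low_n_sim": n_sim < 20}
    exp = expected_sfs(fit.builder, {**fit.fixed, **fit.estimates}, fit.sample_config,
                       fit.n_genealogies, fit.seed, fold=fold)
    clr_obs = saturated_log_likelihood(obs) - composite_log_likelihood(obs, exp)
    null = []
    from .sfs import fold_sfs

    for r in range(n_sim):
        rep_seed = (seed + 104729 * (r + 1)) % 2147483647
        model = fit.fitted_model()
        S = simulate_sfs(model, fit.sample_config, int(fit.n_sites), mode="mutation", seed=rep_seed)
        if fold:
            S = fold_sfs(S)
        null.append(saturated_log_likelihood(S) - composite_log_likelihood(S, exp))
    null = np.array(null)
    p = float((null >= clr_obs).mean())
    return float(clr_obs), p, flags


def akaike_weights(fits: list) -> np.ndarray:
    """Akaike weights from composite likelihoods.

    AIC_i = 2k_i − 2·ln(10)·CL_E,i (composite, so interpret with care under
    linked sites); weights w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2).
    """
    if not fits:
        raise ValueError("empty fit list")
    aic = np.array([2 * len(f.free_names) - 2.0 * math.log(10.0) * f.cl_e for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def rescale(fit_or_params, generation_time_old: float, generation_time_new: float) -> dict:
    """Re-express parameter estimates under a different generation time.

    Effective sizes scale by g_old/g_new; times in years are unchanged;
    times in generations scale by g_old/g_new.  Parameter names starting
    with ``n_`` are treated as sizes, ``t_`` as times in years.
    """
    if generation_time_new <= 0 or generation_time_old <= 0:
        raise ValueError("generation times must be > 0")
    params = fit_or_params.estimates if isinstance(fit_or_params, FitResult) else dict(fit_or_params)
    r = generation_time_old / generation_time_new
    out = {}
    for k, v in params.items():
        if k.startswith("n_"):
            out[k] = v * r
        elif k.startswith("t_"):
            out[k] = {"years": v, "generations": v / generation_time_new}
        else:
            out[k] = v
    return out
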