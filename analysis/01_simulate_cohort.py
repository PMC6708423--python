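#!/usr/bin/env python
"""Generate the synthetic study cohort under the fitted three-spruce model.

Emulates the exome-capture panel: seven *P. abies* clusters (three core
domains, four admixed derived clusters), per-genotype missingness, 0-fold
site thinning, and a fraction of individuals with hidden origin records.
Writes VCF/popmap/annotation to scratch/cohort/ (large, regenerable) and a
small summary table to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from spruce_demog import spruce_model, synthetic_cohort, write_popmap, write_vcf
from spruce_demog.genotypes import write_site_annotation

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sites", type=int, default=12_000)
    ap.add_argument("--per-cluster", type=int, default=40)
    ap.add_argument("--unknown-fraction", type=float, default=0.2)
    args = ap.parse_args()

    cohort = synthetic_cohort(
        spruce_model(),
        cluster_sizes={c: args.per_cluster for c in
                       ("ALP", "CAR", "FEN", "RUS_BALTIC", "N_POLAND",
                        "CENTRAL_EUROPE", "CS_SWEDEN")},
        unknown_fraction=args.unknown_fraction,
        n_sites=args.n_sites,
        missing_rate=0.05,
        seed=args.seed,
    )

    out = ROOT / "scratch" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(cohort.matrix, out / "cohort.vcf")
    write_popmap(cohort.popmap, out / "popmap_truth.tsv")
    write_popmap(cohort.blinded_popmap(), out / "popmap_blinded.tsv")
    write_site_annotation(cohort.matrix, cohort.annotation, out / "annotation.tsv")

    t = cohort.popmap.table
    summary = (
        t.groupby("cluster")
        .agg(n=("sample", "size"), n_unknown=("known_origin", lambda s: int((~s).sum())))
        .reset_index()
    )
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    summary.to_csv(res / "cohort_summary.tsv", sep="\t", index=False)
    print(f"cohort: {cohort.matrix.n_samples} individuals x "
          f"{cohort.matrix.n_sites} SNPs (after 0-fold thinning)")
    print(f"hidden-origin individuals: {(~t['known_origin']).sum()}")
    print(f"wrote {out}/cohort.vcf and {res}/cohort_summary.tsv")


if __name__ == "__main__":
    main()
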