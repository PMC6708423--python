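"""Genotype data model and file ingestion.

The central container is :class:`GenotypeMatrix`: diploid alt-allele dosages
(0/1/2, or :data:`MISSING`) for an ordered set of samples at an ordered set of
biallelic SNPs.  Everything downstream — diversity statistics, site-frequency
spectra, PCA, f3 — operates on this matrix plus a :class:`PopulationMap`
(sample → population → cluster) and an optional :class:`SiteAnnotation`
(0-fold / 4-fold / other degeneracy classes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

try:  # cyvcf2 reads any tabixed/plain VCF 4.x
    from cyvcf2 import VCF as _CyVCF
except ImportError:  # pragma: no cover - cyvcf2 is a hard dependency
    _CyVCF = None

MISSING = np.int8(-1)
"""Sentinel dosage for a genotype with any uncalled allele (``./.`` or ``./1``)."""


@dataclass(frozen=True)
class Site:
    """One biallelic SNP record (VCF coordinates, 1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class LoadReport:
    """Bookkeeping emitted by :func:`read_vcf`.

    Counts records skipped as multiallelic, indel, or otherwise unusable.
    Per-allele read-depth filtering happens upstream of the genotype matrix
    (in the variant caller) and is deliberately not re-applied here.
    """

    n_records: int = 0
    n_loaded: int = 0
    skipped_multiallelic: int = 0
    skipped_indel: int = 0
    skipped_other: int = 0

    @property
    def skipped(self) -> int:
        return self.skipped_multiallelic + self.skipped_indel + self.skipped_other


class GenotypeMatrix:
    """Diploid alt-allele dosages for samples × biallelic SNPs.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    sites
        Ordered :class:`Site` records; ``(chrom, pos)`` must be unique.
    calls
        ``(n_samples, n_sites)`` int8 array with entries in {0, 1, 2} or
        :data:`MISSING`.
    """

    def __init__(self, samples: Sequence[str], sites: Sequence[Site], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(sites)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_samples={len(samples)}, n_sites={len(sites)})"
            )
        bad = ~np.isin(calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or MISSING(-1)")
        keys = {(s.chrom, s.pos) for s in sites}
        if len(keys) != len(sites):
            raise ValueError("duplicate (chrom, pos) among sites")
        self.samples = list(samples)
        self.sites = list(sites)
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in ids], dtype=np.intp)
        except KeyError as e:  # joined object references an absent sample
            raise KeyError(f"sample {e.args[0]!r} not present in GenotypeMatrix") from e

    def called_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_sites) mask of non-missing calls."""
        return self.calls != MISSING

    def take_sites(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(self.samples, [self.sites[i] for i in idx], self.calls[:, idx])

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix([self.samples[i] for i in idx], self.sites, self.calls[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.samples == other.samples
            and self.sites == other.sites
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples × {self.n_sites} sites)"


@dataclass
class PopulationMap:
    """sample → population → cluster assignment with a known-origin flag.

    ``clusters`` is the closed set of admissible cluster labels; rows whose
    cluster is outside it are rejected at construction.
    """

    table: pd.DataFrame  # columns: sample, population, cluster, known_origin
    clusters: tuple[str, ...] = ()

    def __post_init__(self):
        required = {"sample", "population", "cluster", "known_origin"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"popmap missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dup = self.table["sample"][self.table["sample"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample in popmap: {dup!r}")
        if not self.clusters:
            self.clusters = tuple(pd.unique(self.table["cluster"]))
        bad = set(self.table["cluster"]) - set(self.clusters)
        if bad:
            raise ValueError(f"cluster labels outside declared set: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def samples_of(self, group: str, by: str = "population") -> list[str]:
        return list(self.table.loc[self.table[by] == group, "sample"])

    @property
    def known(self) -> pd.DataFrame:
        return self.table[self.table["known_origin"]]

    @property
    def unknown(self) -> pd.DataFrame:
        return self.table[~self.table["known_origin"]]

    def validate_against(self, G: GenotypeMatrix) -> None:
        """Every mapped sample must exist in ``G`` (join invariant)."""
        absent = set(self.table["sample"]) - set(G.samples)
        if absent:
            raise KeyError(f"popmap references samples absent from matrix: {sorted(absent)[:5]}")


DEGENERACY_CLASSES = ("zero_fold", "four_fold", "other")
REGION_CLASSES = ("coding", "intron", "intergenic")


@dataclass
class SiteAnnotation:
    """Per-site degeneracy (0-fold/4-fold/other) and region class."""

    degeneracy: np.ndarray  # object/str array, values in DEGENERACY_CLASSES
    region: np.ndarray = None

    def __post_init__(self):
        self.degeneracy = np.asarray(self.degeneracy, dtype=object)
        if self.region is None:
            self.region = np.full(len(self.degeneracy), "coding", dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        if len(self.region) != len(self.degeneracy):
            raise ValueError("region/degeneracy length mismatch")
        if not set(self.degeneracy) <= set(DEGENERACY_CLASSES):
            raise ValueError("invalid degeneracy class")
        if not set(self.region) <= set(REGION_CLASSES):
            raise ValueError("invalid region class")

    def class_indices(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.degeneracy == cls)

    def __len__(self) -> int:
        return len(self.degeneracy)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset: Sequence[str] | None = None):
    """Load biallelic SNPs from a VCF 4.x file.

    Multiallelic and indel records are skipped and tallied in the returned
    :class:`LoadReport`.  Genotypes with any uncalled allele are MISSING.

    Returns
    -------
    (GenotypeMatrix, LoadReport)
    """
    if _CyVCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    try:
        vcf = _CyVCF(str(path), samples=list(sample_subset) if sample_subset else None)
    except Exception as e:
        raise IOError(f"cannot open VCF {path}: {e}") from e
    samples = list(vcf.samples)
    report = LoadReport()
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        report.n_records += 1
        if len(v.ALT) != 1:
            report.skipped_multiallelic += 1
            continue
        if not v.is_snp:
            report.skipped_indel += 1
            continue
        gts = np.array(v.genotypes, dtype=np.int16)  # (n, 3): a1, a2, phased
        a1, a2 = gts[:, 0], gts[:, 1]
        dosage = (a1 + a2).astype(np.int8)
        dosage[(a1 < 0) | (a2 < 0)] = MISSING  # half-called → MISSING
        sites.append(Site(v.CHROM, v.POS, v.REF, v.ALT[0]))
        rows.append(dosage)
    report.n_loaded = len(sites)
    if not sites:
        raise ValueError(f"no biallelic SNPs in {path}")
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, sites, calls), report


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF 4.2 for ``G`` (round-trips via read_vcf)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in G.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for j, s in enumerate(G.sites):
            gts = "\t".join(code[int(c)] for c in G.calls[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_popmap(path) -> PopulationMap:
    """Read a TSV with header ``sample  population  cluster  known_origin``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample", "population", "cluster", "known_origin"]
    if list(df.columns) != expected:
        extra = set(df.columns) - set(expected)
        raise ValueError(f"popmap columns must be {expected}; offending columns: {sorted(extra) or list(df.columns)}")
    truthy = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
    try:
        df["known_origin"] = df["known_origin"].str.lower().map(truthy)
    except AttributeError:
        pass
    if df["known_origin"].isna().any():
        raise ValueError("known_origin must be true/false")
    return PopulationMap(df)


def write_popmap(pm: PopulationMap, path) -> None:
    out = pm.table.copy()
    out["known_origin"] = np.where(out["known_origin"], "true", "false")
    out.to_csv(path, sep="\t", index=False)


def read_site_annotation(path) -> SiteAnnotation:
    """Read TSV ``chrom  pos  degeneracy  region`` (order must match the matrix)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int})
    return SiteAnnotation(df["degeneracy"].to_numpy(), df["region"].to_numpy())


def write_site_annotation(G: GenotypeMatrix, annot: SiteAnnotation, path) -> None:
    if len(annot) != G.n_sites:
        raise ValueError("annotation length != n_sites")
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in G.sites],
            "pos": [s.pos for s in G.sites],
            "degeneracy": annot.degeneracy,
            "region": annot.region,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_by_missingness(G: GenotypeMatrix, min_called_fraction: float = 0.5) -> GenotypeMatrix:
    """Keep sites where the called fraction is strictly greater than the threshold.

    The default 0.5 is the study filter: a site is kept only if more than half
    of the individuals are successfully genotyped there.  Strict inequality,
    so exactly-half is removed.  Idempotent; site order preserved.
    """
    if not 0.0 <= min_called_fraction <= 1.0:
        raise ValueError("min_called_fraction must be in [0, 1]")
    frac = G.called_mask().mean(axis=0)
    keep = np.flatnonzero(frac > min_called_fraction)
    return G.take_sites(keep)
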