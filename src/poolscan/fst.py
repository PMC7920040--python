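"""Biallelic SNP calling from two-pool counts and FST at SNP, gene and
flanking-region level.

The estimator is the classical Nei-style fixation index computed from
pool allele frequencies.  For a biallelic SNP with minor-allele
frequencies p1, p2 in the two pools:

    H_i      = 2 p_i (1 - p_i)              (within-pool heterozygosity)
    H_within = (H_1 + H_2) / 2
    p_bar    = (p_1 + p_2) / 2              (pools weighted equally)
    H_total  = 2 p_bar (1 - p_bar)
    FST      = (H_total - H_within) / H_total

Uncorrected FST lies in [0, 1].  An optional finite-sample correction
multiplies each H_i by n_i / (n_i - 1), with n_i = min(coverage_i,
2 * pool_size_i); corrected values can be negative and are not clamped,
since clamping would bias genome-wide means and permutation nulls.

Region-level FST (a gene's exons, or exons plus flanks) aggregates by
ratio of sums, sum(H_total) - sum(H_within) over sum(H_total), the
convention of pooled sliding-window estimators; a mean of per-SNP FST
values is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, SyncSite

log = logging.getLogger(__name__)

#: allele columns of a sync count field that can be SNP alleles
_BASES = np.array(["A", "T", "C", "G"])
# alphabetical preference used only to break count ties deterministically
_BASE_TIE_RANK = np.array([0, 3, 1, 2])  # A=0 < C=1 < G=2 < T=3 in sync order


@dataclass(frozen=True)
class SnpFilter:
    """Acceptance thresholds for biallelic SNP calling.

    min_minor_count is summed across pools; coverage bounds are per pool
    and apply to the two called alleles only (third-ranked allele counts
    are dropped, not redistributed).
    """

    min_minor_count: int = 2
    min_coverage: int = 10
    max_coverage: int = 500

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.max_coverage < self.min_coverage:
            raise ValueError("max_coverage must be >= min_coverage")


@dataclass(frozen=True)
class SnpRecord:
    """Biallelic reduction of one site with per-pool major/minor counts."""

    scaffold: str
    position: int
    major_allele: str
    minor_allele: str
    n1_major: int
    n1_minor: int
    n2_major: int
    n2_minor: int

    @property
    def p1(self) -> float:
        return self.n1_minor / (self.n1_major + self.n1_minor)

    @property
    def p2(self) -> float:
        return self.n2_minor / (self.n2_major + self.n2_minor)

    @property
    def snp_id(self) -> str:
        return f"{self.scaffold}:{self.position}"


@dataclass(frozen=True)
class GeneFst:
    """Gene-level FST: exonic, and exons plus 5 kb flanks combined."""

    gene_id: str
    n_snps: int
    fst_gene: float  # NaN when no exonic SNPs survive
    n_snps_flanking: int
    fst_flanking_combined: float
    flanking_snp_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# SNP calling


def _counts_arrays(sites: Sequence[SyncSite]) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.array([s.counts_pool1 for s in sites], dtype=np.int64).reshape(-1, 6)
    c2 = np.array([s.counts_pool2 for s in sites], dtype=np.int64).reshape(-1, 6)
    return c1, c2


def _rank_alleles(c1: np.ndarray, c2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into A,T,C,G) of the major and minor allele per site.

    Ranked by summed count across pools, descending; ties broken by
    alphabetical base order so calls are deterministic.
    """
    total = c1[:, :4] + c2[:, :4]
    # stable key: count dominates, alphabetical preference breaks ties
    score = total * 4 + (3 - _BASE_TIE_RANK)
    order = np.argsort(-score, axis=1, kind="stable")
    return order[:, 0], order[:, 1]


def call_snps_arrays(
    scaffolds: np.ndarray,
    positions: np.ndarray,
    c1: np.ndarray,
    c2: np.ndarray,
    filter: SnpFilter | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Biallelic SNP calling on raw count arrays (n sites x 6 columns).

    The array-level core behind :func:`call_snps`; useful when sites
    already live in columnar form (e.g. straight from the simulator).
    """
    filt = filter or SnpFilter()
    rejections = {"monomorphic": 0, "coverage_low": 0, "coverage_high": 0, "minor_count": 0}
    n_sites = len(positions)
    if n_sites == 0:
        return _empty_snp_frame(), rejections

    major, minor = _rank_alleles(c1, c2)
    rows = np.arange(n_sites)
    n1_major, n1_minor = c1[rows, major], c1[rows, minor]
    n2_major, n2_minor = c2[rows, major], c2[rows, minor]
    cov1, cov2 = n1_major + n1_minor, n2_major + n2_minor
    minor_total = n1_minor + n2_minor

    mono = minor_total == 0
    cov_low = ~mono & ((cov1 < filt.min_coverage) | (cov2 < filt.min_coverage))
    cov_high = ~mono & ~cov_low & ((cov1 > filt.max_coverage) | (cov2 > filt.max_coverage))
    too_few = ~mono & ~cov_low & ~cov_high & (minor_total < filt.min_minor_count)
    keep = ~(mono | cov_low | cov_high | too_few)

    rejections["monomorphic"] = int(mono.sum())
    rejections["coverage_low"] = int(cov_low.sum())
    rejections["coverage_high"] = int(cov_high.sum())
    rejections["minor_count"] = int(too_few.sum())

    idx = np.flatnonzero(keep)
    p1 = n1_minor[idx] / cov1[idx]
    p2 = n2_minor[idx] / cov2[idx]
    df = pd.DataFrame(
        {
            "scaffold": np.asarray(scaffolds)[idx],
            "position": np.asarray(positions, dtype=np.int64)[idx],
            "major_allele": _BASES[major[idx]],
            "minor_allele": _BASES[minor[idx]],
            "n1_major": n1_major[idx],
            "n1_minor": n1_minor[idx],
            "n2_major": n2_major[idx],
            "n2_minor": n2_minor[idx],
            "p1": p1,
            "p2": p2,
        }
    )
    log.info("called %d SNPs from %d sites (rejected %s)", len(df), n_sites, rejections)
    return df, rejections


def call_snps(
    sites: Sequence[SyncSite],
    filter: SnpFilter | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorised biallelic SNP calling over many sites.

    Returns the accepted-SNP table (one row per SNP, with pool counts
    and minor-allele frequencies) and a dict of rejection counts by
    reason.
    """
    if len(sites) == 0:
        return _empty_snp_frame(), {
            "monomorphic": 0, "coverage_low": 0, "coverage_high": 0, "minor_count": 0,
        }
    c1, c2 = _counts_arrays(sites)
    scaffolds = np.array([s.scaffold for s in sites], dtype=object)
    positions = np.array([s.position for s in sites], dtype=np.int64)
    return call_snps_arrays(scaffolds, positions, c1, c2, filter)


def _empty_snp_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": pd.Series(dtype=str),
            "position": pd.Series(dtype=np.int64),
            "major_allele": pd.Series(dtype=str),
            "minor_allele": pd.Series(dtype=str),
            "n1_major": pd.Series(dtype=np.int64),
            "n1_minor": pd.Series(dtype=np.int64),
            "n2_major": pd.Series(dtype=np.int64),
            "n2_minor": pd.Series(dtype=np.int64),
            "p1": pd.Series(dtype=float),
            "p2": pd.Series(dtype=float),
        }
    )


def call_snp(site: SyncSite, filter: SnpFilter | None = None) -> SnpRecord | None:
    """Call a single site; None when the site is rejected by the filter."""
    df, _ = call_snps([site], filter)
    if df.empty:
        return None
    r = df.iloc[0]
    return SnpRecord(
        scaffold=r["scaffold"],
        position=int(r["position"]),
        major_allele=r["major_allele"],
        minor_allele=r["minor_allele"],
        n1_major=int(r["n1_major"]),
        n1_minor=int(r["n1_minor"]),
        n2_major=int(r["n2_major"]),
        n2_minor=int(r["n2_minor"]),
    )


# ---------------------------------------------------------------------------
# FST


def heterozygosity_components(
    p1: np.ndarray | float,
    p2: np.ndarray | float,
    cov1: np.ndarray | float | None = None,
    cov2: np.ndarray | float | None = None,
    pool_sizes: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(H_total, H_within) per SNP; the building blocks of every FST here.

    When ``pool_sizes`` is given the finite-sample correction
    n_i/(n_i - 1), n_i = min(coverage_i, 2*pool_size_i), is applied to
    each within-pool term.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = 2.0 * p1 * (1.0 - p1)
    h2 = 2.0 * p2 * (1.0 - p2)
    if pool_sizes is not None:
        if cov1 is None or cov2 is None:
            raise ValueError("coverages required for the finite-sample correction")
        n1 = np.minimum(np.asarray(cov1, dtype=float), 2 * pool_sizes[0])
        n2 = np.minimum(np.asarray(cov2, dtype=float), 2 * pool_sizes[1])
        h1 = h1 * n1 / (n1 - 1.0)
        h2 = h2 * n2 / (n2 - 1.0)
    h_within = (h1 + h2) / 2.0
    p_bar = (p1 + p2) / 2.0
    h_total = 2.0 * p_bar * (1.0 - p_bar)
    return h_total, h_within


def snp_fst(
    snp: SnpRecord,
    pool_sizes: tuple[int, int] | None = None,
) -> float:
    """FST of one accepted SNP (corrected when ``pool_sizes`` is given)."""
    cov1 = snp.n1_major + snp.n1_minor
    cov2 = snp.n2_major + snp.n2_minor
    ht, hw = heterozygosity_components(snp.p1, snp.p2, cov1, cov2, pool_sizes)
    assert ht > 0, "H_total = 0 should be impossible for a filter-passing SNP"
    return float((ht - hw) / ht)


def add_fst_columns(
    snp_df: pd.DataFrame,
    pool_sizes: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Attach h_total, h_within and per-SNP fst columns to a SNP table."""
    df = snp_df.copy()
    cov1 = (df["n1_major"] + df["n1_minor"]).to_numpy(float)
    cov2 = (df["n2_major"] + df["n2_minor"]).to_numpy(float)
    ht, hw = heterozygosity_components(
        df["p1"].to_numpy(), df["p2"].to_numpy(), cov1, cov2, pool_sizes
    )
    df["h_total"] = ht
    df["h_within"] = hw
    with np.errstate(invalid="ignore", divide="ignore"):
        df["fst"] = np.where(ht > 0, (ht - hw) / np.where(ht > 0, ht, 1.0), np.nan)
    return df


def region_fst(
    h_total: Iterable[float],
    h_within: Iterable[float],
    method: str = "ratio",
) -> float:
    """Aggregate per-SNP heterozygosity components into a region FST.

    ``method='ratio'`` (default): (sum Ht - sum Hw) / sum Ht.
    ``method='mean'``: arithmetic mean of per-SNP FST values.
    Returns NaN (never 0) for an empty region.
    """
    ht = np.asarray(list(h_total), dtype=float)
    hw = np.asarray(list(h_within), dtype=float)
    if ht.size == 0:
        return float("nan")
    if method == "ratio":
        denom = ht.sum()
        return float((denom - hw.sum()) / denom)
    if method == "mean":
        return float(np.mean((ht - hw) / ht))
    raise ValueError(f"unknown region FST method {method!r}")


def region_fst_of_snps(snps: Sequence[SnpRecord], method: str = "ratio",
                       pool_sizes: tuple[int, int] | None = None) -> float:
    """Region FST straight from SnpRecords (convenience wrapper)."""
    if not snps:
        return float("nan")
    covs1 = np.array([s.n1_major + s.n1_minor for s in snps], float)
    covs2 = np.array([s.n2_major + s.n2_minor for s in snps], float)
    ht, hw = heterozygosity_components(
        np.array([s.p1 for s in snps]), np.array([s.p2 for s in snps]),
        covs1, covs2, pool_sizes,
    )
    return region_fst(ht, hw, method=method)


# ---------------------------------------------------------------------------
# gene-level aggregation


def _positions_in_intervals(pos0: np.ndarray, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Boolean mask of 0-based positions falling in any interval.

    ``pos0`` must be sorted ascending; uses searchsorted per interval.
    """
    mask = np.zeros(pos0.shape, dtype=bool)
    for s, e in intervals:
        lo = np.searchsorted(pos0, s, side="left")
        hi = np.searchsorted(pos0, e, side="left")
        mask[lo:hi] = True
    return mask


def gene_fst(
    gene: GeneModel,
    snp_df: pd.DataFrame,
    flank: int = 5000,
    scaffold_length: int | None = None,
    method: str = "ratio",
) -> GeneFst:
    """FST of one gene: exonic SNPs, and exons plus both flanks combined.

    Flank intervals are [start - flank, start) and [end, end + flank),
    clipped to the scaffold.  ``snp_df`` must carry h_total/h_within
    columns (see :func:`add_fst_columns`).
    """
    sub = snp_df[snp_df["scaffold"] == gene.scaffold].sort_values("position")
    pos0 = sub["position"].to_numpy(np.int64) - 1

    exonic = _positions_in_intervals(pos0, gene.exons)
    up = (max(0, gene.start - flank), gene.start)
    down_end = gene.end + flank
    if scaffold_length is not None:
        down_end = min(down_end, scaffold_length)
    down = (gene.end, down_end)
    flanking = exonic | _positions_in_intervals(pos0, [up, down])

    fst_g = region_fst(sub.loc[exonic, "h_total"], sub.loc[exonic, "h_within"], method)
    fst_f = region_fst(sub.loc[flanking, "h_total"], sub.loc[flanking, "h_within"], method)
    snp_ids = tuple(
        f"{gene.scaffold}:{p}" for p in sub.loc[flanking, "position"].tolist()
    )
    return GeneFst(
        gene_id=gene.gene_id,
        n_snps=int(exonic.sum()),
        fst_gene=fst_g,
        n_snps_flanking=int(flanking.sum()),
        fst_flanking_combined=fst_f,
        flanking_snp_ids=snp_ids,
    )


def assign_exonic_genes(snp_df: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Label each SNP with the gene whose exon contains it (else NA)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.scaffold, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, g.gene_id)
    labels: list[str | None] = []
    for scaf, pos in zip(snp_df["scaffold"], snp_df["position"]):
        tree = trees.get(scaf)
        hits = tree[pos - 1] if tree is not None else None
        labels.append(min(iv.data for iv in hits) if hits else None)
    out = snp_df.copy()
    out["gene_id"] = labels
    return out


class _ScaffoldIndex:
    """Sorted SNP positions with prefix sums of the FST components.

    Interval aggregates come from two searchsorted lookups, so the
    per-gene table stays fast at genome scale.  Exons and flanks of one
    gene never overlap, so their interval sums add exactly.
    """

    def __init__(self, sub: pd.DataFrame):
        sub = sub.sort_values("position", kind="stable")
        self.pos0 = sub["position"].to_numpy(np.int64) - 1
        ht = sub["h_total"].to_numpy(float)
        hw = sub["h_within"].to_numpy(float)
        self.cum_ht = np.concatenate([[0.0], np.cumsum(ht)])
        self.cum_hw = np.concatenate([[0.0], np.cumsum(hw)])
        with np.errstate(invalid="ignore", divide="ignore"):
            per_snp = np.where(ht > 0, (ht - hw) / np.where(ht > 0, ht, 1.0), 0.0)
        self.cum_fst = np.concatenate([[0.0], np.cumsum(per_snp)])

    def aggregate(self, intervals: Iterable[tuple[int, int]], method: str) -> tuple[int, float]:
        """(n_snps, region FST) over disjoint 0-based intervals."""
        n = 0
        sum_ht = sum_hw = sum_fst = 0.0
        for s, e in intervals:
            lo = int(np.searchsorted(self.pos0, s, side="left"))
            hi = int(np.searchsorted(self.pos0, e, side="left"))
            n += hi - lo
            sum_ht += self.cum_ht[hi] - self.cum_ht[lo]
            sum_hw += self.cum_hw[hi] - self.cum_hw[lo]
            sum_fst += self.cum_fst[hi] - self.cum_fst[lo]
        if n == 0:
            return 0, float("nan")
        if method == "ratio":
            return n, float((sum_ht - sum_hw) / sum_ht)
        if method == "mean":
            return n, float(sum_fst / n)
        raise ValueError(f"unknown region FST method {method!r}")


def gene_fst_table(
    genes: Sequence[GeneModel],
    snp_df: pd.DataFrame,
    flank: int = 5000,
    scaffold_lengths: Mapping[str, int] | None = None,
    method: str = "ratio",
) -> pd.DataFrame:
    """Per-gene FST table over all genes.

    Genes with zero surviving exonic SNPs get NaN fst_gene and are the
    caller's to exclude from summaries and permutation backgrounds.
    Per gene this equals :func:`gene_fst` on the same inputs.
    """
    indexes: dict[str, _ScaffoldIndex] = {
        scaf: _ScaffoldIndex(sub) for scaf, sub in snp_df.groupby("scaffold")
    }
    empty = _ScaffoldIndex(snp_df.iloc[0:0])
    rows = []
    n_no_snps = 0
    for g in genes:
        idx = indexes.get(g.scaffold, empty)
        slen = scaffold_lengths.get(g.scaffold) if scaffold_lengths else None
        n_ex, fst_g = idx.aggregate(g.exons, method)
        up = (max(0, g.start - flank), g.start)
        down_end = g.end + flank if slen is None else min(g.end + flank, slen)
        n_fl, fst_f = idx.aggregate(list(g.exons) + [up, (g.end, down_end)], method)
        if n_ex == 0:
            n_no_snps += 1
        rows.append(
            {
                "gene_id": g.gene_id,
                "scaffold": g.scaffold,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "n_snps": n_ex,
                "fst_gene": fst_g,
                "n_snps_flanking": n_fl,
                "fst_flanking_combined": fst_f,
            }
        )
    if n_no_snps:
        log.info("%d of %d genes have no surviving exonic SNPs (fst_gene undefined)", n_no_snps, len(genes))
    return pd.DataFrame(rows)


def genomewide_summary(gene_df: pd.DataFrame, snp_df: pd.DataFrame) -> pd.DataFrame:
    """Counts, means, medians and percentiles for each FST level."""
    def _stats(name: str, values: pd.Series) -> dict:
        v = values.dropna()
        if v.empty:
            return {"level": name, "n": 0, "mean": np.nan, "median": np.nan,
                    "p2.5": np.nan, "p97.5": np.nan, "sd": np.nan}
        return {
            "level": name,
            "n": int(v.size),
            "mean": float(v.mean()),
            "median": float(v.median()),
            "p2.5": float(np.percentile(v, 2.5)),
            "p97.5": float(np.percentile(v, 97.5)),
            "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
        }

    snp_vals = snp_df["fst"] if "fst" in snp_df else pd.Series(dtype=float)
    rows = [
        _stats("snp", snp_vals),
        _stats("gene", gene_df["fst_gene"] if "fst_gene" in gene_df else pd.Series(dtype=float)),
        _stats(
            "gene_flanking_combined",
            gene_df["fst_flanking_combined"] if "fst_flanking_combined" in gene_df else pd.Series(dtype=float),
        ),
    ]
    return pd.DataFrame(rows)
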