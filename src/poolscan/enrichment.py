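"""Percentile outlier selection and functional-term enrichment.

Outliers are items whose FST lies strictly above the genome-wide
empirical percentile (linear-interpolation definition); ties sitting
exactly at the threshold are excluded and counted.  Enrichment of
annotation terms among outliers uses the one-sided hypergeometric
(Fisher classic) test with Benjamini-Hochberg adjustment across the
retained terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierSelection:
    outlier_ids: frozenset[str]
    threshold: float
    percentile: float
    n_ties_at_threshold: int


def select_outliers(
    values: Mapping[str, float] | pd.Series,
    percentile: float = 97.5,
) -> OutlierSelection:
    """Items with value strictly greater than the empirical percentile.

    The threshold is the linear-interpolation percentile of the finite
    values; with 1000 distinct values and percentile 97.5 that leaves
    the top 25.  A constant vector yields zero outliers.
    """
    s = (values if isinstance(values, pd.Series) else pd.Series(dict(values))).dropna()
    if s.empty:
        raise ValueError("no finite values to select outliers from")
    arr = s.to_numpy(float)
    threshold = float(np.percentile(arr, percentile))
    outliers = frozenset(s.index[arr > threshold])
    ties = int(np.sum(arr == threshold))
    if not outliers:
        log.warning("no outliers above threshold %.6g (all values tied?)", threshold)
    if ties:
        log.info("%d items tie exactly at the %.4g%% threshold and are excluded", ties, percentile)
    return OutlierSelection(outliers, threshold, percentile, ties)


def fisher_enrichment(
    outliers: Iterable[str],
    annotation_map: AnnotationMap,
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each term among outliers.

    ``annotation_map`` must already be restricted to ``background`` with
    the minimum-term-size filter applied.  For a background of size M
    with K genes in the term and n outliers of which k are in the term,
    p = P[X >= k], X ~ Hypergeom(M, K, n).  BH adjustment runs across
    all retained terms; rows are sorted by p.
    """
    bg = frozenset(background)
    out = frozenset(outliers) & bg
    if not out:
        raise ValueError("outlier set is empty (after restriction to background)")
    M, n = len(bg), len(out)
    rows = []
    for term, genes in annotation_map.terms.items():
        K = len(genes)
        k = len(genes & out)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "term_id": term,
                "term_label": annotation_map.labels.get(term, ""),
                "n_outlier_in_term": k,
                "n_term": K,
                "n_outlier": n,
                "n_background": M,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["bh_adjusted_p"] = pd.Series(dtype=float)
        return df
    df["bh_adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)


def scan_report(
    gene_fst_df: pd.DataFrame,
    outlier_threshold: float,
    candidate_ids: Iterable[str],
    value_column: str = "fst_flanking_combined",
) -> pd.DataFrame:
    """Plot-ready genome-scan table: one row per gene, position ordered.

    Columns: running genome index, the scanned FST value, an outlier
    flag (strictly above threshold) and a candidate flag — enough to
    draw a Manhattan-style scan with the percentile line.
    """
    cand = frozenset(candidate_ids)
    df = gene_fst_df.sort_values(["scaffold", "start"], kind="stable").reset_index(drop=True)
    vals = df[value_column].to_numpy(float)
    return pd.DataFrame(
        {
            "genome_index": np.arange(len(df)),
            "gene_id": df["gene_id"],
            "scaffold": df["scaffold"],
            "start": df["start"],
            "end": df["end"],
            value_column: vals,
            "is_outlier": (vals > outlier_threshold) & np.isfinite(vals),
            "is_candidate": df["gene_id"].isin(cand).to_numpy(),
            "threshold": outlier_threshold,
        }
    )
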