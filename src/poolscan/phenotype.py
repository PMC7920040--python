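"""Insect hemocyte immune-assay indices.

Three point estimates from larval hemolymph assays:

* total hemocyte concentration (cells/µl) from a Neubauer hemocytometer
  count: (cells x 10) / (squares x dilution fraction), where the x10 is
  the 0.1 mm chamber-depth volume factor and the dilution fraction is
  hemolymph volume over total volume (1/20 for an 8 µl : 152 µl mix);
* phagocytic index: the proportion of all hemocytes on a slide that
  have engulfed labelled bacteria, plus the cell-type composition of
  the phagocytosing cells;
* specific phagocytic index: within one hemocyte type, the proportion
  of that type engaged in phagocytosis (its propensity).

Replicate slides/images for one larva are pooled by summing counts
before computing an index, giving the individual-level point estimate;
per-replicate rows are kept for mixed-model use downstream.  Records
lacking a cell type entirely are excluded from that type's analysis
(some slides simply contain no oenocytoids).  Statistical modelling is
out of scope: the module ends at tidy per-individual and per-group
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CELL_TYPES = ("granulocyte", "plasmatocyte", "oenocytoid", "other")


@dataclass(frozen=True)
class HemocytometerCount:
    """Raw chamber count: cells over ``n_squares`` at a known dilution."""

    cells_counted: int
    n_squares: int = 10
    dilution_fraction: float = 1 / 20  # hemolymph volume / total volume

    def __post_init__(self) -> None:
        if self.n_squares < 1:
            raise ValueError("n_squares must be >= 1")
        if self.cells_counted < 0:
            raise ValueError("cells_counted must be >= 0")


@dataclass(frozen=True)
class CellCountRecord:
    """One larva's differential hemocyte counts (replicates pooled or not)."""

    individual_id: str
    population: str
    sex: str
    replicate_id: str = "pooled"
    totals: Mapping[str, int] = field(default_factory=dict)
    phagocytic: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, n_phag in self.phagocytic.items():
            if n_phag > self.totals.get(t, 0):
                raise ValueError(
                    f"{self.individual_id}: phagocytic {t} count {n_phag} exceeds total"
                )


def hemocyte_concentration(count: HemocytometerCount) -> float:
    """Cells per µl of hemolymph: (cells x 10) / (squares x dilution)."""
    d = count.dilution_fraction
    if not (0 < d <= 1):
        raise ValueError(f"dilution_fraction must be in (0, 1], got {d}")
    return (count.cells_counted * 10.0) / (count.n_squares * d)


def phagocytic_index(record: CellCountRecord) -> tuple[float, dict[str, float]]:
    """Overall phagocytic index and phagocyte composition by cell type.

    Index = (sum of phagocytosing cells) / (sum of all hemocytes).
    Composition = each type's share of the phagocytosing cells (empty
    dict when no cell phagocytosed).  NaN index when the record holds
    no hemocytes at all.
    """
    total = sum(record.totals.values())
    n_phag = sum(record.phagocytic.values())
    if total == 0:
        return float("nan"), {}
    index = n_phag / total
    composition = (
        {t: record.phagocytic.get(t, 0) / n_phag for t in record.totals}
        if n_phag > 0
        else {}
    )
    return index, composition


def specific_phagocytic_index(record: CellCountRecord, cell_type: str) -> float:
    """Propensity of one cell type: phagocytic_t / total_t; NaN if absent."""
    total_t = record.totals.get(cell_type, 0)
    if total_t == 0:
        log.debug("%s: no %s cells; record excluded for this type", record.individual_id, cell_type)
        return float("nan")
    return record.phagocytic.get(cell_type, 0) / total_t


# ---------------------------------------------------------------------------
# table-level interface


_LONG_COLUMNS = {"individual_id", "population", "sex", "replicate_id", "cell_type", "total", "phagocytic"}


def read_cell_counts(path: str | Path) -> pd.DataFrame:
    """Read a cell-count CSV in long or wide layout into tidy long form.

    Long: one row per individual x replicate x cell type with ``total``
    and ``phagocytic`` columns.  Wide: one row per individual x
    replicate with ``total_<type>`` / ``phagocytic_<type>`` columns.
    """
    df = pd.read_csv(path)
    if _LONG_COLUMNS <= set(df.columns):
        return df[sorted(_LONG_COLUMNS, key=list(df.columns).index)].copy()
    id_cols = ["individual_id", "population", "sex", "replicate_id"]
    missing = [c for c in id_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing identifier columns {missing}")
    records = []
    for _, row in df.iterrows():
        for t in CELL_TYPES:
            if f"total_{t}" not in df.columns:
                continue
            records.append(
                {**{c: row[c] for c in id_cols}, "cell_type": t,
                 "total": int(row[f"total_{t}"]),
                 "phagocytic": int(row.get(f"phagocytic_{t}", 0))}
            )
    if not records:
        raise ValueError(f"{path}: no recognised cell-count columns")
    return pd.DataFrame(records)


def pool_replicates(long_df: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over replicates, one row per individual x cell type."""
    return (
        long_df.groupby(["individual_id", "population", "sex", "cell_type"], as_index=False)[
            ["total", "phagocytic"]
        ].sum()
    )


def records_from_table(long_df: pd.DataFrame) -> list[CellCountRecord]:
    """Pool replicates and build one CellCountRecord per individual."""
    pooled = pool_replicates(long_df)
    records = []
    for (ind, pop, sex), grp in pooled.groupby(["individual_id", "population", "sex"]):
        records.append(
            CellCountRecord(
                individual_id=str(ind),
                population=str(pop),
                sex=str(sex),
                totals=dict(zip(grp["cell_type"], grp["total"].astype(int))),
                phagocytic=dict(zip(grp["cell_type"], grp["phagocytic"].astype(int))),
            )
        )
    return records


def individual_indices(long_df: pd.DataFrame) -> pd.DataFrame:
    """Per-individual indices: overall, composition and per-type propensity."""
    rows = []
    for rec in records_from_table(long_df):
        index, composition = phagocytic_index(rec)
        row = {
            "individual_id": rec.individual_id,
            "population": rec.population,
            "sex": rec.sex,
            "n_hemocytes": sum(rec.totals.values()),
            "phagocytic_index": index,
        }
        for t in CELL_TYPES:
            row[f"composition_{t}"] = composition.get(t, np.nan)
            row[f"specific_index_{t}"] = specific_phagocytic_index(rec, t)
        rows.append(row)
    return pd.DataFrame(rows)


def assay_summary(long_df: pd.DataFrame) -> pd.DataFrame:
    """Group mean, SD and N of every index by population x sex.

    One row per group x index; individuals with an undefined index for
    a given cell type (no such cells on their slides) are excluded from
    that index's N.  No hypothesis tests — the table is the contract.
    """
    per_ind = individual_indices(long_df)
    index_cols = [c for c in per_ind.columns
                  if c.startswith(("phagocytic_index", "composition_", "specific_index_"))]
    rows = []
    for (pop, sex), grp in per_ind.groupby(["population", "sex"]):
        for col in index_cols:
            v = grp[col].dropna()
            rows.append(
                {
                    "population": pop,
                    "sex": sex,
                    "index": col,
                    "n": int(v.size),
                    "mean": float(v.mean()) if v.size else np.nan,
                    "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def thc_table(counts_df: pd.DataFrame) -> pd.DataFrame:
    """Attach cells/µl to a hemocytometer-count table.

    Expects columns cells_counted, n_squares, dilution_fraction plus
    any identifier columns, which pass through unchanged.
    """
    out = counts_df.copy()
    out["cells_per_ul"] = [
        hemocyte_concentration(
            HemocytometerCount(int(r.cells_counted), int(r.n_squares), float(r.dilution_fraction))
        )
        for r in counts_df.itertuples()
    ]
    return out
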