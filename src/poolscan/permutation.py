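"""Candidate-set permutation tests.

Whether a candidate set of genes (or SNPs) is more or less diverged than
the genome-wide expectation is tested by comparing its mean FST with the
means of many equally sized sets sampled uniformly, without replacement,
from the full background.  p-values follow the Monte-Carlo plus-one
convention, p = (1 + #{null at least as extreme}) / (n_perm + 1), so a
reported p is never exactly zero; ties count in both tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_CHUNK = 500  # replicates drawn per vectorised block


@dataclass(frozen=True)
class PermutationResult:
    observed_mean: float
    null_means: np.ndarray
    p_greater: float
    p_less: float
    p_two_sided: float
    n_perm: int
    set_size: int
    seed: int

    def as_row(self) -> dict:
        """Flat dict for CSV output (null distribution excluded)."""
        return {
            "observed_mean": self.observed_mean,
            "null_mean": float(self.null_means.mean()),
            "null_sd": float(self.null_means.std(ddof=1)),
            "p_greater": self.p_greater,
            "p_less": self.p_less,
            "p_two_sided": self.p_two_sided,
            "n_perm": self.n_perm,
            "set_size": self.set_size,
            "seed": self.seed,
        }


def _as_series(values: Mapping[str, float] | pd.Series) -> pd.Series:
    s = values if isinstance(values, pd.Series) else pd.Series(dict(values))
    return s.astype(float)


def mean_stat(values: Mapping[str, float] | pd.Series, ids: Iterable[str]) -> float:
    """Arithmetic mean of ``values`` over ``ids``; every id must resolve.

    Candidate items without a defined value must be dropped explicitly
    by the caller — silently ignoring them would shrink the set size the
    null is calibrated against.
    """
    s = _as_series(values)
    ids = list(ids)
    missing = [i for i in ids if i not in s.index or not np.isfinite(s[i])]
    if missing:
        raise KeyError(
            f"{len(missing)} ids missing or undefined in background "
            f"(first few: {missing[:5]})"
        )
    return float(s.loc[ids].mean())


def permute_sets(
    background_values: Mapping[str, float] | pd.Series,
    candidate_ids: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    exclude_candidates: bool = False,
) -> PermutationResult:
    """Permutation test of a candidate set's mean against random sets.

    Random sets are drawn from the full background, candidates included,
    matching a literal 'randomly sampled genome-wide' null; pass
    ``exclude_candidates=True`` for the leave-candidates-out variant.
    Identical (background, candidates, n_perm, seed) give identical
    results.
    """
    bg = _as_series(background_values).dropna()
    candidates = sorted(set(candidate_ids) & set(bg.index))
    if not candidates:
        raise ValueError("candidate set empty after intersection with background")
    observed = mean_stat(bg, candidates)

    pool = bg.drop(index=candidates) if exclude_candidates else bg
    values = pool.to_numpy(float)
    k, n = len(candidates), values.size
    if k > n:
        raise ValueError(f"set size {k} exceeds background size {n}")

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        # k smallest random keys per row = uniform draw without replacement
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n else \
            np.tile(np.arange(n), (m, 1))
        null_means[done:done + m] = values[idx].mean(axis=1)
        done += m

    b_greater = int(np.sum(null_means >= observed))
    b_less = int(np.sum(null_means <= observed))
    p_greater = (1 + b_greater) / (n_perm + 1)
    p_less = (1 + b_less) / (n_perm + 1)
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    return PermutationResult(
        observed_mean=observed,
        null_means=null_means,
        p_greater=p_greater,
        p_less=p_less,
        p_two_sided=p_two,
        n_perm=n_perm,
        set_size=k if not exclude_candidates else len(candidates),
        seed=seed,
    )


def snp_level_permutation(
    snp_fst_table: pd.DataFrame,
    candidate_snp_ids: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    exclude_candidates: bool = False,
) -> PermutationResult:
    """As :func:`permute_sets` with SNPs (id = ``scaffold:position``) as unit."""
    ids = snp_fst_table["scaffold"].astype(str) + ":" + snp_fst_table["position"].astype(str)
    values = pd.Series(snp_fst_table["fst"].to_numpy(float), index=ids)
    return permute_sets(values, candidate_snp_ids, n_perm=n_perm, seed=seed,
                        exclude_candidates=exclude_candidates)
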