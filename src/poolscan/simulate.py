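"""Synthetic two-population pool-seq and immune-assay data with known truth.

Divergence model
----------------
Allele frequencies follow the Balding-Nichols model: each SNP has an
ancestral minor-allele frequency p ~ Uniform(0.05, 0.95), and each
population draws its own frequency from
Beta(p (1-F)/F, (1-p) (1-F)/F), whose expected fixation index is F.
Pool-seq observation adds the two sampling layers real data have:
the pooled individuals (allele count ~ Binomial(2 * pool_size, freq)),
then the reads (depth ~ Poisson(mean_depth), alternate-allele reads ~
Binomial(depth, pool frequency)).  The generator records every latent
frequency so any estimator expectation can be recomputed by brute
force from the truth table.

The default shape is a desk-scale genome — 2 scaffolds x 2 Mb, 500
genes, 20 candidate genes, roughly 2 x 10^4 SNPs at depth 100 with
pools of 50 — mirroring a low-divergence (F ~ 0.05) two-population
study design; all sizes scale up through :class:`SimulationConfig`.

The cohort generator emulates larval hemocyte assays: per-individual
cell-type composition ~ Dirichlet (granulocytes dominant), per-type
phagocytosis ~ Binomial with propensities differing by population and
sex, and hemocytometer counts matched to a total hemocyte concentration
of about 14,000 cells/µl (SD ~ 7,000).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationMap, GeneModel, SyncSite

log = logging.getLogger(__name__)

_BASES = np.array(["A", "T", "C", "G"])


@dataclass(frozen=True)
class SimulationConfig:
    """Genome, divergence and sequencing parameters for the generator."""

    n_scaffolds: int = 2
    scaffold_length: int = 2_000_000
    n_genes: int = 500
    min_exons: int = 1
    max_exons: int = 10
    exon_length_mean: int = 300
    snp_density: float = 0.005  # SNPs per bp (~2e4 on the default genome)
    monomorphic_density: float = 0.0005
    indel_density: float = 0.00005
    background_F: float = 0.05
    candidate_F: float | None = None  # planted signal in candidate-gene exons
    pool_size: tuple[int, int] = (50, 50)
    mean_depth: float = 100.0
    n_candidates: int = 20
    n_terms: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.background_F < 1.0):
            raise ValueError(f"background_F must be in (0,1), got {self.background_F}")
        if self.candidate_F is not None and not (0.0 < self.candidate_F < 1.0):
            raise ValueError(f"candidate_F must be in (0,1), got {self.candidate_F}")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if min(self.pool_size) < 1:
            raise ValueError("pool_size must be >= 1")

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: self.scaffold_length for name in self.scaffold_names}


@dataclass(frozen=True)
class Annotation:
    genes: tuple[GeneModel, ...]
    candidate_ids: frozenset[str]
    term_map: AnnotationMap
    scaffold_lengths: dict[str, int]


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig, seed: int | None = None) -> Annotation:
    """Place non-overlapping multi-exon genes and pick a candidate subset.

    The term map holds ``n_terms`` random functional terms plus one
    custom term containing exactly the candidate genes (the analogue of
    adding one's phagocytosis genes as their own category).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes: list[GeneModel] = []
    per_scaffold = [config.n_genes // config.n_scaffolds] * config.n_scaffolds
    for i in range(config.n_genes % config.n_scaffolds):
        per_scaffold[i] += 1
    gi = 0
    for scaf, n_here in zip(config.scaffold_names, per_scaffold):
        cursor = int(rng.integers(500, 2000))
        for _ in range(n_here):
            gi += 1
            n_exons = int(rng.integers(config.min_exons, config.max_exons + 1))
            exons = []
            pos = cursor
            for j in range(n_exons):
                length = max(50, int(rng.poisson(config.exon_length_mean)))
                exons.append((pos, pos + length))
                pos += length
                if j < n_exons - 1:
                    pos += int(rng.integers(100, 800))
            if pos > config.scaffold_length:
                raise ValueError(
                    f"gene placement exceeds scaffold length {config.scaffold_length}; "
                    "reduce n_genes or enlarge scaffolds"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene_{gi:05d}", scaf, strand, tuple(exons)))
            cursor = pos + int(rng.integers(500, 2500))
    gene_ids = [g.gene_id for g in genes]
    candidates = frozenset(rng.choice(gene_ids, size=config.n_candidates, replace=False))

    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(5, min(61, max(6, len(gene_ids) // 2))))
        term_id = f"TERM:{t + 1:04d}"
        terms[term_id] = set(rng.choice(gene_ids, size=size, replace=False))
        labels[term_id] = f"random term {t + 1}"
    amap = AnnotationMap(terms, labels)
    amap.add_term("TERM:candidate", candidates, "candidate phagocytosis genes")
    return Annotation(tuple(genes), candidates, amap, config.scaffold_lengths)


# ---------------------------------------------------------------------------
# divergence


def _exon_boundaries(genes: Sequence[GeneModel], scaffold: str, only: frozenset[str] | None = None):
    """Flattened sorted exon boundary/gene-id arrays for point lookup."""
    ivs = []
    for g in genes:
        if g.scaffold != scaffold or (only is not None and g.gene_id not in only):
            continue
        for s, e in g.exons:
            ivs.append((s, e, g.gene_id))
    ivs.sort()
    starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
    ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
    ids = np.array([g for _, _, g in ivs], dtype=object)
    return starts, ends, ids


def _lookup_genes(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray, ids: np.ndarray):
    """Gene id per 0-based position (None outside exons); exons non-overlap."""
    out = np.full(pos0.shape, None, dtype=object)
    if starts.size == 0:
        return out
    i = np.searchsorted(starts, pos0, side="right") - 1
    ok = (i >= 0) & (pos0 < ends[np.clip(i, 0, ends.size - 1)])
    out[ok] = ids[i[ok]]
    return out


def simulate_divergence_arrays(
    config: SimulationConfig,
    annotation: Annotation | None = None,
    seed: int | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Columnar form of :func:`simulate_divergence`.

    Returns a dict of aligned arrays — scaffold, position (1-based),
    ref base, and the two (n x 6) sync-order count matrices — plus the
    truth table.  This is the vectorised core; the SyncSite wrapper
    simply repackages it row by row.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if annotation is None:
        annotation = simulate_annotation(config, seed=int(rng.integers(2**31)))
    genes = annotation.genes

    out_scaf: list[np.ndarray] = []
    out_pos0: list[np.ndarray] = []
    out_ref: list[np.ndarray] = []
    out_c1: list[np.ndarray] = []
    out_c2: list[np.ndarray] = []
    truth_frames: list[pd.DataFrame] = []
    for scaf in config.scaffold_names:
        L = config.scaffold_length
        n_snps = int(round(config.snp_density * L))
        pos0 = np.sort(rng.choice(L, size=n_snps, replace=False))

        gene_id = _lookup_genes(pos0, *_exon_boundaries(genes, scaf))
        is_cand = np.array(
            [g in annotation.candidate_ids if g else False for g in gene_id], dtype=bool
        )
        F = np.full(n_snps, config.background_F)
        if config.candidate_F is not None:
            F[is_cand] = config.candidate_F

        p_anc = rng.uniform(0.05, 0.95, size=n_snps)
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_pop1 = rng.beta(a, b)
        p_pop2 = rng.beta(a, b)

        n1, n2 = 2 * config.pool_size[0], 2 * config.pool_size[1]
        pool_freq1 = rng.binomial(n1, p_pop1) / n1
        pool_freq2 = rng.binomial(n2, p_pop2) / n2

        depth1 = rng.poisson(config.mean_depth, size=n_snps)
        depth2 = rng.poisson(config.mean_depth, size=n_snps)
        alt1 = rng.binomial(depth1, pool_freq1)
        alt2 = rng.binomial(depth2, pool_freq2)

        ref_idx = rng.integers(0, 4, size=n_snps)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4

        counts1 = np.zeros((n_snps, 6), dtype=np.int64)
        counts2 = np.zeros((n_snps, 6), dtype=np.int64)
        rows = np.arange(n_snps)
        counts1[rows, ref_idx] = depth1 - alt1
        counts1[rows, alt_idx] += alt1
        counts2[rows, ref_idx] = depth2 - alt2
        counts2[rows, alt_idx] += alt2

        # monomorphic filler at configurable density, off SNP positions
        n_mono = int(round(config.monomorphic_density * L))
        mono_pos0 = np.setdiff1d(rng.choice(L, size=n_mono, replace=False), pos0)
        mono_ref = rng.integers(0, 4, size=mono_pos0.size)
        mono_c1 = np.zeros((mono_pos0.size, 6), dtype=np.int64)
        mono_c2 = np.zeros((mono_pos0.size, 6), dtype=np.int64)
        mono_rows = np.arange(mono_pos0.size)
        mono_c1[mono_rows, mono_ref] = rng.poisson(config.mean_depth, size=mono_pos0.size)
        mono_c2[mono_rows, mono_ref] = rng.poisson(config.mean_depth, size=mono_pos0.size)

        pos_all = np.concatenate([pos0, mono_pos0])
        order = np.argsort(pos_all, kind="stable")
        out_scaf.append(np.full(pos_all.size, scaf, dtype=object))
        out_pos0.append(pos_all[order])
        out_ref.append(np.concatenate([ref_idx, mono_ref])[order])
        out_c1.append(np.concatenate([counts1, mono_c1])[order])
        out_c2.append(np.concatenate([counts2, mono_c2])[order])

        truth_frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "position": pos0 + 1,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "F": F,
                    "p_anc": p_anc,
                    "p_pop1": p_pop1,
                    "p_pop2": p_pop2,
                    "pool_freq1": pool_freq1,
                    "pool_freq2": pool_freq2,
                    "gene_id": gene_id,
                    "is_candidate": is_cand,
                }
            )
        )
    truth = pd.concat(truth_frames, ignore_index=True)
    arrays = {
        "scaffold": np.concatenate(out_scaf),
        "position": np.concatenate(out_pos0) + 1,
        "ref": _BASES[np.concatenate(out_ref)],
        "counts1": np.vstack(out_c1),
        "counts2": np.vstack(out_c2),
    }
    log.info("simulated %d sites (%d SNPs) on %d scaffolds",
             len(arrays["position"]), len(truth), config.n_scaffolds)
    return arrays, truth


def simulate_divergence(
    config: SimulationConfig,
    annotation: Annotation | None = None,
    seed: int | None = None,
) -> tuple[list[SyncSite], pd.DataFrame]:
    """Generate sync sites for two pools plus the per-SNP truth table.

    Truth columns: scaffold, position (1-based), ref/alt bases, the F
    each SNP was simulated under, ancestral and per-population latent
    frequencies, realised pool allele frequencies after individual
    sampling, the containing gene (exonic SNPs) and a candidate flag.
    Monomorphic filler sites appear in the sync output only.
    """
    arrays, truth = simulate_divergence_arrays(config, annotation=annotation, seed=seed)
    sites = [
        SyncSite(
            arrays["scaffold"][i],
            int(arrays["position"][i]),
            str(arrays["ref"][i]),
            tuple(int(c) for c in arrays["counts1"][i]),
            tuple(int(c) for c in arrays["counts2"][i]),
        )
        for i in range(len(arrays["position"]))
    ]
    return sites, truth


def simulate_indels(config: SimulationConfig, seed: int | None = None) -> list[tuple[str, int]]:
    """Random indel positions (1-based) at ``indel_density`` per bp."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for scaf in config.scaffold_names:
        n = int(round(config.indel_density * config.scaffold_length))
        for p0 in np.sort(rng.choice(config.scaffold_length, size=n, replace=False)):
            out.append((scaf, int(p0) + 1))
    return out


# ---------------------------------------------------------------------------
# cohort


def _default_propensities() -> dict[str, dict[str, float]]:
    # north = high-latitude population with the higher phagocytic activity
    return {
        "north": {"granulocyte": 0.82, "plasmatocyte": 0.76, "oenocytoid": 0.62, "other": 0.35},
        "south": {"granulocyte": 0.68, "plasmatocyte": 0.63, "oenocytoid": 0.48, "other": 0.25},
    }


@dataclass(frozen=True)
class CohortConfig:
    """Larval cohort shape and generating immune parameters."""

    n_per_group: int = 11  # per population x sex, as in a 22-per-population assay
    populations: tuple[str, str] = ("north", "south")
    sexes: tuple[str, str] = ("F", "M")
    n_replicates: int = 2  # slides per larva; counts summed per individual
    cells_per_replicate_mean: float = 100.0
    composition_alpha: Mapping[str, float] = field(
        default_factory=lambda: {
            "granulocyte": 60.0, "plasmatocyte": 25.0, "oenocytoid": 10.0, "other": 5.0,
        }
    )
    propensities: Mapping[str, Mapping[str, float]] = field(default_factory=_default_propensities)
    male_propensity_shift: float = 0.04  # males phagocytose slightly more
    thc_mean: float = 14_037.0  # cells/µl
    thc_sd: float = 7_125.0
    thc_n_squares: int = 10
    thc_dilution: float = 1 / 20
    seed: int = 0

    def propensity(self, population: str, sex: str, cell_type: str) -> float:
        base = self.propensities[population][cell_type]
        if sex == "M":
            base += self.male_propensity_shift
        return float(np.clip(base, 0.0, 1.0))


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cell-count table (long), hemocytometer table, and generating truth.

    Per larva: a Dirichlet draw fixes its cell-type composition; each
    replicate slide draws a Poisson number of cells, splits them
    multinomially by type, and phagocytoses each type binomially at the
    group propensity.  The hemocytometer table draws a gamma-distributed
    latent concentration and Poisson chamber count per larva.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    types = list(config.composition_alpha)
    alpha = np.array([config.composition_alpha[t] for t in types], dtype=float)

    cell_rows, thc_rows = [], []
    # gamma matched to the target concentration mean and SD
    shape = (config.thc_mean / config.thc_sd) ** 2
    scale = config.thc_sd**2 / config.thc_mean
    ind = 0
    for pop in config.populations:
        for sex in config.sexes:
            props = np.array([config.propensity(pop, sex, t) for t in types])
            for _ in range(config.n_per_group):
                ind += 1
                ind_id = f"larva_{ind:04d}"
                comp = rng.dirichlet(alpha)
                for rep in range(1, config.n_replicates + 1):
                    n_cells = rng.poisson(config.cells_per_replicate_mean)
                    totals = rng.multinomial(n_cells, comp)
                    phag = rng.binomial(totals, props)
                    for t, tot, ph in zip(types, totals, phag):
                        cell_rows.append(
                            {
                                "individual_id": ind_id,
                                "population": pop,
                                "sex": sex,
                                "replicate_id": f"slide_{rep}",
                                "cell_type": t,
                                "total": int(tot),
                                "phagocytic": int(ph),
                            }
                        )
                conc = rng.gamma(shape, scale)
                lam = conc * config.thc_n_squares * config.thc_dilution / 10.0
                thc_rows.append(
                    {
                        "individual_id": ind_id,
                        "population": pop,
                        "sex": sex,
                        "cells_counted": int(rng.poisson(lam)),
                        "n_squares": config.thc_n_squares,
                        "dilution_fraction": config.thc_dilution,
                    }
                )
    truth = {
        "propensities": {
            (pop, sex, t): config.propensity(pop, sex, t)
            for pop in config.populations
            for sex in config.sexes
            for t in types
        },
        "composition_mean": dict(zip(types, alpha / alpha.sum())),
        "thc_mean": config.thc_mean,
        "thc_sd": config.thc_sd,
    }
    return pd.DataFrame(cell_rows), pd.DataFrame(thc_rows), truth
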