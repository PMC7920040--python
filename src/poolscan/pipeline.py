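"""End-to-end analysis driver.

Wires the stages in their canonical order — indel masking, SNP calling,
SNP/gene/flanking FST, candidate-set permutation tests (gene and SNP
unit), percentile outlier selection, term enrichment, scan report — and
writes every stage product as CSV plus a JSON run manifest recording
the config snapshot, derived seeds, input checksums and row counts.
Reruns with an identical config and inputs produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrichment as enr
from . import fst as fst_mod
from . import io as psio
from . import permutation as perm
from . import phenotype as pheno
from . import simulate as sim

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def derive_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _simulate_inputs(config: Mapping[str, Any], out_dir: Path, seed: int) -> dict[str, Path]:
    """Generate sync/annotation/candidate/term/indel/cohort inputs."""
    sim_cfg_raw = dict(config.get("simulate") or {})
    cohort_raw = sim_cfg_raw.pop("cohort", {})
    sim_cfg = sim.SimulationConfig(**{**sim_cfg_raw, "seed": seed})
    seeds = derive_seeds(seed, 4)
    ann = sim.simulate_annotation(sim_cfg, seed=seeds[0])
    sites, truth = sim.simulate_divergence(sim_cfg, annotation=ann, seed=seeds[1])
    indels = sim.simulate_indels(sim_cfg, seed=seeds[2])
    cohort_cfg = sim.CohortConfig(**{**cohort_raw, "seed": seeds[3]})
    cells, thc, _ = sim.simulate_cohort(cohort_cfg)

    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    paths = {
        "sync": inputs / "pools.sync",
        "genes": inputs / "genes.gff3",
        "candidates": inputs / "candidates.txt",
        "annotations": inputs / "terms.tsv",
        "indels": inputs / "indels.tsv",
        "cell_counts": inputs / "cell_counts.csv",
        "hemocytometer": inputs / "hemocytometer.csv",
    }
    psio.write_sync(sites, paths["sync"])
    psio.write_gene_models(list(ann.genes), paths["genes"])
    paths["candidates"].write_text("".join(f"{g}\n" for g in sorted(ann.candidate_ids)))
    psio.write_annotation_map(ann.term_map, paths["annotations"])
    with open(paths["indels"], "w") as fh:
        for scaf, pos in indels:
            fh.write(f"{scaf}\t{pos}\n")
    _write_csv(cells, paths["cell_counts"])
    _write_csv(thc, paths["hemocytometer"])
    _write_csv(truth, inputs / "truth_snps.csv")
    return paths


def run_full_analysis(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run the whole pipeline under one config; returns the output dir.

    ``config`` is a dict (or YAML path) with ``inputs`` paths — or a
    ``simulate`` section to generate them — plus optional ``fst``,
    ``permutation`` and ``outliers`` parameter blocks and a master
    ``seed`` from which all stage seeds derive.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    stage_seeds = derive_seeds(master_seed, 8)

    # ---- inputs
    if config.get("simulate") is not None:
        input_paths = _simulate_inputs(config, out, master_seed)
    else:
        raw = config.get("inputs") or {}
        input_paths = {k: Path(v) for k, v in raw.items()}
    for key in ("sync", "genes", "candidates"):
        if key not in input_paths:
            raise StageError("inputs", f"missing required input '{key}'")
        if not input_paths[key].exists():
            raise StageError("inputs", f"input '{key}' not found: {input_paths[key]}")

    fst_cfg = dict(config.get("fst") or {})
    flank = int(fst_cfg.get("flank", 5000))
    region_method = fst_cfg.get("region_method", "ratio")
    pool_size = fst_cfg.get("pool_size")
    pool_sizes = tuple(pool_size) if pool_size else None
    perm_cfg = dict(config.get("permutation") or {})
    n_perm = int(perm_cfg.get("n_perm", 10_000))
    out_cfg = dict(config.get("outliers") or {})
    percentile = float(out_cfg.get("percentile", 97.5))
    min_term_size = int(out_cfg.get("min_term_size", 5))

    counts: dict[str, int] = {}

    # ---- masking + SNP calling
    try:
        sites = psio.read_sync(input_paths["sync"])
        genes = psio.read_gene_models(
            input_paths["genes"], format=fst_cfg.get("gene_format", "gff3")
        )
        mask = None
        if "indels" in input_paths and input_paths["indels"].exists():
            mask = psio.build_indel_mask(
                psio.read_indel_positions(input_paths["indels"]),
                window=int(fst_cfg.get("indel_window", 5)),
            )
        sites = psio.apply_masks(
            sites, mask=mask, gene_models=genes,
            genic_only=bool(fst_cfg.get("genic_only", False)),
        )
        counts["sites_after_masking"] = len(sites)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("masking", str(exc)) from exc

    try:
        filt = fst_mod.SnpFilter(
            min_minor_count=int(fst_cfg.get("min_minor_count", 2)),
            min_coverage=int(fst_cfg.get("min_coverage", 10)),
            max_coverage=int(fst_cfg.get("max_coverage", 500)),
        )
        snp_df, rejections = fst_mod.call_snps(sites, filt)
        snp_df = fst_mod.add_fst_columns(snp_df, pool_sizes=pool_sizes)
        snp_df = fst_mod.assign_exonic_genes(snp_df, genes)
        counts["snps_called"] = len(snp_df)
        _write_csv(snp_df, out / "snps.csv")
    except Exception as exc:
        raise StageError("snp_calling", str(exc)) from exc

    # ---- gene / flanking FST
    try:
        scaffold_lengths = config.get("scaffold_lengths")
        gene_df = fst_mod.gene_fst_table(
            genes, snp_df, flank=flank,
            scaffold_lengths=scaffold_lengths, method=region_method,
        )
        counts["genes"] = len(gene_df)
        counts["genes_with_fst"] = int(gene_df["fst_gene"].notna().sum())
        _write_csv(gene_df, out / "genes.csv")

        exonic = snp_df[snp_df["gene_id"].notna()]
        summary = fst_mod.genomewide_summary(gene_df, exonic)
        summary.loc[summary["level"] == "snp", "level"] = "snp_exonic"
        all_row = fst_mod.genomewide_summary(gene_df.iloc[0:0], snp_df).iloc[[0]]
        all_row.loc[:, "level"] = "snp_all"
        summary = pd.concat([all_row, summary], ignore_index=True)
        _write_csv(summary, out / "summary.csv")
    except Exception as exc:
        raise StageError("gene_fst", str(exc)) from exc

    # ---- permutation tests
    try:
        candidates = [
            line.strip()
            for line in input_paths["candidates"].read_text().splitlines()
            if line.strip()
        ]
        bg_genes = gene_df[gene_df["fst_gene"].notna()].set_index("gene_id")["fst_gene"]
        dropped = sorted(set(candidates) - set(bg_genes.index))
        if dropped:
            log.info("%d candidate genes lack a defined FST and are dropped: %s",
                     len(dropped), dropped[:5])
        kept = [c for c in candidates if c in bg_genes.index]
        gene_perm = perm.permute_sets(bg_genes, kept, n_perm=n_perm, seed=stage_seeds[4])

        exonic = snp_df[snp_df["gene_id"].notna()]
        cand_snp_ids = (
            exonic.loc[exonic["gene_id"].isin(set(candidates)), "scaffold"].astype(str)
            + ":"
            + exonic.loc[exonic["gene_id"].isin(set(candidates)), "position"].astype(str)
        ).tolist()
        snp_perm = None
        if cand_snp_ids:
            snp_perm = perm.snp_level_permutation(
                exonic, cand_snp_ids, n_perm=n_perm, seed=stage_seeds[5]
            )
        rows = [{"unit": "gene", **gene_perm.as_row()}]
        if snp_perm is not None:
            rows.append({"unit": "snp", **snp_perm.as_row()})
        _write_csv(pd.DataFrame(rows), out / "permutation.csv")
        counts["candidate_genes_tested"] = len(kept)
        counts["candidate_snps_tested"] = len(cand_snp_ids)
    except (StageError,) as exc:
        raise
    except FileNotFoundError as exc:
        raise StageError("permutation", str(exc)) from exc
    except Exception as exc:
        raise StageError("permutation", str(exc)) from exc

    # ---- outliers + enrichment + scan report
    try:
        amap_raw = None
        if "annotations" in input_paths and input_paths["annotations"].exists():
            amap_raw = psio.read_annotation_map(input_paths["annotations"])
        for column in ("fst_gene", "fst_flanking_combined"):
            values = gene_df.set_index("gene_id")[column].dropna()
            sel = enr.select_outliers(values, percentile=percentile)
            pd.DataFrame(
                {
                    "gene_id": sorted(sel.outlier_ids),
                    "threshold": sel.threshold,
                    "percentile": sel.percentile,
                }
            ).to_csv(out / f"outliers_{column}.csv", index=False, float_format=_FLOAT_FMT)
            if amap_raw is not None and sel.outlier_ids:
                background = values.index
                amap = amap_raw.restrict(background, min_term_size=min_term_size)
                enr_df = enr.fisher_enrichment(sel.outlier_ids, amap, background)
                _write_csv(enr_df, out / f"enrichment_{column}.csv")
            if column == "fst_flanking_combined":
                report = enr.scan_report(gene_df, sel.threshold, candidates, value_column=column)
                _write_csv(report, out / "scan_report.csv")
                counts["outlier_genes_flanking"] = int(report["is_outlier"].sum())
    except Exception as exc:
        raise StageError("outlier_enrichment", str(exc)) from exc

    # ---- phenotype (optional)
    try:
        if "cell_counts" in input_paths and input_paths["cell_counts"].exists():
            long_df = pheno.read_cell_counts(input_paths["cell_counts"])
            _write_csv(pheno.individual_indices(long_df), out / "phenotype_indices.csv")
            _write_csv(pheno.assay_summary(long_df), out / "phenotype_summary.csv")
            counts["phenotype_individuals"] = long_df["individual_id"].nunique()
        if "hemocytometer" in input_paths and input_paths["hemocytometer"].exists():
            thc_df = pheno.thc_table(pd.read_csv(input_paths["hemocytometer"]))
            _write_csv(thc_df, out / "thc.csv")
    except Exception as exc:
        raise StageError("phenotype", str(exc)) from exc

    manifest = {
        "software": {"name": "poolscan", "version": __version__},
        "seed": master_seed,
        "stage_seeds": stage_seeds,
        "config": {k: v for k, v in config.items()},
        "input_checksums": {
            k: _sha256(p) for k, p in sorted(input_paths.items()) if p.exists()
        },
        "snp_rejections": rejections,
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
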