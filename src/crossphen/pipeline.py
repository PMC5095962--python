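"""End-to-end orchestration: QC -> heritability -> scans -> FDR -> enrichment.

A run is configured either with input file paths (genotypes, phenotypes,
gene models, annotations) or with a :class:`~crossphen.simulate.SimConfig`
(exactly one of the two).  Every stage writes its TSV into the output
directory, a resolved copy of the configuration is saved for provenance,
and a machine-readable summary (JSON, sorted keys) captures seeds,
versions and per-stage tallies, so identical config + seed reproduces
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cpio
from . import qc
from .cross import scan_cross_phenotype, valid_trait_pairs
from .fdr import estimate_fdr_cross_pairs, estimate_fdr_single
from .models import GenotypePanel, PhenotypeTable, TraitMatrix
from .scan import scan_single_trait
from .simulate import (
    DEFAULT_NORMALIZERS,
    SimConfig,
    random_annotations,
    simulate_panel,
    simulate_phenotypes,
    tile_gene_models,
)
from .enrich import gene_level_scores, rank_enrichment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str | Path = "crossphen_run"
    # exactly one of (file inputs | sim) must be provided
    genotypes: str | None = None
    phenotypes: str | None = None
    genes: str | None = None
    annotations: str | None = None
    sim: SimConfig | None = None

    maf_tiers: tuple = (0.05, 0.25)
    homolog_subset: bool = False
    window_bp: int = 1000
    traits: list | None = None
    normalizers: dict | None = None
    diets: tuple = ("AL", "DR")
    replicate_fold: float = 20.0
    n_perm: int = 10
    fdr_p_column: str = "p_genotype"
    cross_fdr_threshold: float | None = None
    seed: int = 0

    def validate(self) -> None:
        has_files = self.genotypes is not None and self.phenotypes is not None
        if has_files == (self.sim is not None):
            raise ValueError("provide either input file paths or a SimConfig, not both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim = raw["sim"]
            if "planted_effects" in sim:
                from .simulate import PlantedEffect

                sim["planted_effects"] = [PlantedEffect(**pe) for pe in sim["planted_effects"]]
            raw["sim"] = SimConfig(**sim)
        if "maf_tiers" in raw:
            raw["maf_tiers"] = tuple(raw["maf_tiers"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    panel, table, genes, annotations, truth = _load_inputs(config, out)
    summary["stages"]["inputs"] = {
        "n_lines": panel.n_lines,
        "n_markers": panel.n_markers,
        "n_phenotype_records": len(table),
        "n_genes": len(genes) if genes is not None else 0,
    }

    # --- replicate QC and strain means ----------------------------------
    filtered, removed = qc.filter_replicate_outliers(table, fold=config.replicate_fold)
    pd.DataFrame(removed, columns=["line", "trait"]).to_csv(
        out / "qc_removed.tsv", sep="\t", index=False
    )
    matrix = qc.strain_means(filtered)
    matrix.df.to_csv(out / "strain_means.tsv", sep="\t", index=False)
    summary["stages"]["qc"] = {"n_removed_line_traits": len(removed)}

    # --- heritability ----------------------------------------------------
    herit = pd.concat(
        [qc.heritability_table(filtered, diet) for diet in (*config.diets, None)],
        ignore_index=True,
    )
    herit.to_csv(out / "heritability.tsv", sep="\t", index=False)
    summary["stages"]["heritability"] = {
        f"{r.trait}/{r.diet}": round(float(r.H2), 6) for r in herit.itertuples()
    }

    traits = config.traits or [t for t in matrix.traits]
    scan_panel = panel
    if config.homolog_subset and genes:
        scan_panel = cpio.homolog_marker_subset(panel, genes, config.window_bp)
        summary["stages"]["homolog_subset"] = {"n_markers": scan_panel.n_markers}

    # --- single-trait scans ---------------------------------------------
    scans: dict[tuple[str, float], pd.DataFrame] = {}
    for trait in traits:
        for tier in config.maf_tiers:
            res = scan_single_trait(scan_panel, matrix, trait, min_maf=tier)
            scans[(trait, tier)] = res
            res.to_csv(out / f"scan_{_safe(trait)}_maf{tier:g}.tsv", sep="\t", index=False)
    summary["stages"]["single_scans"] = {
        f"{trait}@maf>={tier:g}": int((s["skip_reason"] == "").sum())
        for (trait, tier), s in scans.items()
    }

    # --- cross-phenotype scans ------------------------------------------
    normalizers = config.normalizers
    if normalizers is None:
        normalizers = {t: DEFAULT_NORMALIZERS.get(t) for t in traits}
    pairs = valid_trait_pairs(normalizers)
    base_tier = config.maf_tiers[0]
    cross_scans: dict[tuple[tuple[str, str], str], pd.DataFrame] = {}
    for pair in pairs:
        for diet in config.diets:
            res = scan_cross_phenotype(scan_panel, matrix, pair, diet, min_maf=base_tier)
            cross_scans[(pair, diet)] = res
            res.to_csv(
                out / f"cross_{_safe(pair[0])}__{_safe(pair[1])}_{diet}.tsv",
                sep="\t", index=False,
            )
    summary["stages"]["cross_scans"] = {
        f"{a}|{b}@{diet}": int((s["skip_reason"] == "").sum())
        for ((a, b), diet), s in cross_scans.items()
    }

    # --- permutation FDR (single-trait construction) ---------------------
    fdr_summaries = {}
    for trait in traits:
        real = scans[(trait, base_tier)][config.fdr_p_column].to_numpy()

        def scan_fn(perm_matrix: TraitMatrix, _trait=trait) -> np.ndarray:
            return scan_single_trait(
                scan_panel, perm_matrix, _trait, min_maf=base_tier
            )[config.fdr_p_column].to_numpy()

        fdr_table = estimate_fdr_single(
            real, scan_fn, matrix, n_perm=config.n_perm, seed=config.seed + 101
        )
        fdr_table.to_frame().to_csv(out / f"fdr_{_safe(trait)}.tsv", sep="\t", index=False)
        calls10 = _calls_at_fdr(fdr_table, 0.10)
        fdr_summaries[trait] = {"n_calls_at_fdr10": calls10}
    summary["stages"]["fdr_single"] = fdr_summaries

    # --- cross-pair corrected FDR ----------------------------------------
    if pairs:
        def pair_scan_fn(p: GenotypePanel) -> dict:
            return {
                f"{a}|{b}@{diet}": scan_cross_phenotype(
                    p, matrix, (a, b), diet, min_maf=base_tier
                )["p_joint"].to_numpy()
                for (a, b) in pairs
                for diet in config.diets
            }

        t = config.cross_fdr_threshold
        if t is None:
            best = min(
                (np.nanmin(s["p_joint"].to_numpy()) for s in cross_scans.values()),
                default=float("nan"),
            )
            t = float(best) if np.isfinite(best) and best > 0 else 1e-6
        cross_fdr = estimate_fdr_cross_pairs(
            scan_panel, pair_scan_fn, t, n_perm=config.n_perm, seed=config.seed + 202
        )
        with open(out / "fdr_cross_pairs.json", "w") as fh:
            json.dump(cross_fdr, fh, indent=2, sort_keys=True)
        summary["stages"]["fdr_cross_pairs"] = {
            "t": cross_fdr["t"], "fdr": _round(cross_fdr["fdr"]), "n_true": cross_fdr["n_true"]
        }

    # --- enrichment -------------------------------------------------------
    if genes and annotations is not None and len(annotations):
        assignment = cpio.assign_markers_to_genes(scan_panel, genes, config.window_bp)
        lengths = {g.id: g.length for g in genes}
        enrich_summary = {}
        for trait in traits:
            try:
                ranked = gene_level_scores(scans[(trait, base_tier)], assignment, genes)
                res = rank_enrichment(ranked, annotations, lengths)
            except ValueError as exc:
                logger.warning("enrichment skipped for %s: %s", trait, exc)
                continue
            res.to_csv(out / f"enrichment_{_safe(trait)}.tsv", sep="\t", index=False)
            enrich_summary[trait] = {
                "n_terms": int(len(res)),
                "n_q05": int((res["q_bh"] < 0.05).sum()),
            }
        summary["stages"]["enrichment"] = enrich_summary

    _write_resolved_config(config, out)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _calls_at_fdr(fdr_table, level: float) -> int:
    ok = np.flatnonzero((fdr_table.fdr <= level) & (fdr_table.n_real > 0))
    return int(fdr_table.n_real[ok].max()) if ok.size else 0


def _round(x) -> float:
    return float(np.round(x, 6)) if np.isfinite(x) else float("nan")


def _safe(name: str) -> str:
    return name.replace("/", "-").replace(" ", "_")


def _load_inputs(config: RunConfig, out: Path):
    truth = None
    if config.sim is not None:
        sim = config.sim
        panel = simulate_panel(sim)
        table, truth = simulate_phenotypes(panel, sim)
        genes = tile_gene_models(panel, seed=sim.seed)
        annotations = random_annotations(genes, seed=sim.seed)
    else:
        panel = cpio.read_genotypes(config.genotypes)
        table = cpio.read_phenotypes(config.phenotypes)
        genes = cpio.read_gene_models(config.genes) if config.genes else []
        annotations = (
            cpio.read_annotations(config.annotations) if config.annotations else None
        )
    return panel, table, genes, annotations, truth


def _write_resolved_config(config: RunConfig, out: Path) -> None:
    raw = dataclasses.asdict(config)
    raw["out_dir"] = str(config.out_dir)
    if config.sim is not None:
        raw["sim"]["trait_correlation"] = config.sim.correlation().tolist()
        raw["sim"]["diets"] = list(config.sim.diets)
        raw["sim"]["trait_names"] = list(config.sim.traits())
        raw["sim"]["maf_distribution"] = [
            config.sim.maf_distribution[0], list(config.sim.maf_distribution[1])
        ]
    raw["maf_tiers"] = list(config.maf_tiers)
    raw["diets"] = list(config.diets)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
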