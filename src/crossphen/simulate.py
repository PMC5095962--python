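"""Synthetic inbred-line panel generator with known planted effects.

Emulates the statistical structure of a two-diet metabolic survey of a
homozygous line panel: ~150-200 fully inbred lines genotyped at
biallelic markers, phenotyped on ad libitum (AL) and dietary-restriction
(DR) food for several correlated traits, with 1-2 biological replicates
per line.  The generative model for a measurement is

    y(line, diet, trait, rep) = intercept
                              + beta_diet[trait] * d
                              + sum_planted (beta_g * g + beta_gxd * g * d)
                              + u(line, trait)
                              + eps

with d in {0, 1} coding {AL, DR}, u a line-level effect drawn once per
line from a correlated multivariate normal (variance ``line_variance``,
correlation ``trait_correlation``) and shared across diets, and eps iid
noise with variance ``residual_variance``.  Everything is deterministic
given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import DIETS, GeneModel, GenotypePanel, Marker, PhenotypeTable
from . import io as cpio

#: Trait names mirroring the survey design: starvation resistance, body
#: mass, and mass-normalized triglyceride and glucose content.
DEFAULT_TRAITS = ("starvation", "mass", "tag_per_mass", "glucose_per_mass")

#: Normalizer tags for the default traits (drives admissible pair logic).
DEFAULT_NORMALIZERS = {"tag_per_mass": "mass", "glucose_per_mass": "mass"}


@dataclass
class PlantedEffect:
    """A causal marker: additive effect and/or diet interaction."""

    marker_index: int
    trait_index: int
    beta_genotype: float
    beta_interaction: float = 0.0


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the emulated study conditions.

    175 lines (the survey phenotyped 159-181 strains depending on trait),
    markers with allele frequencies uniform on [0.05, 0.5], four traits
    with modestly correlated line effects, a strong diet main effect, and
    broad-sense heritability ~0.6 (line variance 0.6 vs residual 0.4).
    Replicates default to the survey's mixed design: one biological
    replicate for a random half of lines and two for the rest.
    """

    n_lines: int = 175
    n_markers: int = 2000
    maf_distribution: tuple = ("uniform", (0.05, 0.5))
    diets: tuple = DIETS
    n_traits: int = 4
    trait_correlation: np.ndarray | None = None
    n_replicates_per_line: int | dict | None = None
    planted_effects: list = field(default_factory=list)
    diet_effect: float | np.ndarray = 1.0
    line_variance: float = 0.6
    residual_variance: float = 0.4
    intercept: float = 10.0
    trait_names: tuple = DEFAULT_TRAITS
    seed: int = 0

    def correlation(self) -> np.ndarray:
        if self.trait_correlation is not None:
            c = np.asarray(self.trait_correlation, dtype=float)
        else:
            # modest shared physiology between metabolic traits
            c = np.full((self.n_traits, self.n_traits), 0.3)
            np.fill_diagonal(c, 1.0)
        if c.shape != (self.n_traits, self.n_traits):
            raise ValueError("trait_correlation must be K x K")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("trait_correlation must be positive definite")
        return c

    def traits(self) -> list[str]:
        names = list(self.trait_names)[: self.n_traits]
        while len(names) < self.n_traits:
            names.append(f"trait{len(names)}")
        return names

    def validate(self) -> None:
        if self.line_variance < 0 or self.residual_variance < 0:
            raise ValueError("variances must be >= 0")
        for pe in self.planted_effects:
            if not 0 <= pe.marker_index < self.n_markers:
                raise ValueError(f"planted marker index {pe.marker_index} out of range")
            if not 0 <= pe.trait_index < self.n_traits:
                raise ValueError(f"planted trait index {pe.trait_index} out of range")


@dataclass
class SimTruth:
    """Ground truth for recovery tests.

    ``line_values``: per (line, trait, diet) expected phenotype net of
    diet main effect and noise (line effect + planted genetic effects).
    ``realized_h2``: per-trait broad-sense heritability implied by the
    realized between-line variance of those values (averaged over the
    two diets) against the residual variance.
    """

    line_values: pd.DataFrame
    planted_effects: list
    realized_h2: dict
    config: SimConfig

    def causal_marker_ids(self, panel: GenotypePanel) -> set[str]:
        return {panel.markers[pe.marker_index].id for pe in self.planted_effects}


def _draw_maf(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name, params = law
    if name == "uniform":
        lo, hi = params
        freqs = rng.uniform(lo, hi, size=n)
    elif name == "point":
        freqs = np.full(n, float(params[0]))
    elif name == "beta":
        a, b = params
        freqs = 0.05 + 0.45 * rng.beta(a, b, size=n)
    else:
        raise ValueError(f"unknown maf law {name!r}")
    if n and (freqs.min() < 0 or freqs.max() > 0.5):
        raise ValueError("maf law has mass outside [0, 0.5]")
    return freqs


def simulate_panel(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw a homozygous genotype panel.

    Per marker, a target alternate-allele frequency is drawn from the
    MAF law, then each line's call is an independent Bernoulli draw.
    Markers are laid out every 200 bp on a single synthetic chromosome.
    """
    if config.n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lines = [f"line{i:03d}" for i in range(config.n_lines)]
    freqs = _draw_maf(config.maf_distribution, config.n_markers, rng)
    calls = (rng.random((config.n_lines, config.n_markers)) < freqs).astype(float)
    markers = [
        Marker(f"chr1:{1 + 200 * j}", "chr1", 1 + 200 * j, "A", "T")
        for j in range(config.n_markers)
    ]
    return GenotypePanel(lines, markers, calls)


def simulate_phenotypes(
    panel: GenotypePanel, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PhenotypeTable, SimTruth]:
    """Draw replicated two-diet phenotypes with planted effects."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    K = config.n_traits
    n = panel.n_lines
    traits = config.traits()
    corr = config.correlation()
    if config.line_variance > 0:
        cov = config.line_variance * corr
        u = rng.multivariate_normal(np.zeros(K), cov, size=n, method="cholesky")
    else:
        u = np.zeros((n, K))

    beta_diet = np.broadcast_to(np.asarray(config.diet_effect, dtype=float), (K,))

    # expected phenotype net of diet main effect and noise: (line, trait, diet)
    lv = np.repeat(u[:, :, None], 2, axis=2)
    for pe in config.planted_effects:
        g = panel.calls[:, pe.marker_index]
        if np.isnan(g).any():
            raise ValueError("planted markers must have complete calls")
        lv[:, pe.trait_index, 0] += pe.beta_genotype * g
        lv[:, pe.trait_index, 1] += (pe.beta_genotype + pe.beta_interaction) * g

    reps = _replicate_counts(config, panel.lines, rng)
    rows = []
    sd = float(np.sqrt(config.residual_variance))
    for i, line in enumerate(panel.lines):
        r = reps[line]
        for di, diet in enumerate(config.diets):
            mu = config.intercept + beta_diet * di + lv[:, :, di][i]
            eps = rng.normal(0.0, 1.0, size=(r, K)) * sd
            for rep in range(r):
                for k in range(K):
                    rows.append((line, diet, traits[k], rep + 1, mu[k] + eps[rep, k]))
    table = PhenotypeTable(
        pd.DataFrame(rows, columns=["line", "diet", "trait", "replicate", "value"])
    )

    realized_h2 = {}
    for k, t in enumerate(traits):
        var_between = float(np.mean([np.var(lv[:, k, d], ddof=1) for d in (0, 1)]))
        denom = var_between + config.residual_variance
        realized_h2[t] = var_between / denom if denom > 0 else float("nan")

    lv_rows = [
        (line, traits[k], config.diets[d], lv[i, k, d])
        for i, line in enumerate(panel.lines)
        for k in range(K)
        for d in (0, 1)
    ]
    truth = SimTruth(
        line_values=pd.DataFrame(lv_rows, columns=["line", "trait", "diet", "value"]),
        planted_effects=list(config.planted_effects),
        realized_h2=realized_h2,
        config=config,
    )
    return table, truth


def _replicate_counts(config: SimConfig, lines: list[str], rng: np.random.Generator) -> dict:
    spec = config.n_replicates_per_line
    if isinstance(spec, dict):
        return {line: int(spec[line]) for line in lines}
    if spec is None:
        # survey-style mixed design: half the lines single-replicate
        n = len(lines)
        single = set(rng.permutation(n)[: n // 2])
        return {line: (1 if i in single else 2) for i, line in enumerate(lines)}
    return {line: int(spec) for line in lines}


def tile_gene_models(
    panel: GenotypePanel,
    gene_length: int = 2000,
    gap: int = 2000,
    homolog_fraction: float = 0.3,
    seed: int = 0,
) -> list[GeneModel]:
    """Tile gene models over the simulated chromosome span.

    Gene lengths vary log-normally around ``gene_length`` (real gene
    length distributions are heavy-tailed, and the enrichment stage
    adjusts for length, so the variation matters); a random fraction is
    flagged as disease homologs for homolog-subset scans.
    """
    if not panel.markers:
        return []
    rng = np.random.default_rng(seed)
    span = max(m.pos for m in panel.markers)
    genes = []
    start, i = 0, 0
    while start < span:
        length = max(200, int(gene_length * rng.lognormal(0.0, 0.5)))
        genes.append(
            GeneModel(
                f"G{i:05d}", "chr1", start, start + length,
                bool(rng.random() < homolog_fraction),
            )
        )
        start += length + gap
        i += 1
    return genes


def random_annotations(
    genes: list[GeneModel], n_terms: int = 50, mean_terms_per_gene: float = 2.0, seed: int = 0
) -> pd.DataFrame:
    """Random gene-to-term annotations (2-column frame: gene, term)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        k = min(n_terms, rng.poisson(mean_terms_per_gene))
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append((g.id, f"T{t:04d}"))
    return pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates().reset_index(drop=True)


def write_fixture_bundle(config: SimConfig, directory: str | Path) -> dict[str, Path]:
    """Simulate a full study and write it as a parseable file bundle.

    Emits genotypes.vcf, phenotypes.tsv, genes.gff3, annotations.tsv,
    truth.tsv and a config.yaml sidecar echoing all parameters; a given
    seed always yields byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel(config)
    table, truth = simulate_phenotypes(panel, config)
    genes = tile_gene_models(panel, seed=config.seed)
    annotations = random_annotations(genes, seed=config.seed)

    paths = {
        "genotypes": directory / "genotypes.vcf",
        "phenotypes": directory / "phenotypes.tsv",
        "genes": directory / "genes.gff3",
        "annotations": directory / "annotations.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "config.yaml",
    }
    cpio.write_genotypes(panel, paths["genotypes"], format="vcf")
    cpio.write_phenotypes(table, paths["phenotypes"])
    cpio.write_gene_models(genes, paths["genes"])
    cpio.write_annotations(annotations, paths["annotations"])

    traits = config.traits()
    truth_rows = [
        {
            "kind": "planted",
            "marker": panel.markers[pe.marker_index].id,
            "trait": traits[pe.trait_index],
            "beta_genotype": pe.beta_genotype,
            "beta_interaction": pe.beta_interaction,
        }
        for pe in truth.planted_effects
    ] + [
        {"kind": "realized_h2", "marker": "", "trait": t,
         "beta_genotype": h2, "beta_interaction": ""}
        for t, h2 in truth.realized_h2.items()
    ]
    pd.DataFrame(
        truth_rows, columns=["kind", "marker", "trait", "beta_genotype", "beta_interaction"]
    ).to_csv(paths["truth"], sep="\t", index=False)

    cfg = asdict(config)
    cfg["trait_correlation"] = config.correlation().tolist()
    cfg["planted_effects"] = [asdict(pe) for pe in config.planted_effects]
    cfg["diet_effect"] = np.broadcast_to(
        np.asarray(config.diet_effect, dtype=float), (config.n_traits,)
    ).tolist()
    cfg["diets"] = list(config.diets)
    cfg["trait_names"] = list(config.traits())
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
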