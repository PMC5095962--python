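"""Replicate QC, strain means, diet-ratio traits and broad-sense heritability.

Broad-sense heritability for an inbred panel follows the
variance-partition estimator

    H^2 = (sigma2_total - sigma2_intrastrain) / sigma2_total

where sigma2_total is the variance across all measurements of lines with
replicate measurements and sigma2_intrastrain is the average of the
per-line replicate variances.  Sample (n-1) variances are used
throughout for unbiasedness at small replicate counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import HeritabilityResult, PhenotypeTable, TraitMatrix

logger = logging.getLogger(__name__)


def filter_replicate_outliers(
    table: PhenotypeTable, fold: float = 20.0
) -> tuple[PhenotypeTable, list[tuple[str, str]]]:
    """Drop lines whose replicate variance dwarfs the panel's typical value.

    For each trait, replicate variance is computed within every
    (line, diet) cell that has >= 2 replicates; the reference is the
    median of those variances across the trait.  A line whose variance
    in any cell exceeds ``fold`` times the median (strictly) is removed
    for that trait only (both diets).  Returns the filtered table and
    the removed (line, trait) pairs.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    df = table.df
    removed: list[tuple[str, str]] = []
    grp = df.groupby(["trait", "line", "diet"])["value"]
    sizes = grp.size()
    variances = grp.var(ddof=1)
    variances = variances[sizes >= 2]
    if variances.empty:
        logger.warning("no line has >= 2 replicates; replicate filter is a no-op")
        return table, removed
    for trait, sub in variances.groupby(level="trait"):
        ref = float(sub.median())
        flagged = sub[sub > fold * ref]
        for (_, line, _diet) in flagged.index:
            if (line, trait) not in removed:
                removed.append((line, trait))
    if removed:
        mask = pd.Series(True, index=df.index)
        for line, trait in removed:
            mask &= ~((df["line"] == line) & (df["trait"] == trait))
        df = df[mask]
        logger.info("replicate filter removed %d (line, trait) pairs", len(removed))
    return PhenotypeTable(df), removed


def strain_means(table: PhenotypeTable) -> TraitMatrix:
    """Average phenotype measurements across replicates per (line, diet, trait)."""
    if len(table) == 0:
        raise ValueError("phenotype table is empty")
    means = (
        table.df.groupby(["line", "diet", "trait"], as_index=False)["value"].mean()
    )
    return TraitMatrix(means)


def diet_ratio_trait(matrix: TraitMatrix, trait: str) -> TraitMatrix:
    """Append a per-line AL/DR ratio as a derived trait "<trait>_AL/DR".

    Lines missing either diet value or with a zero DR value are skipped
    (logged).  The derived trait lives in a single "AL" stratum since it
    has no diet dimension of its own.
    """
    wide = matrix.pivot(trait)
    if "AL" not in wide.columns or "DR" not in wide.columns:
        raise ValueError(f"trait {trait!r} must be measured on both diets")
    ok = wide["AL"].notna() & wide["DR"].notna() & (wide["DR"] != 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("diet ratio for %s: %d lines skipped (missing or zero DR)", trait, n_skipped)
    ratio = wide.loc[ok, "AL"] / wide.loc[ok, "DR"]
    extra = pd.DataFrame(
        {"line": ratio.index, "diet": "AL", "trait": f"{trait}_AL/DR", "value": ratio.values}
    )
    return TraitMatrix(pd.concat([matrix.df, extra], ignore_index=True))


def broad_sense_heritability(
    table: PhenotypeTable, trait: str, diet: str | None = "AL"
) -> HeritabilityResult:
    """Variance-partition H^2 for one trait.

    ``diet`` selects one diet stratum (default) or pools both diets when
    None (diet differences then count as intrastrain only if replicates
    are pooled across diets — pooled mode keeps replicate variance
    within (line, diet) cells and pools the cells).  Only lines with
    >= 2 replicates enter both variance components.
    """
    df = table.df[table.df["trait"] == trait]
    if diet is not None:
        df = df[df["diet"] == diet]
    if df.empty:
        raise ValueError(f"no measurements for trait {trait!r} diet {diet!r}")
    cell = ["line"] if diet is not None else ["line", "diet"]
    sizes = df.groupby(cell)["value"].size()
    replicated = sizes[sizes >= 2].index
    if len(replicated) < 2:
        raise ValueError(
            f"heritability for trait {trait!r} diet {diet!r} needs >= 2 lines "
            "with >= 2 replicates"
        )
    keyed = df.set_index(cell)
    sub = keyed.loc[keyed.index.isin(replicated)]
    sigma2_total = float(sub["value"].var(ddof=1))
    sigma2_intra = float(sub.groupby(level=list(range(len(cell))))["value"].var(ddof=1).mean())
    h2 = (sigma2_total - sigma2_intra) / sigma2_total if sigma2_total > 0 else float("nan")
    result = HeritabilityResult(
        trait=trait,
        diet=diet,
        sigma2_total=sigma2_total,
        sigma2_intrastrain=sigma2_intra,
        h2=h2,
        n_lines=int(len(set(i[0] if isinstance(i, tuple) else i for i in replicated))),
    )
    if result.flagged_negative:
        logger.warning("negative H2 for %s/%s: %.3f (intrastrain > total)", trait, diet, h2)
    return result


def heritability_table(table: PhenotypeTable, diet: str | None = "AL") -> pd.DataFrame:
    """H^2 for every trait that meets the replicate precondition."""
    rows = []
    for trait in table.traits:
        try:
            r = broad_sense_heritability(table, trait, diet)
        except ValueError:
            continue
        rows.append(
            {
                "trait": r.trait,
                "diet": r.diet if r.diet is not None else "pooled",
                "sigma2_total": r.sigma2_total,
                "sigma2_intrastrain": r.sigma2_intrastrain,
                "H2": r.h2,
                "n_lines": r.n_lines,
                "flagged_negative": r.flagged_negative,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait", "diet", "sigma2_total", "sigma2_intrastrain",
            "H2", "n_lines", "flagged_negative",
        ],
    )
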