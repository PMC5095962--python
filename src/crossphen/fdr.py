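"""Permutation-based false discovery rate estimation.

Single-trait scans: phenotype vectors are randomized across lines while
the true diet assignment is retained (a line's AL and DR means, and all
traits, move together), the full scan is re-run per permutation, and

    fdr(t) = mean_i n_i(t) / n_real(t)

where n_i(t) counts markers with p <= t in permutation i and n_real(t)
counts real calls.  Ten permutations by default; this gives coarse FDR
resolution, and a warning says so.

Cross-pair family: one permuted genotype-to-strain assignment per
permutation is reused across every trait pair, a locus counts when it
reaches t in at least one pair, and the family FDR at t is
mean(n_perm) / n_true.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import FDRTable, GenotypePanel, TraitMatrix

logger = logging.getLogger(__name__)


def permute_phenotypes(matrix: TraitMatrix, seed: int | np.random.Generator) -> TraitMatrix:
    """Randomize phenotype vectors across lines, keeping diet assignment.

    Each line receives another line's complete phenotype vector (all
    traits, both diets), so every per-diet value multiset is preserved
    exactly.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(matrix.lines)
    if n < 2:
        raise ValueError("permutation needs >= 2 lines")
    order = rng.permutation(n)
    return matrix.permute_lines(order)


def permute_genotypes(panel: GenotypePanel, seed: int | np.random.Generator) -> GenotypePanel:
    """Permute the assignment of genotype rows to strains."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(panel.n_lines)
    return GenotypePanel(panel.lines, panel.markers, panel.calls[order, :])


def _counts_at(pvals: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    p = np.sort(pvals[~np.isnan(pvals)])
    return np.searchsorted(p, thresholds, side="right")


def estimate_fdr_single(
    real_pvalues: Sequence[float],
    scan_fn: Callable[[TraitMatrix], np.ndarray],
    matrix: TraitMatrix,
    thresholds: Sequence[float] | None = None,
    n_perm: int = 10,
    seed: int = 0,
) -> FDRTable:
    """Permutation FDR for a single-trait scan.

    ``scan_fn`` maps a (permuted) TraitMatrix to the per-marker p-value
    array of the re-run scan.  ``thresholds`` defaults to the sorted
    distinct real p-values (decreasing), so the FDR is evaluable at
    every achievable call set.  A scan failure inside a permutation
    aborts: partial permutation sets would bias the estimate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm <= 10:
        logger.warning("n_perm = %d gives coarse FDR resolution", n_perm)
    real = np.asarray(real_pvalues, dtype=float)
    real = real[~np.isnan(real)]
    if thresholds is None:
        thresholds = np.unique(real)[::-1]
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and (thresholds.min() <= 0 or thresholds.max() > 1):
        raise ValueError("thresholds must lie in (0, 1]")

    n_real = _counts_at(real, thresholds)
    rng = np.random.default_rng(seed)
    perm_counts = np.zeros((n_perm, thresholds.size))
    for i in range(n_perm):
        permuted = permute_phenotypes(matrix, rng)
        pvals = np.asarray(scan_fn(permuted), dtype=float)
        _assert_multisets_preserved(matrix, permuted)
        perm_counts[i] = _counts_at(pvals, thresholds)
    mean_n_perm = perm_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_raw = np.where(n_real > 0, mean_n_perm / np.maximum(n_real, 1), np.nan)
    return FDRTable(
        thresholds=thresholds,
        n_real=n_real,
        mean_n_perm=mean_n_perm,
        fdr_raw=fdr_raw,
        n_permutations=n_perm,
        seed=seed if isinstance(seed, int) else -1,
    )


def _assert_multisets_preserved(before: TraitMatrix, after: TraitMatrix) -> None:
    for (diet, trait), sub in before.df.groupby(["diet", "trait"]):
        other = after.df[(after.df["diet"] == diet) & (after.df["trait"] == trait)]
        if not np.array_equal(np.sort(sub["value"].to_numpy()), np.sort(other["value"].to_numpy())):
            raise AssertionError("permutation altered a per-diet value multiset")


def estimate_fdr_cross_pairs(
    panel: GenotypePanel,
    pair_scan_fn: Callable[[GenotypePanel], dict],
    t: float,
    n_perm: int = 10,
    seed: int = 0,
) -> dict:
    """Multiple-testing-corrected FDR across the trait-pair family.

    ``pair_scan_fn`` maps a (possibly genotype-permuted) panel to a dict
    pair -> per-marker p-value array, all aligned on the same marker
    order.  n_true counts loci reaching significance at or below t in at
    least one pair on the real panel; each permutation reuses a single
    genotype-to-strain shuffle across all pairs.  Returns the corrected
    FDR with its components.
    """
    if not 0 < t <= 1:
        raise ValueError("t must be in (0, 1]")
    real = pair_scan_fn(panel)
    n_true = int(_family_calls(real, t))
    if n_true == 0:
        logger.warning("no real locus reaches t = %g in any pair; FDR undefined", t)
        return {"t": t, "n_true": 0, "mean_n_perm": float("nan"), "fdr": float("nan"),
                "n_permutations": n_perm, "seed": seed}
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_perm):
        shuffled = permute_genotypes(panel, rng)
        counts.append(_family_calls(pair_scan_fn(shuffled), t))
    mean_n_perm = float(np.mean(counts))
    return {
        "t": t,
        "n_true": n_true,
        "mean_n_perm": mean_n_perm,
        "fdr": mean_n_perm / n_true,
        "n_permutations": n_perm,
        "seed": seed,
    }


def _family_calls(pair_pvalues: dict, t: float) -> int:
    arrays = [np.asarray(v, dtype=float) for v in pair_pvalues.values()]
    if not arrays:
        return 0
    stacked = np.vstack(arrays)
    with np.errstate(invalid="ignore"):
        hit = np.nanmin(stacked, axis=0) <= t
    return int(np.nansum(hit))
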