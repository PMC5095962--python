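"""Cross-phenotype association via a common-scaled-effect test.

Each admissible trait pair is tested per diet: both outcomes are
standardized (zero mean, unit variance) over the lines entering the
test, stacked into a single regression with one intercept per outcome
and a single common genotype effect, and fit by least squares under
working independence.  The variance of the common effect uses the
line-clustered sandwich estimator, so the 1-df Wald chi-square

    statistic = beta_hat^2 / Var_hat(beta_hat)

is valid whatever the within-line correlation between the outcomes.
This is the defining construction of scaled marginal models for
multiple continuous outcomes; a score-test variant is available via
``method="score"``.  Exact numerical agreement with any particular
external implementation of the scaled marginal model is not claimed.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .models import CrossAssocResult, GenotypePanel, TraitMatrix
from .io import filter_by_maf
from .scan import variance_explained

logger = logging.getLogger(__name__)


def scale_phenotypes(
    matrix: TraitMatrix, trait_pair: tuple[str, str], diet: str
) -> tuple[pd.Index, np.ndarray]:
    """Standardized lines x 2 outcome matrix for one trait pair and diet.

    Lines missing either trait are dropped; each remaining column is
    centered and divided by its (n-1) standard deviation.  Returns the
    included line index and the standardized array.
    """
    cols = []
    for trait in trait_pair:
        sub = matrix.df[(matrix.df["trait"] == trait) & (matrix.df["diet"] == diet)]
        cols.append(sub.set_index("line")["value"])
    wide = pd.concat(cols, axis=1, keys=trait_pair).dropna()
    if len(wide) < 10:
        raise ValueError(
            f"trait pair {trait_pair} on {diet}: needs >= 10 common lines, got {len(wide)}"
        )
    Y = wide.to_numpy(dtype=float)
    sd = Y.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance trait in pair {trait_pair} on {diet}")
    return wide.index, (Y - Y.mean(axis=0)) / sd


def smat_test(
    Y: np.ndarray, g: np.ndarray, marker_id: str = "", method: str = "wald"
) -> CrossAssocResult:
    """Common-scaled-effect test of genotype on K standardized outcomes.

    Stacks the K outcomes per line, fits per-outcome intercepts plus a
    single common genotype slope by OLS (working independence), and
    tests the slope with a line-clustered sandwich variance against the
    1-df chi-square.  ``method="score"`` replaces the Wald statistic
    with the robust score statistic evaluated under the null fit.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    g = np.asarray(g, dtype=float)
    n, K = Y.shape
    if g.shape != (n,):
        raise ValueError("g must have one entry per line")
    keep = ~np.isnan(g) & ~np.isnan(Y).any(axis=1)
    Y, g = Y[keep], g[keep]
    n = g.size
    result = CrossAssocResult(marker_id, trait_pair=("", ""), diet="", n_used=int(n * K))
    if n < 3 or np.ptp(g) == 0:
        result.skip_reason = "monomorphic-after-missing" if n else "no-observations"
        return result

    # stacked design: K intercept indicators + common genotype column
    ystack = Y.reshape(-1)                             # line-major: (i,k) -> i*K + k
    X = np.zeros((n * K, K + 1))
    for k in range(K):
        X[k::K, k] = 1.0
    X[:, K] = np.repeat(g, K)

    XtX = X.T @ X
    bread = np.linalg.inv(XtX)
    beta = bread @ (X.T @ ystack)

    if method == "wald":
        resid = ystack - X @ beta
        # per-line score sums X_i' e_i
        scores = (X * resid[:, None]).reshape(n, K, K + 1).sum(axis=1)
        meat = scores.T @ scores
        cov = bread @ meat @ bread
        var = float(cov[K, K])
        est = float(beta[K])
    elif method == "score":
        # robust score test under the null (intercepts-only) fit:
        # U = sum_i (g_i - gbar) * sum_k e0_ik,  Var(U) = sum_i u_i^2
        gc = g - g.mean()
        e0 = Y - Y.mean(axis=0)
        u_i = gc * e0.sum(axis=1)
        est = float(u_i.sum())
        var = float((u_i**2).sum())
    else:
        raise ValueError(f"unknown method {method!r}")

    if var <= 0 or not np.isfinite(var):
        result.skip_reason = "degenerate-variance"
        return result
    statistic = est * est / var
    result.beta_common = est if method == "wald" else float("nan")
    result.var_sandwich = var
    result.statistic = float(statistic)
    result.p_joint = float(stats.chi2.sf(statistic, df=1))
    return result


def valid_trait_pairs(normalizers: dict[str, str | None]) -> list[tuple[str, str]]:
    """Admissible unordered trait pairs.

    ``normalizers`` maps each trait name to the trait it was normalized
    by (or None).  A pair is excluded when the two traits share a
    normalizer, or when one trait is the other's normalizer — in either
    case the measurements are not independent.
    """
    traits = sorted(normalizers)
    pairs = []
    for a, b in combinations(traits, 2):
        na, nb = normalizers[a], normalizers[b]
        if na is not None and na == nb:
            continue
        if na == b or nb == a:
            continue
        pairs.append((a, b))
    return pairs


def scan_cross_phenotype(
    panel: GenotypePanel,
    matrix: TraitMatrix,
    trait_pair: tuple[str, str],
    diet: str,
    min_maf: float = 0.05,
    method: str = "wald",
) -> pd.DataFrame:
    """Cross-phenotype scan: one row per marker passing the MAF filter.

    Outcomes are re-standardized over the complete-case lines entering
    each marker's test, so the zero-mean/unit-variance property holds
    exactly per test even under missing genotypes.  The per-trait
    genotype-only R^2 values are computed alongside and the maximum is
    reported.
    """
    work = filter_by_maf(panel, min_maf)
    line_idx, Y_full = scale_phenotypes(matrix, trait_pair, diet)
    pos = {ln: i for i, ln in enumerate(panel.lines)}
    rows_in_panel = np.array([pos[ln] for ln in line_idx if ln in pos])
    kept_lines = [ln for ln in line_idx if ln in pos]
    Y_raw = Y_full[[i for i, ln in enumerate(line_idx) if ln in pos]]

    records = []
    for j, m in enumerate(work.markers):
        g = work.calls[rows_in_panel, j]
        keep = ~np.isnan(g)
        Yk = Y_raw[keep]
        # re-standardize over this marker's complete-case lines
        sd = Yk.std(axis=0, ddof=1) if len(Yk) > 1 else np.zeros(Y_raw.shape[1])
        if len(Yk) < 3 or (sd == 0).any():
            res = CrossAssocResult(m.id, trait_pair, diet, skip_reason="degenerate-outcomes")
        else:
            Yk = (Yk - Yk.mean(axis=0)) / sd
            res = smat_test(Yk, g[keep], marker_id=m.id, method=method)
            res.trait_pair = trait_pair
            res.diet = diet
            if res.skip_reason is None:
                r2s = [variance_explained(Yk[:, t], g[keep])[0] for t in range(Yk.shape[1])]
                res.max_r2 = float(max(r2s))
        records.append(
            {
                "chrom": m.chrom,
                "pos": m.pos,
                "marker": m.id,
                "diet": diet,
                "trait_pair": "|".join(trait_pair),
                "beta_common": res.beta_common,
                "var_sandwich": res.var_sandwich,
                "statistic": res.statistic,
                "p_joint": res.p_joint,
                "max_r2": res.max_r2,
                "n_used": res.n_used,
                "skip_reason": res.skip_reason or "",
            }
        )
    out = pd.DataFrame(
        records,
        columns=[
            "chrom", "pos", "marker", "diet", "trait_pair", "beta_common",
            "var_sandwich", "statistic", "p_joint", "max_r2", "n_used", "skip_reason",
        ],
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
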