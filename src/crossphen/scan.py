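"""Per-marker gene-by-diet association scan via ordinary least squares.

Model per marker:  y = b0 + b1*g + b2*d + b3*g*d,
with y the per-(line, diet) replicate-mean trait value, g the 0/1
homozygous genotype and d the diet code (AL = 0, DR = 1).  p_genotype
tests b1 = 0 and p_interaction tests b3 = 0, both two-sided t-tests on
n_used - 4 residual degrees of freedom.

Two code paths exist on purpose: :func:`fit_gxd_model` fits one marker
through statsmodels OLS, while :func:`scan_single_trait` evaluates the
same closed-form normal equations for all markers at once (the design
has only four columns, and for 0/1 genotype and diet every cross-product
reduces to a cell count, so the whole scan is a handful of matrix
products).  The two paths agree to floating-point accuracy and are
cross-checked in the test suite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import AssocResult, GenotypePanel, TraitMatrix
from .io import filter_by_maf

logger = logging.getLogger(__name__)

_SATURATED_TOL = 1e-12


def fit_gxd_model(y: np.ndarray, g: np.ndarray, d: np.ndarray, marker_id: str = "") -> AssocResult:
    """OLS fit of the 4-parameter genotype x diet model at one marker.

    ``y``, ``g``, ``d`` are observation-level arrays of equal length
    (one observation per line per diet); observations with missing
    genotype or phenotype are dropped (complete case).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    d = np.asarray(d, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g) | np.isnan(d))
    y, g, d = y[keep], g[keep], d[keep]
    n = y.size
    if n < 5:
        return AssocResult(marker_id, n_used=n, skip_reason="too-few-observations")
    if np.ptp(g) == 0:
        return AssocResult(marker_id, n_used=n, skip_reason="monomorphic-after-missing")
    X = np.column_stack([np.ones(n), g, d, g * d])
    if np.linalg.matrix_rank(X) < 4:
        return AssocResult(marker_id, n_used=n, skip_reason="rank-deficient-design")
    fit = sm.OLS(y, X).fit()
    b = fit.params
    se = fit.bse
    ssr = float(fit.ssr)
    saturated = ssr <= _SATURATED_TOL * max(1.0, float(y @ y))
    p_g = 0.0 if saturated else float(fit.pvalues[1])
    p_i = 0.0 if saturated else float(fit.pvalues[3])
    return AssocResult(
        marker_id=marker_id,
        intercept=float(b[0]),
        beta_genotype=float(b[1]),
        beta_diet=float(b[2]),
        beta_interaction=float(b[3]),
        se_intercept=float(se[0]),
        se_genotype=float(se[1]),
        se_diet=float(se[2]),
        se_interaction=float(se[3]),
        p_genotype=p_g,
        p_interaction=p_i,
        n_used=int(n),
        r2_genotype_only=variance_explained(y, g)[0],
        saturated=saturated,
    )


def variance_explained(y: np.ndarray, g: np.ndarray) -> tuple[float, bool]:
    """R^2 of the genotype-only regression y ~ intercept + g.

    Returns (r2, flagged); constant y yields r2 = 0 with a flag.  The
    value is an upper bound on the variance truly explained at loci
    selected for significance (winner's-curse / Beavis bias).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    sst = float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0
    if sst == 0.0:
        return 0.0, True
    sgg = float(np.sum((g - g.mean()) ** 2))
    if sgg == 0.0:
        return 0.0, True
    sgy = float(np.sum((g - g.mean()) * (y - y.mean())))
    return sgy * sgy / (sgg * sst), False


def scan_single_trait(
    panel: GenotypePanel,
    matrix: TraitMatrix,
    trait: str,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Genome scan of one trait: one row per marker passing the MAF filter.

    Output columns: chrom, pos, marker, trait, n_used, beta_* and se_*
    coefficients, p_genotype, p_interaction, r2, skip_reason.  Rows are
    ordered by (chrom, pos).  Per-marker degeneracies (monomorphic after
    missingness, an empty genotype-diet cell) are recorded in
    skip_reason, never raised.
    """
    work = filter_by_maf(panel, min_maf)
    meta = pd.DataFrame(
        {
            "chrom": [m.chrom for m in work.markers],
            "pos": [m.pos for m in work.markers],
            "marker": work.marker_ids(),
        }
    )
    if work.n_markers == 0:
        logger.warning("scan of %s: no markers pass MAF %.3f", trait, min_maf)
        return _finalize_scan(meta, trait, _empty_stats(0))
    y_al = matrix.trait_values(trait, "AL", work.lines)
    y_dr = matrix.trait_values(trait, "DR", work.lines)
    if np.isnan(y_al).all() or np.isnan(y_dr).all():
        raise ValueError(f"trait {trait!r} must be measured on both diets")
    stats_ = _batched_gxd(work.calls, y_al, y_dr)
    return _finalize_scan(meta, trait, stats_)


def _empty_stats(m: int) -> dict:
    nan = np.full(m, np.nan)
    return {
        "n_used": np.zeros(m, dtype=int),
        "intercept": nan.copy(), "beta_genotype": nan.copy(),
        "beta_diet": nan.copy(), "beta_interaction": nan.copy(),
        "se_intercept": nan.copy(), "se_genotype": nan.copy(),
        "se_diet": nan.copy(), "se_interaction": nan.copy(),
        "p_genotype": nan.copy(), "p_interaction": nan.copy(),
        "r2": nan.copy(), "skip_reason": np.array([""] * m, dtype=object),
    }


def _finalize_scan(meta: pd.DataFrame, trait: str, stats_: dict) -> pd.DataFrame:
    out = meta.copy()
    out["trait"] = trait
    for k, v in stats_.items():
        out[k] = v
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def _batched_gxd(calls: np.ndarray, y_al: np.ndarray, y_dr: np.ndarray) -> dict:
    """Closed-form OLS for all markers at once.

    Observations are the two diet rows per line.  For 0/1 genotype and
    diet, X'X per marker is built from the four genotype-by-diet cell
    counts and X'y from four masked sums, all obtained as matrix
    products; the 4x4 systems are then solved in a single batched call.
    """
    n_lines, M = calls.shape
    # observation-level stacking: AL block then DR block
    G = np.vstack([calls, calls])                      # (2n, M), NaN = missing genotype
    y = np.concatenate([y_al, y_dr])                   # NaN = missing phenotype
    d = np.concatenate([np.zeros(n_lines), np.ones(n_lines)])

    obs_ok = ~np.isnan(y)
    W = (~np.isnan(G)) & obs_ok[:, None]               # usable (obs, marker)
    G0 = np.where(W, np.nan_to_num(G), 0.0)
    Wf = W.astype(float)
    y0 = np.where(obs_ok, y, 0.0)

    n = Wf.sum(axis=0)
    Sg = G0.sum(axis=0)
    Sd = d @ Wf
    Sgd = d @ G0
    Sy = y0 @ Wf
    Sgy = y0 @ G0
    Sdy = (y0 * d) @ Wf
    Sgdy = (y0 * d) @ G0
    Syy = (y0 * y0) @ Wf

    # genotype-by-diet cell counts; all four must be occupied for rank 4
    n11 = Sgd
    n10 = Sg - Sgd
    n01 = Sd - Sgd
    n00 = n - Sg - Sd + Sgd
    ok = (n >= 5) & (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)

    out = _empty_stats(M)
    out["n_used"] = n.astype(int)
    skip = out["skip_reason"]
    mono = ((Sg == 0) | (Sg == n)) & (n >= 5)
    skip[n < 5] = "too-few-observations"
    skip[mono] = "monomorphic-after-missing"
    skip[(~ok) & (n >= 5) & ~mono] = "rank-deficient-design"

    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return out
    A = np.empty((idx.size, 4, 4))
    nn, sg, sd, sgd = n[idx], Sg[idx], Sd[idx], Sgd[idx]
    A[:, 0, 0] = nn
    A[:, 0, 1] = A[:, 1, 0] = sg
    A[:, 0, 2] = A[:, 2, 0] = sd
    A[:, 0, 3] = A[:, 3, 0] = sgd
    A[:, 1, 1] = sg
    A[:, 1, 2] = A[:, 2, 1] = sgd
    A[:, 1, 3] = A[:, 3, 1] = sgd
    A[:, 2, 2] = sd
    A[:, 2, 3] = A[:, 3, 2] = sgd
    A[:, 3, 3] = sgd
    b = np.stack([Sy[idx], Sgy[idx], Sdy[idx], Sgdy[idx]], axis=1)

    Ainv = np.linalg.inv(A)
    beta = np.einsum("mij,mj->mi", Ainv, b)
    ssr = Syy[idx] - np.einsum("mi,mi->m", beta, b)
    ssr = np.maximum(ssr, 0.0)
    df = nn - 4
    s2 = ssr / df
    saturated = ssr <= _SATURATED_TOL * np.maximum(1.0, Syy[idx])
    se = np.sqrt(np.maximum(s2[:, None] * np.diagonal(Ainv, axis1=1, axis2=2), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df[:, None])
    p[saturated] = 0.0

    names = ["intercept", "beta_genotype", "beta_diet", "beta_interaction"]
    for j, name in enumerate(names):
        out[name][idx] = beta[:, j]
        out["se_" + name.replace("beta_", "")][idx] = se[:, j]
    out["p_genotype"][idx] = p[:, 1]
    out["p_interaction"][idx] = p[:, 3]

    # genotype-only R^2 from the same masked sums
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = Sg[idx] - Sg[idx] ** 2 / nn
        sxy = Sgy[idx] - Sg[idx] * Sy[idx] / nn
        sst = Syy[idx] - Sy[idx] ** 2 / nn
        r2 = np.where((sxx > 0) & (sst > 0), sxy**2 / (sxx * sst), 0.0)
    out["r2"][idx] = np.clip(r2, 0.0, 1.0)
    return out
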