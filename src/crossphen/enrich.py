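"""Rank-based gene-set enrichment with gene-length bias adjustment.

Genes are scored by the single best (minimum) marker p-value among
their assigned markers, ranked ascending, and each candidate term is
tested by a binary-response regression of term membership on the
normalized gene rank with log gene length as a covariate: long genes
harbor more markers and therefore better extreme-value scores, so the
length term absorbs that bias instead of letting it masquerade as
enrichment.  The two-sided Wald p-value on the rank coefficient is the
term's enrichment p (negative coefficient = members concentrate at the
top); Benjamini-Hochberg correction is applied across all tested terms.
Terms need strictly more than ``min_members`` scored genes to be tested.

When the maximum-likelihood logistic fit fails (perfect separation —
e.g. a term's genes occupying an exact rank prefix — or non-convergence)
the term is refit with Firth's Jeffreys-prior penalized logistic
regression and flagged; the p-value then comes from the penalized
likelihood-ratio test, which stays calibrated where the Wald statistic
collapses under separation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .models import EnrichmentResult, GeneModel

logger = logging.getLogger(__name__)


def gene_level_scores(
    scan_results: pd.DataFrame,
    marker_to_genes: dict[str, set[str]],
    genes: list[GeneModel] | None = None,
    p_column: str = "p_genotype",
) -> pd.DataFrame:
    """Best-marker-per-gene scores, ranked ascending by p.

    Genes with no tested marker are absent (never imputed).  Ties in the
    minimum p are broken by (chrom, start, gene id) when gene models are
    supplied, else by gene id, so the ranking is deterministic.
    Returns a frame with columns gene, score, rank (1-based).
    """
    sub = scan_results[["marker", p_column]].dropna()
    best: dict[str, float] = {}
    for marker, p in zip(sub["marker"], sub[p_column]):
        for gene in marker_to_genes.get(marker, ()):
            if gene not in best or p < best[gene]:
                best[gene] = float(p)
    if not best:
        raise ValueError("no marker maps to any gene")
    meta = {g.id: (g.chrom, g.start) for g in genes} if genes else {}
    order = sorted(best, key=lambda g: (best[g], *meta.get(g, ("", 0)), g))
    return pd.DataFrame(
        {"gene": order, "score": [best[g] for g in order], "rank": np.arange(1, len(order) + 1)}
    )


def rank_enrichment(
    ranked_genes: pd.DataFrame,
    annotations: pd.DataFrame,
    gene_lengths: dict[str, int],
    min_members: int = 10,
    length_adjust: bool = True,
) -> pd.DataFrame:
    """Length-adjusted rank regression per term, BH-corrected.

    ``ranked_genes``: output of :func:`gene_level_scores`.
    ``annotations``: 2-column frame (gene, term).  ``gene_lengths`` maps
    gene id to bp length; genes lacking a length get the median.
    ``length_adjust=False`` drops the covariate (for comparison runs).
    Returns a frame (term, n, coefficient, p, q_bh, fallback) sorted by p.
    """
    n = len(ranked_genes)
    genes = ranked_genes["gene"].to_numpy()
    rank_norm = ranked_genes["rank"].to_numpy(dtype=float) / n
    lengths = np.array([gene_lengths.get(g, np.nan) for g in genes], dtype=float)
    if np.isnan(lengths).all():
        lengths = np.ones(n)
    med = np.nanmedian(lengths)
    lengths = np.where(np.isnan(lengths) | (lengths <= 0), med, lengths)
    log_len = np.log(lengths)

    members_by_term = annotations.groupby("term")["gene"].apply(set)
    gene_set = {g: i for i, g in enumerate(genes)}

    results: list[EnrichmentResult] = []
    for term, members in members_by_term.items():
        idx = [gene_set[g] for g in members if g in gene_set]
        if len(idx) <= min_members:
            continue
        y = np.zeros(n)
        y[idx] = 1.0
        cols = [np.ones(n), rank_norm]
        # a constant length column is collinear with the intercept
        if length_adjust and np.ptp(log_len) > 1e-12:
            cols.append(log_len)
        X = np.column_stack(cols)
        coef, p, fallback = _logit_rank_test(y, X)
        results.append(EnrichmentResult(str(term), len(idx), coef, p, fallback=fallback))

    if len(results) < 2:
        raise ValueError("fewer than 2 terms pass the membership filter")
    pvals = np.array([r.p for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q_bh = float(q)
    out = pd.DataFrame(
        {
            "term": [r.term for r in results],
            "n": [r.n_members_tested for r in results],
            "coefficient": [r.coefficient for r in results],
            "p": [r.p for r in results],
            "q_bh": [r.q_bh for r in results],
            "fallback": [r.fallback for r in results],
        }
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def _logit_rank_test(y: np.ndarray, X: np.ndarray) -> tuple[float, float, bool]:
    """Wald test on the rank coefficient (column 1); Firth PLRT on failure."""
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # non-convergence is expected under separation; the Firth
            # fallback below handles it
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if fit.mle_retvals.get("converged", False) and np.isfinite(fit.bse[1]) and fit.bse[1] < 50:
            return float(fit.params[1]), float(fit.pvalues[1]), False
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        pass
    beta, _, pll_full = _firth_logit(y, X)
    X0 = np.delete(X, 1, axis=1)
    _, _, pll_null = _firth_logit(y, X0)
    lr = max(2.0 * (pll_full - pll_null), 0.0)
    return float(beta[1]), float(stats.chi2.sf(lr, df=1)), True


def _firth_logit(
    y: np.ndarray, X: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    """Firth (Jeffreys-prior) penalized logistic regression.

    The penalized score U*(b) = X'(y - mu + h (1/2 - mu)) with h the
    leverages of the weighted design keeps estimates finite under
    separation.  Newton iterations with step halving; returns the
    coefficients, Fisher-information standard errors, and the maximized
    penalized log-likelihood (for likelihood-ratio tests).
    """
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_loglik(b: np.ndarray) -> float:
        eta = np.clip(X @ b, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        ll = float(y @ eta - np.logaddexp(0, eta).sum())
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    ll_old = penalized_loglik(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        Xw = X * w[:, None]
        info = X.T @ Xw
        info_inv = np.linalg.pinv(info)
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], info_inv, X * np.sqrt(w)[:, None])
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # step halving on the penalized likelihood
        factor = 1.0
        for _ in range(20):
            cand = beta + factor * step
            ll_new = penalized_loglik(cand)
            if ll_new >= ll_old - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        if np.max(np.abs(factor * step)) < tol:
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    info = X.T @ (X * w[:, None])
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se, penalized_loglik(beta)
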