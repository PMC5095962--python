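"""Single-trait gene-by-diet OLS scan and variance explained."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossphen import qc
from crossphen.models import GenotypePanel, Marker, TraitMatrix
from crossphen.scan import fit_gxd_model, scan_single_trait, variance_explained
from crossphen.simulate import PlantedEffect, SimConfig, simulate_panel, simulate_phenotypes


def ols_oracle(y, g, d):
    """Independent normal-equations + t-distribution fit of the GxD model."""
    X = np.column_stack([np.ones(len(y)), g, d, g * d])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - 4
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(s2 * XtX_inv))
    p = 2 * stats.t.sf(np.abs(beta / se), df)
    return beta, se, p


def random_instance(rng, n_lines):
    g = rng.integers(0, 2, n_lines).astype(float)
    while g.min() == g.max():
        g = rng.integers(0, 2, n_lines).astype(float)
    gg = np.concatenate([g, g])
    d = np.concatenate([np.zeros(n_lines), np.ones(n_lines)])
    y = rng.normal(size=2 * n_lines) + 0.5 * gg - 0.3 * d + 0.2 * gg * d
    return y, gg, d


def test_diet_only_signal():
    """y tracking diet exactly (plus jitter) loads only on beta_diet."""
    rng = np.random.default_rng(0)
    n = 30
    g = rng.integers(0, 2, n).astype(float)
    gg = np.concatenate([g, g])
    d = np.concatenate([np.zeros(n), np.ones(n)])
    y = d + rng.normal(0, 1e-9, 2 * n)
    r = fit_gxd_model(y, gg, d)
    assert r.beta_diet == pytest.approx(1.0, abs=1e-6)
    assert r.beta_genotype == pytest.approx(0.0, abs=1e-6)
    assert r.beta_interaction == pytest.approx(0.0, abs=1e-6)


def test_matches_normal_equations_oracle(rng):
    """statsmodels path and batched path both agree with the oracle."""
    for _ in range(100):
        n_lines = int(rng.integers(5, 21))  # <= 42 observations
        y, gg, d = random_instance(rng, n_lines)
        beta, se, p = ols_oracle(y, gg, d)
        r = fit_gxd_model(y, gg, d)
        got = [r.intercept, r.beta_genotype, r.beta_diet, r.beta_interaction]
        np.testing.assert_allclose(got, beta, atol=1e-8)
        np.testing.assert_allclose(
            [r.se_intercept, r.se_genotype, r.se_diet, r.se_interaction], se, atol=1e-8
        )
        np.testing.assert_allclose([r.p_genotype, r.p_interaction], p[[1, 3]], atol=1e-8)


def _as_matrix(y_al, y_dr, lines, trait="t"):
    rows = [(ln, "AL", trait, v) for ln, v in zip(lines, y_al)]
    rows += [(ln, "DR", trait, v) for ln, v in zip(lines, y_dr)]
    return TraitMatrix(pd.DataFrame(rows, columns=["line", "diet", "trait", "value"]))


def _panel_from_calls(calls):
    n, m = calls.shape
    markers = [Marker(f"m{j}", "c1", j + 1) for j in range(m)]
    return GenotypePanel([f"L{i}" for i in range(n)], markers, np.asarray(calls, float))


def test_batched_scan_equals_scalar_fit(rng):
    """The vectorized scan agrees with per-marker statsmodels fits, NaNs included."""
    n = 25
    calls = rng.choice([0.0, 1.0, np.nan], size=(n, 40), p=[0.45, 0.45, 0.1])
    calls[:3, :] = [[0.0], [1.0], [0.0]] * np.ones((3, 40))
    panel = _panel_from_calls(calls)
    lines = panel.lines
    y_al = rng.normal(size=n)
    y_dr = rng.normal(size=n)
    matrix = _as_matrix(y_al, y_dr, lines)
    res = scan_single_trait(panel, matrix, "t", min_maf=0.0)
    for _, row in res.iterrows():
        j = int(row["marker"][1:])
        gg = np.concatenate([calls[:, j], calls[:, j]])
        r = fit_gxd_model(np.concatenate([y_al, y_dr]), gg,
                          np.concatenate([np.zeros(n), np.ones(n)]))
        if r.skip_reason:
            assert row["skip_reason"] == r.skip_reason
            continue
        assert row["skip_reason"] == ""
        np.testing.assert_allclose(row["beta_genotype"], r.beta_genotype, atol=1e-10)
        np.testing.assert_allclose(row["p_genotype"], r.p_genotype, atol=1e-10)
        np.testing.assert_allclose(row["p_interaction"], r.p_interaction, atol=1e-10)
        np.testing.assert_allclose(row["r2"], r.r2_genotype_only, atol=1e-10)
        assert row["n_used"] == r.n_used


def test_allele_swap_invariance(rng):
    y, gg, d = random_instance(rng, 20)
    a = fit_gxd_model(y, gg, d)
    b = fit_gxd_model(y, 1 - gg, d)
    assert b.p_genotype == pytest.approx(a.p_genotype, abs=1e-10)
    assert b.p_interaction == pytest.approx(a.p_interaction, abs=1e-10)
    assert b.beta_genotype == pytest.approx(-a.beta_genotype, abs=1e-10)
    assert b.beta_interaction == pytest.approx(-a.beta_interaction, abs=1e-10)


def test_constant_shift_moves_only_intercept(rng):
    y, gg, d = random_instance(rng, 20)
    a = fit_gxd_model(y, gg, d)
    b = fit_gxd_model(y + 5.0, gg, d)
    assert b.intercept == pytest.approx(a.intercept + 5.0)
    for attr in ("beta_genotype", "beta_diet", "beta_interaction", "p_genotype"):
        assert getattr(b, attr) == pytest.approx(getattr(a, attr), abs=1e-10)


def test_skip_reasons():
    n = 10
    y = np.random.default_rng(0).normal(size=2 * n)
    d = np.concatenate([np.zeros(n), np.ones(n)])
    const = np.zeros(2 * n)
    assert fit_gxd_model(y, const, d).skip_reason == "monomorphic-after-missing"
    # genotype varying but one diet entirely absent
    g = np.concatenate([np.arange(n) % 2, np.arange(n) % 2]).astype(float)
    assert fit_gxd_model(y[:n], g[:n], np.zeros(n)).skip_reason == "rank-deficient-design"
    assert fit_gxd_model(y[:3], g[:3], d[:3]).skip_reason == "too-few-observations"


def test_maf_tier_nesting(small_study):
    _, panel, _, _, matrix = small_study
    loose = scan_single_trait(panel, matrix, "starvation", 0.05)
    tight = scan_single_trait(panel, matrix, "starvation", 0.25)
    assert set(tight["marker"]).issubset(set(loose["marker"]))


def test_empty_panel_after_filter(small_study):
    _, panel, _, _, matrix = small_study
    res = scan_single_trait(panel, matrix, "starvation", 0.5)
    assert res.columns.tolist()[:3] == ["chrom", "pos", "marker"]


def test_planted_marker_is_top_hit():
    """A strong planted effect attains the smallest p_genotype."""
    hits = 0
    for seed in range(10):
        cfg = SimConfig(
            n_lines=200, n_markers=2000, n_traits=1, trait_correlation=np.eye(1),
            line_variance=0.0, residual_variance=0.25, n_replicates_per_line=1,
            seed=500 + seed, planted_effects=[PlantedEffect(100, 0, 1.0)],
        )
        panel = simulate_panel(cfg)
        table, _ = simulate_phenotypes(panel, cfg)
        matrix = qc.strain_means(table)
        res = scan_single_trait(panel, matrix, cfg.traits()[0], 0.05)
        top = res.loc[res["p_genotype"].idxmin(), "marker"]
        hits += top == panel.markers[100].id
    assert hits >= 9


class TestVarianceExplained:
    def test_perfect_fit(self):
        g = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        assert variance_explained(g.copy(), g) == (1.0, False)

    def test_independent_large_n(self, rng):
        y = rng.normal(size=5000)
        g = rng.integers(0, 2, 5000).astype(float)
        r2, _ = variance_explained(y, g)
        assert r2 < 0.01

    def test_hand_computation_eight_obs(self):
        y = np.array([1.0, 2.0, 0.5, 3.0, 2.5, 1.5, 0.0, 2.0])
        g = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0])
        X = np.column_stack([np.ones(8), g])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        ssr = np.sum((y - X @ beta) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert variance_explained(y, g)[0] == pytest.approx(1 - ssr / sst, abs=1e-12)

    def test_constant_y_flagged(self):
        r2, flagged = variance_explained(np.ones(10), np.arange(10) % 2)
        assert r2 == 0.0 and flagged
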