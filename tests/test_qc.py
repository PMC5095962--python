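"""Replicate QC, strain means, diet ratios, broad-sense heritability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossphen import qc
from crossphen.models import PhenotypeTable
from crossphen.simulate import SimConfig, simulate_panel, simulate_phenotypes


def _table(rows):
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["line", "diet", "trait", "replicate", "value"])
    )


def _replicate_table(variance_by_line, trait="t", diet="AL"):
    """Lines with 2 replicates whose sample variance is as requested."""
    rows = []
    for i, v in enumerate(variance_by_line):
        half = np.sqrt(v / 2)  # var({m-h, m+h}) = 2 h^2
        rows += [
            (f"L{i}", diet, trait, 1, 10.0 - half),
            (f"L{i}", diet, trait, 2, 10.0 + half),
        ]
    return _table(rows)


class TestReplicateFilter:
    def test_inflated_line_removed(self):
        table = _replicate_table([1, 1, 1, 25])
        _, removed = qc.filter_replicate_outliers(table, fold=20)
        assert removed == [("L3", "t")]

    def test_boundary_is_strict(self):
        table = _replicate_table([1, 1, 1, 19])
        _, removed = qc.filter_replicate_outliers(table, fold=20)
        assert removed == []

    def test_homogeneous_untouched(self):
        table = _replicate_table([2, 2, 2, 2])
        filtered, removed = qc.filter_replicate_outliers(table)
        assert removed == [] and len(filtered) == len(table)

    def test_no_replicates_noop(self):
        table = _table([("L0", "AL", "t", 1, 1.0), ("L1", "AL", "t", 1, 2.0)])
        filtered, removed = qc.filter_replicate_outliers(table)
        assert removed == [] and len(filtered) == 2

    def test_removal_is_per_trait(self):
        """An outlier in one trait keeps the line's other traits."""
        a = _replicate_table([1, 1, 1, 500], trait="a")
        b = _replicate_table([1, 1, 1, 1], trait="b")
        table = _table(pd.concat([a.df, b.df]).values.tolist())
        filtered, removed = qc.filter_replicate_outliers(table)
        assert removed == [("L3", "a")]
        assert "L3" in set(filtered.df[filtered.df["trait"] == "b"]["line"])


class TestStrainMeans:
    def test_simple_means(self):
        table = _table(
            [("L0", "AL", "t", 1, 2.0), ("L0", "AL", "t", 2, 4.0), ("L1", "AL", "t", 1, 7.0)]
        )
        m = qc.strain_means(table)
        assert m.trait_values("t", "AL", ["L0", "L1"]).tolist() == [3.0, 7.0]

    def test_matches_groupby_oracle(self, rng):
        rows = []
        for line in range(15):
            for diet in ("AL", "DR"):
                for rep in range(int(rng.integers(1, 4))):
                    rows.append((f"L{line}", diet, "t", rep, float(rng.normal())))
        table = _table(rows)
        m = qc.strain_means(table)
        oracle = table.df.groupby(["line", "diet"])["value"].mean()
        for (line, diet), v in oracle.items():
            assert m.trait_values("t", diet, [line])[0] == pytest.approx(v)


class TestDietRatio:
    def test_simple_ratio(self):
        table = _table([("L0", "AL", "t", 1, 10.0), ("L0", "DR", "t", 1, 5.0)])
        m = qc.diet_ratio_trait(qc.strain_means(table), "t")
        assert m.trait_values("t_AL/DR", "AL", ["L0"])[0] == pytest.approx(2.0)

    def test_zero_dr_excluded(self):
        table = _table(
            [
                ("L0", "AL", "t", 1, 10.0), ("L0", "DR", "t", 1, 0.0),
                ("L1", "AL", "t", 1, 8.0), ("L1", "DR", "t", 1, 4.0),
            ]
        )
        m = qc.diet_ratio_trait(qc.strain_means(table), "t")
        vals = m.trait_values("t_AL/DR", "AL", ["L0", "L1"])
        assert np.isnan(vals[0]) and vals[1] == pytest.approx(2.0)


class TestHeritability:
    def test_hand_arithmetic_oracle(self):
        """Two lines A={0,2}, B={1,3}: the components by hand."""
        table = _table(
            [
                ("A", "AL", "t", 1, 0.0), ("A", "AL", "t", 2, 2.0),
                ("B", "AL", "t", 1, 1.0), ("B", "AL", "t", 2, 3.0),
            ]
        )
        r = qc.broad_sense_heritability(table, "t", "AL")
        assert r.sigma2_total == pytest.approx(np.var([0, 2, 1, 3], ddof=1))  # 5/3
        assert r.sigma2_intrastrain == pytest.approx(2.0)  # mean of var({0,2}), var({1,3})
        assert r.h2 == pytest.approx((5 / 3 - 2) / (5 / 3))
        assert r.flagged_negative

    def test_identical_replicates_give_h2_one(self):
        table = _table(
            [
                ("A", "AL", "t", 1, 1.0), ("A", "AL", "t", 2, 1.0),
                ("B", "AL", "t", 1, 5.0), ("B", "AL", "t", 2, 5.0),
            ]
        )
        r = qc.broad_sense_heritability(table, "t", "AL")
        assert r.sigma2_intrastrain == 0.0 and r.h2 == 1.0

    def test_precondition_error_names_trait(self):
        table = _table([("A", "AL", "t", 1, 1.0), ("B", "AL", "t", 1, 2.0)])
        with pytest.raises(ValueError, match="'t'"):
            qc.broad_sense_heritability(table, "t", "AL")

    def test_only_replicated_lines_enter(self):
        """A single-replicate line must not perturb either component."""
        base = [
            ("A", "AL", "t", 1, 0.0), ("A", "AL", "t", 2, 2.0),
            ("B", "AL", "t", 1, 1.0), ("B", "AL", "t", 2, 3.0),
        ]
        with_extra = base + [("C", "AL", "t", 1, 100.0)]
        r0 = qc.broad_sense_heritability(_table(base), "t", "AL")
        r1 = qc.broad_sense_heritability(_table(with_extra), "t", "AL")
        assert r1.h2 == pytest.approx(r0.h2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=50).map(lambda v: round(v, 3)),
        b=st.floats(min_value=-100, max_value=100).map(lambda v: round(v, 3)),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_affine_invariance(self, a, b, sign):
        """H2 is unchanged by y -> a*y + b for a != 0."""
        rng = np.random.default_rng(99)
        rows = []
        for i in range(12):
            mu = rng.normal(0, 2)
            for rep in (1, 2, 3):
                rows.append((f"L{i}", "AL", "t", rep, mu + rng.normal()))
        table = _table(rows)
        scaled = _table([(l, d, t, r, sign * a * v + b) for l, d, t, r, v in rows])
        r0 = qc.broad_sense_heritability(table, "t", "AL")
        r1 = qc.broad_sense_heritability(scaled, "t", "AL")
        assert r1.h2 == pytest.approx(r0.h2, rel=1e-9)


def test_ratio_trait_heritable_in_low_noise_limit():
    """As replicate noise vanishes, all AL/DR ratio variance is genetic.

    (With a shared additive line effect the ratio's between-line signal
    is second-order in the diet effect, so the ratio's H2 need not match
    the source trait's H2 in general; the noise-free limit is the clean
    invariant.)
    """
    cfg = SimConfig(
        n_lines=60, n_markers=1, n_traits=1, trait_correlation=np.eye(1),
        line_variance=1.0, residual_variance=1e-4, diet_effect=2.0,
        n_replicates_per_line=3, intercept=10.0, seed=21,
    )
    panel = simulate_panel(cfg)
    table, _ = simulate_phenotypes(panel, cfg)
    wide = table.df.pivot_table(
        index=["line", "replicate"], columns="diet", values="value"
    ).dropna()
    ratio_rows = [
        (line, "AL", "ratio", rep, row["AL"] / row["DR"])
        for (line, rep), row in wide.iterrows()
    ]
    h_ratio = qc.broad_sense_heritability(_table(ratio_rows), "ratio", "AL").h2
    assert h_ratio > 0.95
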