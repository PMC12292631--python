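import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kdscreen import (
    FidelityReport,
    fidelity_report,
    information_gain,
    mmd,
    pcd,
    rank_to_stars,
    shannon_entropy,
)
from conftest import make_table


class TestMMD:
    def test_identical_samples_give_zero(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        assert mmd(X, X) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(40, 3)), rng.normal(2, 1, size=(60, 3))
        assert mmd(X, Y) == pytest.approx(mmd(Y, X))

    def test_separated_samples_exceed_null(self):
        """N(0,1) vs N(5,1) separates above an independent null resample,
        across 10 seeds."""
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rng.normal(0, 1, (200, 2))
            Y = rng.normal(5, 1, (200, 2))
            Xp = rng.normal(0, 1, (200, 2))
            assert mmd(X, Y) > mmd(X, Xp)

    def test_feature_mismatch_and_degenerate_bandwidth(self):
        with pytest.raises(ValueError, match="mismatch"):
            mmd(np.zeros((3, 2)), np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="floored"):
            v = mmd(np.zeros((5, 2)), np.zeros((5, 2)))
        assert v == 0.0


class TestPCD:
    def test_identical_and_symmetry(self):
        X = np.random.default_rng(2).normal(size=(100, 5))
        assert pcd(X, X) == 0.0

    def test_negated_column_closed_form(self):
        """Negating one column of a 2-feature sample flips both off-diagonal
        correlations: PCD = 2 * sqrt(2) * |r| exactly."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        X = np.column_stack([x, 0.8 * x + 0.6 * rng.normal(size=500)])
        Y = X.copy()
        Y[:, 1] *= -1
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert pcd(X, Y) == pytest.approx(2 * np.sqrt(2) * abs(r))

    def test_independent_samples_converge_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5000, 4))
        Y = rng.normal(size=(5000, 4))
        assert pcd(X, Y) < 0.2

    def test_constant_column_convention(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        Y = X.copy()
        Y[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            v = pcd(X, Y)
        assert np.isfinite(v)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError, match="two features"):
            pcd(np.zeros((10, 1)), np.zeros((10, 1)))


class TestEntropy:
    def test_reference_values(self):
        assert shannon_entropy(np.full(100, 3.3)) == 0.0
        assert shannon_entropy(np.r_[np.zeros(50), np.ones(50)], "categorical") == 1.0
        uniform64 = np.repeat(np.arange(64, dtype=float), 100)
        assert shannon_entropy(uniform64, 64) == pytest.approx(6.0)

    def test_broader_support_does_not_decrease_entropy(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=500)
        widened = np.r_[base, base.max() + 1 + rng.random(200) * 3]
        # same binning range covering both samples: bin the pooled range
        lo, hi = widened.min(), widened.max()
        edges = np.linspace(lo, hi, 65)

        def h(v):
            c = np.histogram(v, bins=edges)[0]
            p = c[c > 0] / c.sum()
            return -(p * np.log2(p)).sum()

        assert h(widened) >= h(base) - 1e-12


class TestInformationGain:
    def test_perfectly_separating_feature_attains_label_entropy(self):
        labels = np.r_[np.ones(500, int), np.zeros(500, int)]
        values = labels.astype(float)
        assert information_gain(values, labels, "categorical") == pytest.approx(1.0)
        assert information_gain(values, labels, 64) == pytest.approx(1.0)

    def test_independent_feature_has_negligible_gain(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 10_000)
        values = rng.normal(size=10_000)
        assert information_gain(values, labels, 64) < 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            information_gain(np.arange(5.0), np.ones(5, int))

    @given(st.integers(0, 500))
    def test_invariant_under_monotone_transform_with_quantile_bins(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=300)
        labels = (rng.random(300) < 0.3).astype(int)
        if labels.sum() in (0, 300):
            return
        a = information_gain(values, labels, "quantile")
        b = information_gain(np.exp(values), labels, "quantile")
        assert a == pytest.approx(b, abs=1e-12)


class TestReportAndStars:
    def test_report_on_identical_tables_is_null(self, tiny_schema):
        t = make_table(tiny_schema, 120, 0.3, seed=1)
        rep = fidelity_report(t, t, backend="kde")
        assert rep.mmd == 0.0 and rep.pcd == 0.0
        for f in rep.per_feature:
            assert f.entropy_real == f.entropy_aug
            assert f.ig_real == f.ig_aug

    def test_report_json_round_trip(self, tiny_schema, tmp_path):
        a = make_table(tiny_schema, 100, 0.3, seed=2)
        b = make_table(tiny_schema, 150, 0.3, seed=3)
        rep = fidelity_report(a, b, backend="gaussian_copula")
        rep.to_json(tmp_path / "rep.json")
        back = FidelityReport.from_dict(
            json.loads((tmp_path / "rep.json").read_text())
        )
        assert back == rep

    def test_star_rankings(self):
        assert rank_to_stars({"kde": 0.1, "ctgan": 0.2, "ganblr": 0.3}) == {
            "kde": 5,
            "ctgan": 3,
            "ganblr": 1,
        }
        assert rank_to_stars({"kde": 0.3}, higher_is_better=True) == {"kde": 5}
        tied = rank_to_stars({"a": 0.1, "b": 0.1, "c": 0.4})
        assert tied["a"] == tied["b"] == 5 and tied["c"] == 1
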