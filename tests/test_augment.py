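import numpy as np
import pytest
from hypothesis import given, strategies as st

from kdscreen import (
    BackendUnavailableError,
    CohortTable,
    GeneratorBackendConfig,
    augmentation_count,
    balance_cohort,
    fit_backend,
    sample_synthetic,
)
from conftest import make_table


def minority_table(schema, n, seed=0):
    t = make_table(schema, n, 1.0, seed=seed)
    t.labels[:] = 1
    return t


class TestAugmentationCount:
    def test_published_balancing_row(self):
        """913 positives + 52,454 retained negatives at 1:24 (ceiling) need
        1,273 synthetic rows for a final minority of 2,186."""
        plan = augmentation_count(52_454, 913, 24, "ceil")
        assert plan.n_aug == 1273
        assert plan.n_minor_final == 2186

    def test_no_deficit_yields_zero(self):
        assert augmentation_count(2400, 100, 24).n_aug == 0

    @given(
        n_major=st.integers(0, 10_000),
        n_minor=st.integers(0, 2_000),
        rounding=st.sampled_from(["ceil", "floor", "nearest"]),
        r=st.integers(1, 60),
    )
    def test_final_ratio_within_one_of_target(self, n_major, n_minor, rounding, r):
        plan = augmentation_count(n_major, n_minor, r, rounding)
        assert plan.n_aug >= 0
        # rounding keeps the realized ratio within one of the target once the
        # majority is large enough for the integer rounding to be second-order
        if plan.n_aug > 0 and n_major >= r * r:
            ratio = n_major / plan.n_minor_final
            assert r - 1 <= ratio <= r + 1


class TestKDEBackend:
    def test_determinism(self, tiny_schema):
        m = minority_table(tiny_schema, 40)
        cfg = GeneratorBackendConfig(backend="kde", seed=5)
        a = sample_synthetic(fit_backend(m, cfg), 20, seed=5)
        b = sample_synthetic(fit_backend(m, cfg), 20, seed=5)
        np.testing.assert_array_equal(a.rows, b.rows)

    def test_small_bandwidth_concentrates_on_training_points(self, tiny_schema):
        m = minority_table(tiny_schema, 5)
        gen = fit_backend(m, GeneratorBackendConfig(backend="kde"))
        gen.bandwidth = gen.bandwidth * 1e-9
        batch = sample_synthetic(gen, 200, seed=0)
        # continuous coordinate collapses onto a training point
        d_cont = np.abs(
            batch.rows[:, 0][:, None] - m.values[:, 0][None, :]
        ).min(axis=1)
        assert d_cont.max() < 1e-6
        # count coordinate collapses onto a training count after rounding
        assert set(batch.rows[:, 1]) <= set(m.values[:, 1])

    def test_samples_stay_within_kernel_support(self, tiny_schema):
        m = minority_table(tiny_schema, 60, seed=2)
        gen = fit_backend(m, GeneratorBackendConfig(backend="kde"))
        batch = sample_synthetic(gen, 300, seed=1)
        # every smoothed coordinate within 6 bandwidths of some training row
        for j, col in enumerate(gen._smooth_idx):
            d = np.abs(
                batch.rows[:, col][:, None] - m.values[:, col][None, :]
            ).min(axis=1)
            assert (d <= 6 * gen.bandwidth[j] + 0.5).all()

    def test_categorical_snapping_and_count_integrality(self, tiny_schema):
        m = minority_table(tiny_schema, 30, seed=3)
        gen = fit_backend(m, GeneratorBackendConfig(backend="kde"))
        batch = sample_synthetic(gen, 500, seed=2)
        assert set(batch.rows[:, 2]) <= set(m.values[:, 2])
        counts = batch.rows[:, 1]
        assert (counts >= 0).all() and np.array_equal(counts, np.rint(counts))

    def test_statistical_sanity_of_sample_means(self, tiny_schema):
        """Synthetic feature means track the fitting data within 4 SE
        (seed-averaged over 5 seeds at 10x oversampling)."""
        m = minority_table(tiny_schema, 200, seed=4)
        gen = fit_backend(m, GeneratorBackendConfig(backend="kde"))
        n_synth = 10 * m.n_rows
        devs = []
        for s in range(5):
            batch = sample_synthetic(gen, n_synth, seed=100 + s)
            se = m.values.std(axis=0) / np.sqrt(n_synth)
            devs.append(np.abs(batch.rows.mean(axis=0) - m.values.mean(axis=0)) / se)
        assert np.mean(devs, axis=0).max() < 4.0

    def test_empty_minority_rejected(self, tiny_schema):
        empty = CohortTable(
            schema=tiny_schema,
            values=np.empty((0, 3)),
            labels=np.empty(0, dtype=int),
        )
        with pytest.raises(ValueError, match="empty"):
            fit_backend(empty, GeneratorBackendConfig(backend="kde"))


class TestCopulaBackend:
    def test_determinism_and_support(self, tiny_schema):
        m = minority_table(tiny_schema, 80, seed=6)
        cfg = GeneratorBackendConfig(backend="gaussian_copula", seed=1)
        a = sample_synthetic(fit_backend(m, cfg), 100, seed=1)
        b = sample_synthetic(fit_backend(m, cfg), 100, seed=1)
        np.testing.assert_array_equal(a.rows, b.rows)
        assert set(a.rows[:, 2]) <= set(m.values[:, 2])
        # inverse-empirical-CDF sampling stays inside the observed range
        assert a.rows[:, 0].min() >= m.values[:, 0].min() - 1e-9
        assert a.rows[:, 0].max() <= m.values[:, 0].max() + 1e-9

    def test_preserves_strong_correlation(self, tiny_schema):
        rng = np.random.default_rng(7)
        x = rng.normal(size=400)
        values = np.column_stack([x, np.rint(np.abs(4 + 2 * x + rng.normal(0, 0.5, 400))), rng.integers(0, 2, 400)])
        m = CohortTable(schema=tiny_schema, values=values, labels=np.ones(400, int))
        gen = fit_backend(m, GeneratorBackendConfig(backend="gaussian_copula"))
        batch = sample_synthetic(gen, 2000, seed=3)
        r_real = np.corrcoef(values[:, 0], values[:, 1])[0, 1]
        r_syn = np.corrcoef(batch.rows[:, 0], batch.rows[:, 1])[0, 1]
        assert abs(r_real - r_syn) < 0.15


def test_external_backends_raise_capability_error(tiny_schema):
    m = minority_table(tiny_schema, 10)
    for backend in ("ctgan", "ganblr"):
        with pytest.raises(BackendUnavailableError, match=backend):
            fit_backend(m, GeneratorBackendConfig(backend=backend))


class TestBalanceCohort:
    def test_balances_to_target_and_flags_synthetic(self, tiny_schema):
        table = make_table(tiny_schema, 600, 0.03, seed=8)
        balanced, plan = balance_cohort(table, 10.0, GeneratorBackendConfig(seed=2))
        assert balanced.n_neg == table.n_neg
        assert balanced.n_pos == int(np.ceil(table.n_neg / 10.0))
        synth_mask = balanced.provenance == "synthetic"
        assert synth_mask.sum() == plan.n_aug
        assert (balanced.labels[synth_mask] == 1).all()
        # real rows pass through unmodified, in order
        np.testing.assert_array_equal(
            balanced.values[: table.n_rows], table.values
        )

    def test_already_balanced_is_identity(self, tiny_schema):
        table = make_table(tiny_schema, 100, 0.4, seed=9)
        balanced, plan = balance_cohort(table, 24.0, GeneratorBackendConfig())
        assert plan.n_aug == 0
        assert balanced is table
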