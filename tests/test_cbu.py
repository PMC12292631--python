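import numpy as np
import pytest
from sklearn.cluster import KMeans

from kdscreen import (
    ClusterAssignment,
    ClusteringConfig,
    CohortTable,
    FilterPolicy,
    assign_clusters,
    filter_clusters,
    random_undersample,
    summarize_clusters,
)
from conftest import make_table


def _table(values, labels, schema):
    return CohortTable(schema=schema, values=values, labels=labels)


def blob_table(tiny_schema, centers, n_per, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    parts, truth = [], []
    for i, c in enumerate(centers):
        parts.append(rng.normal(0, noise, (n_per, 3)) + np.asarray(c))
        truth.extend([i] * n_per)
    values = np.vstack(parts)
    labels = np.zeros(values.shape[0], dtype=int)
    labels[0] = 1  # keep both classes representable
    return _table(values, labels, tiny_schema), np.array(truth)


def test_single_cluster_centroid_is_column_mean(tiny_table):
    a = assign_clusters(tiny_table, ClusteringConfig(k=1, seed=0))
    assert set(a.labels_by_row) == {0}
    np.testing.assert_allclose(a.centroids[0], tiny_table.values.mean(axis=0))


@pytest.mark.parametrize("metric", ["euclidean", "manhattan", "cosine"])
def test_separated_blobs_are_recovered(tiny_schema, metric):
    """Two blobs at +/-10 with unit noise: assignment purity is 100% against
    the generating blob (brute-force nearest-center oracle)."""
    table, truth = blob_table(tiny_schema, [(-10, -10, -10), (10, 10, 10)], 100)
    a = assign_clusters(table, ClusteringConfig(k=2, metric=metric, seed=3))
    found = a.labels_by_row
    purity = max(
        (found == truth).mean(), (found == 1 - truth).mean()
    )
    assert purity == 1.0


def test_euclidean_partition_matches_sklearn_on_blobs(tiny_schema):
    table, truth = blob_table(
        tiny_schema, [(-8, 0, 0), (0, 8, 0), (8, 0, 8)], 80, seed=5
    )
    ours = assign_clusters(table, ClusteringConfig(k=3, seed=1)).labels_by_row
    ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(table.values)
    # same partition up to label permutation
    from itertools import permutations

    agree = max(
        (np.array([p[c] for c in ours]) == ref).mean()
        for p in permutations(range(3))
    )
    assert agree == 1.0


def test_assignment_is_deterministic(tiny_table):
    cfg = ClusteringConfig(k=4, seed=9)
    a = assign_clusters(tiny_table, cfg)
    b = assign_clusters(tiny_table, cfg)
    np.testing.assert_array_equal(a.labels_by_row, b.labels_by_row)
    np.testing.assert_array_equal(a.centroids, b.centroids)


def test_too_few_rows_and_cosine_zero_vector_errors(tiny_schema):
    small = make_table(tiny_schema, 3, 0.5, seed=0)
    with pytest.raises(ValueError, match="k=5"):
        assign_clusters(small, ClusteringConfig(k=5))
    zeroed = make_table(tiny_schema, 10, 0.5, seed=0)
    zeroed.values[4] = 0.0
    with pytest.raises(ValueError, match="row 4"):
        assign_clusters(zeroed, ClusteringConfig(k=2, metric="cosine"))


def test_summaries_conserve_counts(tiny_table):
    a = assign_clusters(tiny_table, ClusteringConfig(k=5, seed=2))
    summaries = summarize_clusters(a, tiny_table.labels)
    assert sum(s.n_pos for s in summaries) == tiny_table.n_pos
    assert sum(s.n_neg for s in summaries) == tiny_table.n_neg
    single = _fake_assignment(np.zeros(10, dtype=int), k=1)
    s = summarize_clusters(single, np.r_[np.ones(3, int), np.zeros(7, int)])
    assert (s[0].n_pos, s[0].n_neg) == (3, 7) and s[0].neg_per_pos == 7 / 3


def _fake_assignment(labels_by_row, k):
    return ClusterAssignment(
        config=ClusteringConfig(k=k),
        labels_by_row=np.asarray(labels_by_row),
        centroids=np.zeros((k, 3)),
        n_iter_run=0,
    )


def test_filter_toy_example(tiny_schema):
    """Clusters A(0/50), B(1/300), C(2/100): keep C whole, keep B's positive,
    drop A entirely -> 3 positives, 100 negatives."""
    labels = np.r_[
        np.zeros(50, int),                      # A: pure negative
        np.ones(1, int), np.zeros(300, int),    # B: 1:300
        np.ones(2, int), np.zeros(100, int),    # C: 1:50
    ]
    assign = np.r_[
        np.zeros(50, int), np.ones(301, int), np.full(102, 2)
    ]
    rng = np.random.default_rng(0)
    table = _table(rng.normal(size=(453, 3)), labels, tiny_schema)
    out = filter_clusters(table, _fake_assignment(assign, 3))
    assert (out.n_pos, out.n_neg) == (3, 100)
    # literal whole-cluster policy drops B's positive too
    literal = FilterPolicy(retain_positives_from_dropped=False)
    out2 = filter_clusters(table, _fake_assignment(assign, 3), literal)
    assert (out2.n_pos, out2.n_neg) == (2, 100)


def test_permissive_policy_is_identity(tiny_table):
    a = assign_clusters(tiny_table, ClusteringConfig(k=3, seed=1))
    policy = FilterPolicy(max_neg_per_pos=np.inf, drop_pure_negative=False)
    out = filter_clusters(tiny_table, a, policy)
    np.testing.assert_array_equal(out.values, tiny_table.values)


@pytest.mark.parametrize("seed", range(4))
def test_filter_never_loses_positives_or_gains_negatives(tiny_schema, seed):
    table = make_table(tiny_schema, 150, 0.1, seed=seed)
    a = assign_clusters(table, ClusteringConfig(k=4, seed=seed))
    out = filter_clusters(table, a, FilterPolicy(max_neg_per_pos=5.0))
    assert out.n_pos == table.n_pos
    assert out.n_neg <= table.n_neg


def test_random_undersample_hits_target_and_keeps_positives(tiny_schema):
    table = make_table(tiny_schema, 300, 0.1, seed=1)
    out = random_undersample(table, 2.0, seed=0)
    assert out.n_pos == table.n_pos
    assert out.n_neg == int(2.0 * table.n_pos)
    untouched = random_undersample(table, 1e9, seed=0)
    assert untouched.n_rows == table.n_rows
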