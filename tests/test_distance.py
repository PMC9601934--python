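"""Component metrics, geometric variability and the joint robust metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dynagower import (
    DegenerateSourceError,
    DegenerateVariableError,
    SquaredDistanceMatrix,
    cityblock_gower_matrix,
    distance_series,
    geometric_variability,
    hamming_matrix,
    jaccard_matrix,
    joint_metric_at_time,
    mahalanobis_matrix,
    normalize_unit_gv,
    read_panel,
    robust_covariance,
    write_panel,
)
from oracles import (
    cityblock_gower_bruteforce,
    gv_bruteforce,
    hamming_bruteforce,
    jaccard_bruteforce,
    mahalanobis_bruteforce,
    sqeuclidean_bruteforce,
)

SETTINGS = settings(deadline=None, derandomize=True, max_examples=40)


# ---------------------------------------------------------------- gv ----

@pytest.mark.parametrize(
    "matrix, expected",
    [
        ([[0.0, 4.0], [4.0, 0.0]], 1.0),
        (np.zeros((5, 5)), 0.0),
        (2.0 * (1 - np.eye(3)), 2.0 / 3.0),
    ],
)
def test_geometric_variability_closed_forms(matrix, expected):
    assert geometric_variability(np.asarray(matrix)) == pytest.approx(expected, abs=1e-14)


@SETTINGS
@given(arrays(float, (6, 6), elements=st.floats(0, 50)))
def test_gv_is_linear(a):
    d_a = np.triu(a, 1) + np.triu(a, 1).T
    d_b = 2.0 * d_a[::-1, ::-1]
    lhs = geometric_variability(d_a + d_b)
    rhs = geometric_variability(d_a) + geometric_variability(d_b)
    assert abs(lhs - rhs) < 1e-12 * max(1.0, abs(rhs))
    assert abs(geometric_variability(d_a) - gv_bruteforce(d_a)) < 1e-12


def test_normalize_unit_gv_rescales_and_is_idempotent():
    d = SquaredDistanceMatrix(("a", "b", "c"), 2.0 * (1 - np.eye(3)))
    assert d.gv == pytest.approx(2.0 / 3.0)
    normalized = normalize_unit_gv(d)
    np.testing.assert_allclose(normalized.values, d.values * 1.5, atol=1e-14)
    assert normalized.gv == pytest.approx(1.0, abs=1e-10)
    again = normalize_unit_gv(normalized)
    assert np.abs(again.values - normalized.values).max() < 1e-12


def test_normalize_scale_equivariance():
    rng = np.random.default_rng(3)
    raw = rng.random((5, 5))
    d = np.triu(raw, 1) + np.triu(raw, 1).T
    base = normalize_unit_gv(SquaredDistanceMatrix(tuple("abcde"), d))
    for c in (0.1, 7.0, 1e6):
        scaled = normalize_unit_gv(SquaredDistanceMatrix(tuple("abcde"), c * d))
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-9)


def test_normalize_zero_matrix_is_degenerate():
    d = SquaredDistanceMatrix(("a", "b"), np.zeros((2, 2)))
    with pytest.raises(DegenerateSourceError):
        normalize_unit_gv(d, source="health")


# ------------------------------------------------------- robust scatter --

def test_robust_covariance_consistent_on_clean_normal():
    rng = np.random.default_rng(42)
    X = rng.standard_normal((2000, 2))
    scatter, location, method = robust_covariance(X, seed=0)
    assert method == "mcd"
    assert np.abs(scatter - np.eye(2)).max() < 0.15
    assert np.abs(location).max() < 0.15


def test_robust_covariance_resists_gross_outliers():
    rng = np.random.default_rng(1)
    inliers = rng.standard_normal((20, 2))
    X = np.vstack([inliers, np.full((5, 2), 100.0)])
    _, location, _ = robust_covariance(X, seed=0)
    assert np.linalg.norm(location) < 1.0
    assert np.linalg.norm(X.mean(axis=0)) > 10.0  # classical mean is dragged


def test_robust_covariance_rejects_constant_column():
    X = np.column_stack([np.arange(10.0), np.ones(10)])
    with pytest.raises(DegenerateVariableError, match="x2"):
        robust_covariance(X, names=["x1", "x2"])


def test_robust_covariance_shrinkage_fallback_for_tiny_n():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((5, 4))  # n < q + 2
    scatter, _, method = robust_covariance(X)
    assert method == "shrinkage"
    np.linalg.cholesky(scatter)  # positive definite


# ----------------------------------------------------------- components --

def test_mahalanobis_closed_forms():
    d = mahalanobis_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]), np.eye(2))
    assert d.values[0, 1] == pytest.approx(25.0, abs=1e-12)
    d = mahalanobis_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]), np.eye(2))
    assert d.values[0, 1] == 0.0
    d = mahalanobis_matrix(np.array([[0.0, 0.0], [2.0, 0.0]]), np.diag([4.0, 1.0]))
    assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_mahalanobis_singular_scatter_raises():
    with pytest.raises(np.linalg.LinAlgError):
        mahalanobis_matrix(np.eye(3), np.ones((3, 3)))


@SETTINGS
@given(arrays(float, (8, 3), elements=st.floats(-20, 20)))
def test_mahalanobis_identity_equals_sqeuclidean(X):
    d = mahalanobis_matrix(X, np.eye(3))
    assert np.abs(d.values - sqeuclidean_bruteforce(X)).max() < 1e-10


@SETTINGS
@given(st.integers(0, 10_000))
def test_mahalanobis_matches_bruteforce_with_random_scatter(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(7, 3))
    A = rng.normal(size=(3, 5))
    scatter = A @ A.T + 0.5 * np.eye(3)
    d = mahalanobis_matrix(X, scatter)
    assert np.abs(d.values - mahalanobis_bruteforce(X, scatter)).max() < 1e-10


def test_cityblock_gower_closed_forms():
    d = cityblock_gower_matrix(np.array([[0.0], [5.0], [10.0]]))
    assert d.values[0, 2] == pytest.approx(1.0)
    assert d.values[0, 1] == pytest.approx(0.5)
    assert d.values[1, 1] == 0.0


def test_cityblock_gower_zero_range_rejected():
    with pytest.raises(DegenerateVariableError):
        cityblock_gower_matrix(np.ones((4, 2)))


@SETTINGS
@given(st.integers(0, 10_000))
def test_cityblock_gower_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(5, 3))
    d = cityblock_gower_matrix(X)
    assert np.abs(d.values - cityblock_gower_bruteforce(X)).max() < 1e-12
    assert d.values.max() <= 1.0 + 1e-12


def test_jaccard_closed_forms():
    d = jaccard_matrix(np.array([[1, 1, 0], [1, 0, 0]]))
    assert d.values[0, 1] == pytest.approx(0.5)
    d = jaccard_matrix(np.ones((2, 3)))
    assert d.values[0, 1] == 0.0
    d = jaccard_matrix(np.zeros((2, 3)))  # empty denominator convention
    assert d.values[0, 1] == 0.0


def test_hamming_closed_forms():
    d = hamming_matrix(np.array([["a", "b"], ["a", "c"]], dtype=object))
    assert d.values[0, 1] == pytest.approx(0.5)
    d = hamming_matrix(np.array([["x", "y", "z"], ["x", "y", "z"]], dtype=object))
    assert d.values[0, 1] == 0.0
    d = hamming_matrix(np.array([["a", "b", "c"], ["x", "y", "z"]], dtype=object))
    assert d.values[0, 1] == pytest.approx(1.0)


@SETTINGS
@given(
    st.integers(2, 20),
    st.integers(1, 10),
    st.integers(0, 10_000),
)
def test_binary_categorical_components_match_bruteforce(n, q, seed):
    rng = np.random.default_rng(seed)
    B = rng.integers(0, 2, size=(n, q))
    dj = jaccard_matrix(B)
    assert np.abs(dj.values - jaccard_bruteforce(B)).max() < 1e-12
    C = rng.choice(list("abcd"), size=(n, q)).astype(object)
    dh = hamming_matrix(C)
    assert np.abs(dh.values - hamming_bruteforce(C)).max() < 1e-12
    for d in (dj, dh):
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert d.values.min() >= 0 and d.values.max() <= 1 + 1e-12


# ---------------------------------------------------------- joint metric --

def test_joint_metric_single_group_is_normalized_component(mixed_panel):
    t = mixed_panel.times[0]
    joint, raw, norm = joint_metric_at_time(mixed_panel, t, grouping="by_source")
    clinical = norm["clinical"]
    assert clinical.gv == pytest.approx(1.0, abs=1e-10)
    only_quant, _, _ = joint_metric_at_time(
        mixed_panel, t, grouping="by_type"
    )
    assert set(raw) == {"clinical", "symptoms", "strain"}
    assert joint.gv == pytest.approx(3.0, abs=1e-9)
    assert only_quant.gv == pytest.approx(3.0, abs=1e-9)


def test_joint_metric_covid_snapshot_gv_three(covid_panel):
    joint, raw, norm = joint_metric_at_time(
        covid_panel, covid_panel.times[0], grouping="by_source"
    )
    assert set(raw) == {"health", "stringency", "mobility"}
    assert joint.gv == pytest.approx(3.0, abs=1e-9)
    for m in norm.values():
        assert m.gv == pytest.approx(1.0, abs=1e-10)


def test_joint_metric_toy_panel_matches_hand_normalized_components(toy_panel):
    snap = toy_panel.slice_time("t1")
    X = snap[["temp", "crp"]].to_numpy(dtype=float)
    scatter, _, _ = robust_covariance(X, seed=0)
    parts = [
        mahalanobis_bruteforce(X, scatter),
        jaccard_bruteforce(snap[["cough", "fever"]].to_numpy(dtype=int)),
        hamming_bruteforce(snap[["strain"]].to_numpy(dtype=object)),
    ]
    expected = sum(p / gv_bruteforce(p) for p in parts)
    joint, _, _ = joint_metric_at_time(toy_panel, "t1", grouping="by_source")
    assert np.abs(joint.values - expected).max() < 1e-10


def test_mixed_source_is_split_by_type(toy_panel):
    # relabel all variables under a single source: must split into 3 sub-blocks
    from dynagower.distance import group_variables
    from dynagower.panel import VariableSpec

    panel = toy_panel
    merged = [VariableSpec(v.name, v.vtype, "all") for v in panel.variables]
    clone = type(panel)(
        panel.entities, panel.times, merged,
        {t: panel.slice_time(t) for t in panel.times},
    )
    groups = group_variables(clone, "by_source")
    assert list(groups) == ["all:quantitative", "all:binary", "all:categorical"]
    joint, _, _ = joint_metric_at_time(clone, "t1", grouping="by_source")
    assert joint.gv == pytest.approx(3.0, abs=1e-9)


def test_degenerate_group_error_names_group_and_time(toy_panel):
    frames = {t: toy_panel.slice_time(t) for t in toy_panel.times}
    frames["t1"]["strain"] = "alpha"  # all identical -> zero gv component
    clone = type(toy_panel)(
        toy_panel.entities, toy_panel.times, toy_panel.variables, frames
    )
    with pytest.raises(DegenerateSourceError, match="virology.*t1"):
        joint_metric_at_time(clone, "t1", grouping="by_source")


def test_distance_series_structure_and_lenient_mode(mixed_panel, mixed_series):
    assert len(mixed_series.matrices) == mixed_panel.N
    single, _, _ = joint_metric_at_time(mixed_panel, mixed_panel.times[0])
    np.testing.assert_allclose(
        mixed_series.matrices[0].values, single.values, atol=1e-12
    )
    for key in mixed_series.components_raw:
        assert len(mixed_series.components_raw[key]) == mixed_panel.N


def test_distance_series_invariant_to_row_permutation(tmp_path, mixed_panel):
    data, meta = tmp_path / "p.csv", tmp_path / "m.yaml"
    write_panel(mixed_panel, data, meta)
    base = distance_series(read_panel(data, meta), seed=0)

    df = pd.read_csv(data, dtype=str)
    shuffled = df.sample(frac=1.0, random_state=99)
    shuffled.to_csv(tmp_path / "shuffled.csv", index=False)
    other = distance_series(read_panel(tmp_path / "shuffled.csv", meta), seed=0)

    order = [other.labels.index(e) for e in base.labels]
    for m_base, m_other in zip(base.matrices, other.matrices):
        realigned = m_other.values[np.ix_(order, order)]
        assert np.abs(m_base.values - realigned).max() < 1e-10
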