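import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from interheat import (DataMatrix, is_na10, normalize_columns,
                       percentize_columns, scale_columns, sqrt_transform)
from interheat.transforms import TransformError, TransformSpec, apply_transform


def dm(values):
    a = np.atleast_2d(np.asarray(values, dtype=float))
    return DataMatrix(a, [f"r{i}" for i in range(a.shape[0])],
                      [f"c{j}" for j in range(a.shape[1])])


def col(values):
    return dm(np.asarray(values, dtype=float)[:, None])


# -- example-based checks ----------------------------------------------------

def test_sqrt_exact_roots():
    out = sqrt_transform(dm([[0, 4], [9, 16]]))
    assert out.values.tolist() == [[0, 2], [3, 4]]


def test_sqrt_zero_fixed_point():
    out = sqrt_transform(dm(np.zeros((2, 3))))
    assert (out.values == 0).all()


def test_sqrt_negative_cell_named():
    with pytest.raises(TransformError, match=r"'r0'.*'c1'"):
        sqrt_transform(dm([[1, -1]]))


@pytest.mark.parametrize("data,expected", [
    ([1, 2, 3], [-1, 0, 1]),
    ([5, 5, 5], [0, 0, 0]),
    ([2, 4], [-1 / np.sqrt(2), 1 / np.sqrt(2)]),  # sd = sqrt(2)
])
def test_scale_examples(data, expected):
    out = scale_columns(col(data))
    np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)


def test_scale_too_few_values_rejected():
    with pytest.raises(TransformError):
        scale_columns(col([1.0]))


@pytest.mark.parametrize("data,expected", [
    ([2, 4, 6], [0, 0.5, 1]),
    ([-1, 1], [0, 1]),
    ([3, 3, 3], [0, 0, 0]),
])
def test_normalize_examples(data, expected):
    out = normalize_columns(col(data))
    np.testing.assert_allclose(out.values[:, 0], expected)


@pytest.mark.parametrize("data,expected", [
    ([10, 20, 30, 40], [0.25, 0.5, 0.75, 1.0]),
    ([1, 1, 3], [2 / 3, 2 / 3, 1.0]),
    ([1, np.nan, 2], [0.5, np.nan, 1.0]),  # ECDF over non-missing only
])
def test_percentize_examples(data, expected):
    out = percentize_columns(col(data))
    np.testing.assert_allclose(out.values[:, 0], expected)


def test_percentize_matches_counting_oracle():
    rng = np.random.default_rng(11)
    v = rng.integers(0, 5, size=12).astype(float)
    v[[2, 7]] = np.nan
    out = percentize_columns(col(v)).values[:, 0]
    obs = v[~np.isnan(v)]
    for i, x in enumerate(v):
        if np.isnan(x):
            assert np.isnan(out[i])
        else:
            assert out[i] == pytest.approx(np.sum(obs <= x) / len(obs))


def test_is_na10_indicator():
    m = dm([[1, np.nan], [np.nan, 4]])
    out = is_na10(m)
    assert out.values.tolist() == [[0, 1], [1, 0]]
    assert not out.missing_mask.any()
    assert is_na10(dm([[1, 2]])).values.tolist() == [[0, 0]]
    assert is_na10(dm([[np.nan, np.nan]])).values.tolist() == [[1, 1]]


def test_row_axis_transposes_the_margin():
    m = dm([[1, 2, 3], [10, 20, 30]])
    out = apply_transform(m, TransformSpec("normalize", axis="row"))
    np.testing.assert_allclose(out.values, [[0, 0.5, 1], [0, 0.5, 1]])


# -- property-based checks ---------------------------------------------------

finite_cols = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=30)


@given(finite_cols)
def test_percentize_is_rank_preserving(data):
    v = np.asarray(data)
    p = percentize_columns(col(v)).values[:, 0]
    assert ((p > 0) & (p <= 1)).all()
    order = np.argsort(v, kind="stable")
    assert (np.diff(p[order]) >= 0).all()
    # ties get identical outputs
    for i in range(len(v)):
        same = v == v[i]
        assert len(set(p[same])) == 1


@given(finite_cols)
def test_normalize_is_idempotent(data):
    m = col(np.asarray(data))
    once = normalize_columns(m)
    twice = normalize_columns(once)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-15)


@given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=30)
       .filter(lambda v: len(set(v)) > 1))
def test_scale_moments(data):
    out = scale_columns(col(np.asarray(data))).values[:, 0]
    assert abs(out.mean()) < 1e-12
    assert abs(out.std(ddof=1) - 1) < 1e-12


@pytest.mark.parametrize("fn", [sqrt_transform, scale_columns,
                                normalize_columns, percentize_columns])
def test_transforms_preserve_shape_labels_and_mask(fn):
    rng = np.random.default_rng(5)
    values = np.abs(rng.normal(size=(8, 4))) + 0.1
    values[2, 1] = np.nan
    values[5, 3] = np.nan
    m = DataMatrix(values, [f"r{i}" for i in range(8)], list("wxyz"))
    out = fn(m)
    assert out.values.shape == m.values.shape
    assert out.row_labels == m.row_labels and out.col_labels == m.col_labels
    assert (out.missing_mask == m.missing_mask).all()
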