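"""One-dimensional basis construction: values, dimensions, knot placement."""

import subprocess
import shutil

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pydlnm import BasisSpec, basis_dimension, evaluate_basis, make_lag_knots


def _colspace_projector(M):
    q, _ = np.linalg.qr(M)
    return q @ q.T


# ---------------------------------------------------------------------------
# evaluate_basis values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, expected",
    [(5.0, 2.0), (2.0, 0.0), (3.0, 0.0)],
)
def test_threshold_is_truncated_linear(x, expected):
    """(x - k)_+ : the hockey-stick transform above the threshold knot."""
    b = evaluate_basis(BasisSpec.threshold([3.0]), [x], warn_range=False)
    assert b.values.shape == (1, 1)
    assert b.values[0, 0] == expected


def test_polynomial_monomials():
    b = evaluate_basis(BasisSpec.polynomial(2), [3.0])
    np.testing.assert_array_equal(b.values, [[3.0, 9.0]])
    b_i = evaluate_basis(BasisSpec.polynomial(2, intercept=True), [3.0])
    np.testing.assert_array_equal(b_i.values, [[1.0, 3.0, 9.0]])


def _natural_truncated_power(x, knots, boundary):
    """Independent textbook natural-spline basis (truncated power form).

    With all knots tau_1 < ... < tau_M (boundary knots included as knots),
    the natural cubic spline space is spanned by {1, x, N_1 .. N_{M-2}} with
    N_k = d_k - d_{M-1},  d_k(x) = [(x-tau_k)^3_+ - (x-tau_M)^3_+]/(tau_M-tau_k).
    """
    tau = np.concatenate([[boundary[0]], np.asarray(knots, float), [boundary[1]]])
    M = len(tau)

    def d(k):
        return (np.maximum(x - tau[k], 0) ** 3 - np.maximum(x - tau[M - 1], 0) ** 3) / (
            tau[M - 1] - tau[k]
        )

    cols = [np.ones_like(x), x] + [d(k) - d(M - 2) for k in range(M - 2)]
    return np.column_stack(cols)


def test_natural_spline_matches_truncated_power_oracle():
    """The B-spline-with-constraints construction spans the same space as the
    textbook truncated-power natural basis, checked via projection matrices."""
    x = np.linspace(0.0, 10.0, 200)
    knots, boundary = [2.0, 4.0, 6.0], (0.0, 10.0)
    ours = evaluate_basis(
        BasisSpec.natural_spline(knots=knots, boundary_knots=boundary), x
    ).values
    oracle = _natural_truncated_power(x, knots, boundary)
    # without intercept the basis spans the natural space modulo constants
    ours_full = np.column_stack([np.ones_like(x), ours])
    assert ours_full.shape[1] == oracle.shape[1]
    diff = _colspace_projector(ours_full) - _colspace_projector(oracle)
    assert np.abs(diff).max() < 1e-8


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_natural_spline_matches_splines_ns(tmp_path):
    """Column-by-column agreement with R's splines::ns (same construction)."""
    script = tmp_path / "ns.R"
    script.write_text(
        "library(splines)\n"
        "x <- seq(0, 10, length.out = 150)\n"
        "b <- ns(x, knots = c(2.5, 5, 7), Boundary.knots = c(0, 10))\n"
        f"write.csv(b, '{tmp_path}/r_ns.csv', row.names = FALSE)\n"
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    import pandas as pd

    R = pd.read_csv(tmp_path / "r_ns.csv").to_numpy()
    x = np.linspace(0, 10, 150)
    P = evaluate_basis(
        BasisSpec.natural_spline(knots=[2.5, 5, 7], boundary_knots=(0, 10)), x
    ).values
    np.testing.assert_allclose(P, R, atol=1e-10)


def test_strata_indicators_partition():
    x = np.array([-1.0, 0.5, 1.5, 3.0, 10.0])
    with_int = evaluate_basis(BasisSpec.strata([1.0, 2.0], intercept=True), x).values
    assert with_int.shape == (5, 3)
    np.testing.assert_array_equal(with_int.sum(axis=1), np.ones(5))
    without = evaluate_basis(BasisSpec.strata([1.0, 2.0]), x).values
    assert without.shape == (5, 2)
    np.testing.assert_array_equal(without, with_int[:, 1:])


def test_identity_one_column_per_lag():
    lags = np.arange(7)
    b = evaluate_basis(BasisSpec.identity(), lags)
    np.testing.assert_array_equal(b.values, np.eye(7))
    with pytest.raises(ValueError, match="integer"):
        evaluate_basis(BasisSpec.identity(), [0.5, 1.5])


def test_missing_values_propagate_to_rows():
    x = np.array([1.0, np.nan, 3.0])
    for spec in [
        BasisSpec.linear(),
        BasisSpec.polynomial(2),
        BasisSpec.threshold([2.0]),
        BasisSpec.strata([2.0], intercept=True),
        BasisSpec.natural_spline(df=3),
        BasisSpec.constant(),
    ]:
        v = evaluate_basis(spec, x).values
        assert np.isnan(v[1]).all(), spec.kind
        assert np.isfinite(v[[0, 2]]).all(), spec.kind


# ---------------------------------------------------------------------------
# basis_dimension
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "spec, values, expected",
    [
        (BasisSpec.linear(), None, 1),
        (BasisSpec.constant(), None, 1),
        (BasisSpec.polynomial(3), None, 3),
        (BasisSpec.polynomial(2, intercept=True), None, 3),
        (BasisSpec.threshold([1.0, 2.0]), None, 2),
        (BasisSpec.strata([1.0, 2.0]), None, 2),
        (BasisSpec.strata([1.0, 2.0], intercept=True), None, 3),
        (BasisSpec.natural_spline(knots=[1, 2, 3, 4], boundary_knots=(0, 5)), None, 5),
        (BasisSpec.natural_spline(df=11), None, 11),
        (BasisSpec.identity(), np.arange(31), 31),
    ],
)
def test_basis_dimension_rule(spec, values, expected):
    assert basis_dimension(spec, values=values) == expected


def test_spline_dimension_matches_column_count_and_rank():
    """4 internal knots, no intercept -> 5 columns of full rank (the '5 df'
    lag basis convention: df = internal knots + 1)."""
    x = np.linspace(0, 30, 300)
    spec = BasisSpec.natural_spline(knots=[2, 5, 10, 20], boundary_knots=(0, 30))
    b = evaluate_basis(spec, x)
    assert b.values.shape[1] == basis_dimension(spec) == 5
    assert np.linalg.matrix_rank(b.values) == 5


# ---------------------------------------------------------------------------
# make_lag_knots
# ---------------------------------------------------------------------------

def test_lag_knots_single_is_log_midpoint():
    k = make_lag_knots(30, 1)
    np.testing.assert_allclose(k, [np.sqrt(30.0)])


def test_lag_knots_denser_at_small_lags():
    k = make_lag_knots(30, 3)
    assert len(k) == 3
    assert np.all(np.diff(k) > 0)
    assert k[0] > 0 and k[-1] < 30
    assert (k[1] - k[0]) < (k[2] - k[1])


def test_lag_knots_validation():
    with pytest.raises(ValueError):
        make_lag_knots(2, 2)
    with pytest.raises(ValueError):
        make_lag_knots(10, 0)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def test_affine_shift_preserves_spline_column_space():
    x = np.linspace(0, 10, 120)
    shift = 7.5
    a = evaluate_basis(
        BasisSpec.natural_spline(knots=[3, 6], boundary_knots=(0, 10)), x
    ).values
    b = evaluate_basis(
        BasisSpec.natural_spline(knots=[3 + shift, 6 + shift], boundary_knots=(shift, 10 + shift)),
        x + shift,
    ).values
    ones = np.ones((len(x), 1))
    diff = _colspace_projector(np.hstack([ones, a])) - _colspace_projector(np.hstack([ones, b]))
    assert np.abs(diff).max() < 1e-8


def test_natural_spline_linear_beyond_boundary():
    spec = BasisSpec.natural_spline(knots=[3, 5, 7], boundary_knots=(0, 10))
    h = 0.05
    interior = evaluate_basis(spec, np.arange(0, 10, h)).values
    d2_int = np.abs(np.diff(interior, 2, axis=0) / h**2).max()
    outside = evaluate_basis(spec, np.arange(11, 14, h), warn_range=False).values
    d2_out = np.abs(np.diff(outside, 2, axis=0) / h**2).max()
    assert d2_out < 1e-6 * d2_int


def test_repeated_value_rows_bit_identical():
    x = np.full(5, 3.7)
    v = evaluate_basis(
        BasisSpec.natural_spline(knots=[3.0], boundary_knots=(0, 10)), x, warn_range=False
    ).values
    for i in range(1, 5):
        assert (v[i] == v[0]).all()


def test_invalid_specs_error():
    with pytest.raises(ValueError, match="strictly increasing"):
        BasisSpec.threshold([2.0, 1.0])
    with pytest.raises(ValueError, match="within boundary"):
        BasisSpec.natural_spline(knots=[5.0], boundary_knots=(0.0, 2.0))
    with pytest.raises(ValueError, match="kind"):
        BasisSpec("cubic_magic")
    with pytest.raises(ValueError, match="degree"):
        BasisSpec("polynomial")


def test_out_of_range_knots_warn_not_error():
    with pytest.warns(UserWarning, match="outside the data range"):
        evaluate_basis(BasisSpec.threshold([100.0]), np.linspace(0, 10, 20))


def test_spec_serialization_round_trip():
    spec = BasisSpec.natural_spline(knots=[2.0, 4.0], boundary_knots=(0.0, 10.0), intercept=True)
    again = BasisSpec.from_dict(spec.to_dict())
    assert again == spec
    x = np.linspace(0, 10, 50)
    np.testing.assert_array_equal(
        evaluate_basis(spec, x).values, evaluate_basis(again, x).values
    )


def test_df_resolution_places_even_and_quantile_knots():
    rng = np.random.default_rng(5)
    x = rng.gamma(2.0, 5.0, 500)
    even = BasisSpec.natural_spline(df=5).resolved(x)
    assert len(even.knots) == 4
    np.testing.assert_allclose(even.knots, np.linspace(x.min(), x.max(), 6)[1:-1])
    quant = BasisSpec.natural_spline(df=5, knot_placement="quantiles").resolved(x)
    np.testing.assert_allclose(quant.knots, np.quantile(x, [0.2, 0.4, 0.6, 0.8]))
    assert basis_dimension(even) == basis_dimension(quant) == 5


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=1, max_size=30),
    st.floats(-20, 20),
)
def test_threshold_column_formula_property(xs, knot):
    x = np.asarray(xs)
    v = evaluate_basis(BasisSpec.threshold([knot]), x, warn_range=False).values
    np.testing.assert_array_equal(v[:, 0], np.maximum(x - knot, 0.0))
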