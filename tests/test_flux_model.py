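"""Unit and property tests for the three-pool label-incorporation model."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import curve_fit

from mepflux.flux_model import (
    DEGENERACY_RTOL,
    FluxFit,
    LabelCurve,
    PoolSizes,
    cascade_ode_oracle,
    fit_flux,
    flux_fit_row,
    label_fraction,
    read_label_curve,
)


def distinct_pools(a, b, c, rtol=1e-3):
    scale = max(a, b, c)
    return min(abs(a - b), abs(a - c), abs(b - c)) > rtol * scale


pool_values = st.floats(min_value=1.0, max_value=200.0)


@st.composite
def pool_triples(draw):
    a, b, c = draw(pool_values), draw(pool_values), draw(pool_values)
    if not distinct_pools(a, b, c):
        a, b, c = a, a * 1.7 + 1.0, a * 3.1 + 2.0
    return PoolSizes(a, b, c)


class TestPoolSizes:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            PoolSizes(0.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            PoolSizes(1.0, -3.0, 2.0)

    def test_distinctness_predicate(self):
        assert PoolSizes(1.0, 2.0, 3.0).is_distinct()
        assert not PoolSizes(1.0, 1.0 + 1e-9, 3.0).is_distinct()
        assert not PoolSizes(5.0, 3.0, 5.0 * (1 + 0.5 * DEGENERACY_RTOL)).is_distinct()


class TestLabelFraction:
    def test_starts_at_zero(self, reference_rows):
        for row in reference_rows:
            pools = PoolSizes(row["A"], row["B"], row["C"])
            assert label_fraction(0.0, pools, row["J"], row["m"]) == pytest.approx(0.0, abs=1e-12)

    def test_reference_prediction_at_20min(self, ev_high):
        """EV at high light/temperature: ~91% labeled at 20 min, within the
        85-95% plateau range observed for isoprene."""
        pools = PoolSizes(ev_high["A"], ev_high["B"], ev_high["C"])
        f20 = label_fraction(20.0, pools, ev_high["J"], ev_high["m"])
        assert f20 == pytest.approx(0.908, abs=5e-3)
        assert 0.85 <= f20 <= 0.95

    def test_asymptote_reaches_plateau(self, ev_high):
        pools = PoolSizes(ev_high["A"], ev_high["B"], ev_high["C"])
        assert label_fraction(1000.0, pools, ev_high["J"], ev_high["m"]) == pytest.approx(
            ev_high["m"], abs=1e-12
        )

    @given(pools=pool_triples(), J=st.floats(1.0, 100.0), m=st.floats(0.1, 1.0))
    def test_coefficient_normalization(self, pools, J, m):
        """The three partial-fraction coefficients sum to 1, hence f(0)=0."""
        a, b, c = pools.as_tuple()
        coeffs = (
            a * a / ((a - b) * (a - c))
            + b * b / ((b - a) * (b - c))
            + c * c / ((c - a) * (c - b))
        )
        assert coeffs == pytest.approx(1.0, abs=1e-10)
        assert label_fraction(0.0, pools, J, m) == pytest.approx(0.0, abs=1e-10)

    @given(pools=pool_triples(), J=st.floats(1.0, 100.0), m=st.floats(0.1, 1.0))
    def test_monotone_and_bounded(self, pools, J, m):
        t = np.linspace(0.0, 60.0, 121)
        f = label_fraction(t, pools, J, m)
        assert np.all(f >= -1e-12) and np.all(f <= m + 1e-12)
        assert np.all(np.diff(f) >= -1e-9)

    def test_rejects_bad_parameters(self, ev_high):
        pools = PoolSizes(ev_high["A"], ev_high["B"], ev_high["C"])
        with pytest.raises(ValueError):
            label_fraction(1.0, pools, -1.0, 0.9)
        with pytest.raises(ValueError):
            label_fraction(1.0, pools, 10.0, 1.5)
        with pytest.raises(ValueError):
            label_fraction(-1.0, pools, 10.0, 0.9)

    def test_degenerate_pools_fall_back_to_integration(self, grid):
        """Equal pool sizes void the closed form; evaluation must still work
        and agree with the cascade integration."""
        pools = PoolSizes(10.0, 10.0, 10.0)
        f = label_fraction(grid, pools, 5.0, 1.0)
        oracle = cascade_ode_oracle(grid, pools, 5.0, 1.0)
        assert f[0] == pytest.approx(0.0, abs=1e-9)
        assert f[-1] == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(f, oracle.f, atol=1e-9)


class TestCascadeOracle:
    def test_matches_closed_form_on_reference_rows(self, reference_rows, grid):
        for row in reference_rows:
            pools = PoolSizes(row["A"], row["B"], row["C"])
            closed = label_fraction(grid, pools, row["J"], row["m"])
            oracle = cascade_ode_oracle(grid, pools, row["J"], row["m"])
            assert np.max(np.abs(closed - oracle.f)) <= 1e-6

    def test_matches_closed_form_on_random_draws(self, rng, grid):
        """The closed form's coefficient-to-rate pairing (pool X's coefficient
        decays at rate J/X) must agree with direct integration for asymmetric
        pool triples."""
        for _ in range(25):
            a, b, c = rng.uniform(2.0, 150.0, size=3)
            if not distinct_pools(a, b, c):
                continue
            pools = PoolSizes(a, b, c)
            J = rng.uniform(1.0, 60.0)
            m = rng.uniform(0.3, 1.0)
            closed = label_fraction(grid, pools, J, m)
            oracle = cascade_ode_oracle(grid, pools, J, m)
            assert np.max(np.abs(closed - oracle.f)) <= 1e-6

    def test_fast_equilibration_limit(self):
        pools = PoolSizes(10.0, 12.0, 9.0)
        t = np.arange(0.0, 50.5, 0.5)
        curve = cascade_ode_oracle(t, pools, 1e4, 0.9)
        assert curve.f[1] == pytest.approx(0.9, abs=1e-6)

    def test_rejects_descending_grid(self):
        with pytest.raises(ValueError):
            cascade_ode_oracle(np.array([5.0, 1.0]), PoolSizes(1, 2, 3), 1.0, 0.9)


class TestLabelCurve:
    def test_clips_small_overshoot(self):
        c = LabelCurve(np.array([0.0, 1.0, 2.0]), np.array([-0.01, 0.5, 1.01]))
        assert c.f[0] == 0.0 and c.f[-1] == 1.0

    def test_rejects_gross_values_and_unordered_times(self):
        with pytest.raises(ValueError):
            LabelCurve(np.array([0.0, 1.0]), np.array([0.0, 1.5]))
        with pytest.raises(ValueError):
            LabelCurve(np.array([1.0, 0.5]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            LabelCurve(np.array([0.0, 1.0]), np.array([np.nan, 0.2]))


class TestFitFlux:
    @pytest.mark.parametrize(
        "genotype,ppfd,temp_c",
        [("EV", 1000, 30), ("OE", 1000, 30), ("EV", 250, 21)],
    )
    def test_noiseless_round_trip_reference(self, reference_rows, grid, genotype, ppfd, temp_c):
        row = next(
            r for r in reference_rows
            if r["genotype"] == genotype and r["ppfd"] == ppfd and r["temp_c"] == temp_c
        )
        pools = PoolSizes(row["A"], row["B"], row["C"])
        curve = LabelCurve(grid, label_fraction(grid, pools, row["J"], row["m"]))
        fit = fit_flux(curve, pools, init_J=1.0, init_m=0.5)
        assert fit.converged
        assert fit.J == pytest.approx(row["J"], rel=1e-3)
        assert fit.m == pytest.approx(row["m"], rel=1e-3)

    def test_agrees_with_independent_optimizer(self, ev_high, grid):
        """Cross-check the fit against scipy.curve_fit on the same model."""
        pools = PoolSizes(ev_high["A"], ev_high["B"], ev_high["C"])
        rng = np.random.default_rng(7)
        f = label_fraction(grid, pools, ev_high["J"], ev_high["m"])
        noisy = np.clip(f + rng.normal(0.0, 0.01, f.size), 0.0, 1.0)
        curve = LabelCurve(grid, noisy)
        fit = fit_flux(curve, pools, init_J=1.0, init_m=0.5)

        popt, _ = curve_fit(
            lambda t, J, m: label_fraction(t, pools, J, m),
            grid, noisy, p0=[1.0, 0.5],
            bounds=([1e-9, 1e-6], [np.inf, 1.0]),
        )
        assert fit.J == pytest.approx(popt[0], rel=1e-4)
        assert fit.m == pytest.approx(popt[1], rel=1e-4)

    def test_default_initialization_recovers(self, reference_rows, grid):
        """The half-rise heuristic start must reach the same optimum as an
        explicit guess, for every reference parameter row."""
        for row in reference_rows:
            pools = PoolSizes(row["A"], row["B"], row["C"])
            curve = LabelCurve(grid, label_fraction(grid, pools, row["J"], row["m"]))
            fit = fit_flux(curve, pools)
            assert fit.converged and fit.J == pytest.approx(row["J"], rel=1e-3)

    def test_noisy_recovery_mean_bias(self, ev_high, grid):
        """Additive noise at sd 0.01: the mean recovered flux stays within a
        few percent of the generating value."""
        pools = PoolSizes(ev_high["A"], ev_high["B"], ev_high["C"])
        f = label_fraction(grid, pools, ev_high["J"], ev_high["m"])
        rng = np.random.default_rng(11)
        estimates = []
        for _ in range(50):
            noisy = np.clip(f + rng.normal(0.0, 0.01, f.size), 0.0, 1.0)
            fit = fit_flux(LabelCurve(grid, noisy), pools)
            if fit.converged:
                estimates.append(fit.J)
        assert len(estimates) >= 45
        assert np.mean(estimates) == pytest.approx(ev_high["J"], rel=0.05)

    def test_all_zero_and_all_plateau_curves_flagged(self, grid):
        pools = PoolSizes(40.0, 80.0, 35.0)
        flat0 = fit_flux(LabelCurve(grid, np.zeros_like(grid)), pools)
        assert not flat0.converged and "zero" in flat0.message
        plateau = fit_flux(LabelCurve(grid, np.full_like(grid, 0.9)), pools)
        assert not plateau.converged and "transient" in plateau.message

    def test_unresolved_transient_reports_large_uncertainty(self, grid):
        """When all time constants are far below the grid spacing the flux is
        unidentifiable and se_J must blow up instead of feigning precision."""
        pools = PoolSizes(8.0, 12.0, 10.0)
        f = label_fraction(grid, pools, 1e4, 0.9)
        fit = fit_flux(LabelCurve(grid, f), pools, init_J=5e3, init_m=0.8)
        assert (not np.isfinite(fit.se_J)) or fit.se_J > fit.J

    def test_too_few_points_rejected(self):
        pools = PoolSizes(1.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            fit_flux(LabelCurve(np.array([0.0, 1.0]), np.array([0.0, 0.5])), pools)


class TestIO:
    def test_label_curve_round_trip(self):
        csv = io.StringIO("time_min,f_label\n0,0.0\n1,0.3\n2,0.5\n")
        curve = read_label_curve(csv)
        assert len(curve) == 3 and curve.f[1] == 0.3

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            read_label_curve(io.StringIO("t,f\n0,0\n"))

    def test_flux_fit_row_format(self):
        fit = FluxFit(J=28.65, m=0.912, se_J=0.1, se_m=0.01, rss=1e-4,
                      n_points=101, converged=True)
        row = flux_fit_row("EV_r01", fit)
        fields = row.split("\t")
        assert fields[0] == "EV_r01" and fields[-1] == "1" and len(fields) == 8
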