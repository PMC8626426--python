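"""Kinetic model core: closed forms against independent numeric oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from turnoverkit import (
    TissueCoefficients,
    exogenous_suspect,
    flag_impossible_observations,
    half_life_from_rate,
    missed_cleavage_fractions,
    precursor_fraction,
    protein_fraction,
    rate_from_half_life,
)
from turnoverkit.model import InvalidCoefficientsError, UndefinedHalfLifeError

LN2 = math.log(2.0)


def ode_precursor(coeffs: TissueCoefficients, t: float) -> float:
    """Independent oracle: integrate the compartment ODEs numerically."""

    def rhs(_, y):
        a, b = y
        return [
            coeffs.k_st * (1 - a) + coeffs.k_a0 * (b - a),
            coeffs.k_bt * (a - b),
        ]

    sol = solve_ivp(rhs, (0.0, t), [0.0, 0.0], rtol=1e-11, atol=1e-13)
    return float(sol.y[0, -1])


coeff_strategy = st.tuples(
    st.floats(0.01, 5.0), st.floats(0.005, 1.0), st.floats(0.005, 5.0)
).map(lambda v: TissueCoefficients(*v))


class TestPrecursorFraction:
    def test_initial_condition_and_steady_state(self, coeffs):
        assert precursor_fraction(coeffs, 0.0) == 0.0
        assert precursor_fraction(coeffs, 1e6) == pytest.approx(1.0, abs=1e-6)

    def test_matches_ode_integration(self, coeffs):
        assert precursor_fraction(coeffs, 7.0) == pytest.approx(
            ode_precursor(coeffs, 7.0), abs=1e-6
        )

    @settings(max_examples=30, deadline=None)
    @given(coeff_strategy, st.floats(0.1, 200.0))
    def test_ode_agreement_randomized(self, c, t):
        assert abs(precursor_fraction(c, t) - ode_precursor(c, t)) < 1e-6

    @settings(max_examples=50, deadline=None)
    @given(coeff_strategy)
    def test_monotone_and_bounded(self, c):
        grid = np.linspace(0.0, 200.0, 400)
        a = np.asarray(precursor_fraction(c, grid))
        assert np.all((a >= 0.0) & (a <= 1.0))
        assert np.all(np.diff(a) >= -1e-12)

    def test_invalid_inputs_rejected(self, coeffs):
        with pytest.raises(ValueError):
            precursor_fraction(coeffs, -1.0)
        with pytest.raises(InvalidCoefficientsError):
            TissueCoefficients(0.0, 0.05, 0.1)
        with pytest.raises(InvalidCoefficientsError):
            TissueCoefficients(0.25, -0.05, 0.1)


class TestProteinFraction:
    def test_no_turnover_is_zero(self, coeffs):
        for t in (0.0, 5.0, 100.0):
            assert protein_fraction(coeffs, 0.0, t) == 0.0

    def test_instantaneous_turnover_tracks_precursor(self, coeffs):
        # A protein with near-zero half-life resynthesizes constantly from
        # the free pool, so its unlabeled fraction matches the pool's.
        for t in (3.0, 14.0, 60.0):
            assert protein_fraction(coeffs, 1e6, t) == pytest.approx(
                precursor_fraction(coeffs, t), abs=1e-6
            )

    def test_matches_age_distribution_quadrature(self, coeffs):
        k = LN2 / 7.5
        oracle, _ = quad(
            lambda s: k * math.exp(-k * (14.0 - s)) * precursor_fraction(coeffs, s),
            0.0, 14.0, epsabs=1e-12, epsrel=1e-12,
        )
        assert protein_fraction(coeffs, k, 14.0) == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(coeff_strategy, st.floats(1e-3, 5.0), st.floats(0.0, 200.0))
    def test_below_precursor_and_bounded(self, c, k, t):
        f = protein_fraction(c, k, t)
        assert 0.0 <= f <= 1.0
        assert f <= precursor_fraction(c, t) + 1e-9

    @settings(max_examples=25, deadline=None)
    @given(coeff_strategy, st.floats(1.0, 100.0))
    def test_monotone_in_rate(self, c, t):
        ks = np.logspace(-3, 1.5, 40)
        f = np.asarray(protein_fraction(c, ks[:, None], np.asarray([t])))[:, 0]
        assert np.all(np.diff(f) >= -1e-10)

    def test_fast_precursor_limit_is_first_order(self):
        # With instant precursor and no recycling the model collapses to
        # F = 1 - exp(-k t), so F at one half-life is exactly 1/2.  The
        # limit requires dietary influx to dominate recycling exchange
        # (k_st >> k_a0); if both grow together the free pool instead
        # equilibrates with the still-labeled bulk pool.
        c = TissueCoefficients(k_st=1e8, k_bt=0.05, k_a0=10.0)
        k = LN2 / 7.5
        assert protein_fraction(c, k, 7.5) == pytest.approx(0.5, abs=1e-6)
        for t in (1.0, 10.0, 40.0):
            assert protein_fraction(c, k, t) == pytest.approx(
                1.0 - math.exp(-k * t), abs=1e-4
            )


class TestHalfLifeConversion:
    def test_known_values_and_round_trip(self):
        assert half_life_from_rate(LN2) == pytest.approx(1.0)
        assert half_life_from_rate(LN2 / 7.5) == pytest.approx(7.5)
        assert half_life_from_rate(rate_from_half_life(7.5)) == pytest.approx(
            7.5, rel=1e-12
        )

    def test_nonpositive_rate_rejected(self):
        for bad in (0.0, -1.0, math.nan):
            with pytest.raises(UndefinedHalfLifeError):
                half_life_from_rate(bad)


class TestMissedCleavageFractions:
    def test_everything_labeled_at_time_zero(self, coeffs):
        p = missed_cleavage_fractions(coeffs, LN2 / 7.5, 0.0)
        assert (p.p00, p.p08, p.p88) == (0.0, 0.0, 1.0)

    @settings(max_examples=60, deadline=None)
    @given(coeff_strategy, st.floats(1e-3, 5.0), st.floats(0.0, 120.0))
    def test_sum_and_marginal_identities(self, c, k, t):
        p = missed_cleavage_fractions(c, k, t)
        assert p.p00 + p.p08 + p.p88 == pytest.approx(1.0, abs=1e-9)
        assert p.p00 + p.p08 / 2.0 == pytest.approx(
            protein_fraction(c, k, t), abs=1e-9
        )

    def test_monte_carlo_oracle(self, coeffs):
        # Draw synthesis ages from the exponential age distribution and two
        # independent label states per molecule; molecules synthesized
        # before the switch are fully labeled.
        k = LN2 / 7.5
        t = 30.0
        n = 10**6
        rng = np.random.default_rng(2024)
        ages = rng.exponential(1.0 / k, size=n)
        synth = t - ages
        a = np.where(
            synth < 0,
            0.0,
            np.asarray(precursor_fraction(coeffs, np.clip(synth, 0.0, None))),
        )
        light1 = rng.random(n) < a
        light2 = rng.random(n) < a
        mc = np.array(
            [(light1 & light2).mean(), (light1 ^ light2).mean(),
             (~light1 & ~light2).mean()]
        )
        pred = missed_cleavage_fractions(coeffs, k, t)
        se = np.sqrt(mc * (1 - mc) / n)
        for got, want, s in zip(mc, (pred.p00, pred.p08, pred.p88), se):
            assert abs(got - want) < 3.0 * max(s, 1e-6)


class TestImpossibleRegionFlagging:
    def test_point_above_curve_flagged(self, coeffs):
        # ratio far above the free-lysine curve cannot be endogenous
        a3 = precursor_fraction(coeffs, 3.0)
        flags = flag_impossible_observations([3.0], [min(a3 + 0.2, 0.99)], coeffs,
                                             tol=0.05)
        assert flags.tolist() == [True]

    def test_points_on_model_curve_not_flagged(self, coeffs):
        k = LN2 / 7.5
        t = np.array([3.0, 7.0, 14.0, 30.0, 60.0])
        r = np.asarray(protein_fraction(coeffs, k, t))
        assert not flag_impossible_observations(t, r, coeffs, tol=0.05).any()

    def test_empty_input(self, coeffs):
        assert flag_impossible_observations([], [], coeffs).size == 0
        assert not exogenous_suspect([], [], coeffs)

    def test_fast_external_precursor_majority_flagged(self, coeffs):
        # an albumin-like peptide synthesized elsewhere with a fast
        # precursor pool exceeds this tissue's free-lysine curve
        fast = TissueCoefficients(k_st=5.0, k_bt=0.1, k_a0=0.5)
        k = rate_from_half_life(2.0)
        t = np.repeat([3.0, 7.0, 14.0, 30.0, 60.0], 4)
        rng = np.random.default_rng(7)
        r = np.clip(
            np.asarray(protein_fraction(fast, k, t)) + rng.normal(0, 0.02, t.size),
            0.0, 1.0,
        )
        flags = flag_impossible_observations(t, r, coeffs, tol=0.05)
        assert flags.mean() >= 0.5
        assert exogenous_suspect(t, r, coeffs, tol=0.05)


def test_curve_table_schema(coeffs):
    from turnoverkit import curve_table

    df = curve_table(coeffs, [LN2 / 7.5, LN2 / 30.0], t_max=60.0)
    assert list(df.columns[:2]) == ["t_d", "precursor"]
    assert len(df) == 200
    assert df["t_d"].iloc[-1] == pytest.approx(72.0)  # 1.2 x max timepoint
    assert (df.iloc[:, 1:].to_numpy() <= 1.0).all()
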