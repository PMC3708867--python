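"""Allelic-switching Markov chain: construction, stationarity, dynamics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import allelopop as ap
from allelopop.markov import N_STATES


class TestTransitionSpec:
    def test_defaults_are_valid(self, spec):
        assert np.isclose(sum(spec.z_star), 1.0)
        assert spec.shuttle_fraction(1, 2) == 0.12
        assert spec.shuttle_fraction(1, 4) == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"z_star": (0.5, 0.5, 0.0, 0.1)},  # does not sum to 1
            {"z_star": (-0.1, 0.5, 0.3, 0.3)},
            {"t_d": 0.0},
            {"shuttle": {(1, 4): 0.1}},  # states 1 and 4 are not linked
            {"shuttle": {(1, 2): 1.5}},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ap.TransitionSpec(**kwargs)


class TestTransitionProbabilities:
    def test_printed_shuttle_values(self, spec):
        p = ap.build_transition_probabilities(spec)
        # 12% of the population shuttles between states 1 and 2; 14% sit in state 1
        assert p[0, 1] == pytest.approx(0.06 / 0.14)
        assert p[0, 2] == pytest.approx(0.06 / 0.14)
        assert p[0, 3] == 0.0 and p[3, 0] == 0.0  # states 1 and 4 unlinked
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.all((p >= 0) & (p <= 1))

    def test_no_switching_gives_identity(self):
        spec = ap.TransitionSpec(shuttle={})
        assert np.array_equal(ap.build_transition_probabilities(spec), np.eye(4))

    def test_oversized_shuttle_rejected_naming_row(self):
        spec = ap.TransitionSpec(shuttle={(1, 2): 0.40})  # 0.20/0.14 > 1
        with pytest.raises(ValueError, match="row"):
            ap.build_transition_probabilities(spec)

    def test_detailed_balance_exact(self, spec):
        p = ap.build_transition_probabilities(spec)
        z = np.asarray(spec.z_star)
        for i in range(4):
            for j in range(4):
                assert z[i] * p[i, j] == pytest.approx(z[j] * p[j, i], abs=1e-15)


class TestRateMatrix:
    def test_rates_are_probabilities_over_doubling_time(self, spec):
        p = ap.build_transition_probabilities(spec)
        k = ap.build_rate_matrix(p, spec.t_d)
        assert k[0, 1] == pytest.approx(0.06 / 0.14 / 10.0)
        assert np.allclose(k.sum(axis=1), 0.0, atol=1e-12)

    def test_identity_probabilities_give_zero_rates(self):
        assert np.array_equal(ap.build_rate_matrix(np.eye(4), 10.0), np.zeros((4, 4)))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ap.build_rate_matrix(np.eye(4), 0.0)
        with pytest.raises(ValueError):
            ap.build_rate_matrix(np.full((4, 4), 0.5), 10.0)


class TestGrowthRates:
    def test_ln2_over_doubling_time(self):
        lam = ap.growth_rates(10.0)
        assert np.allclose(lam, np.log(2) / 10)
        assert np.allclose(np.exp(lam * 10.0), 2.0)  # doubles over one cycle
        assert ap.growth_rates(np.log(2))[0] == pytest.approx(1.0)

    def test_requires_positive_doubling_time(self):
        with pytest.raises(ValueError):
            ap.growth_rates(-1.0)


class TestStationaryComposition:
    def test_recovers_observed_composition(self, rates):
        z = ap.stationary_composition(rates.k)
        assert z == pytest.approx([0.14, 0.28, 0.28, 0.30], abs=1e-12)

    def test_disconnected_chain_rejected(self):
        with pytest.raises(ValueError, match="communicating"):
            ap.stationary_composition(np.zeros((4, 4)))

    def test_matches_long_run_single_cell_occupancy(self, rates):
        """Brute-force chain simulation oracle: time-averaged occupancy."""
        rng = np.random.default_rng(42)
        k = rates.k
        occupancy = np.zeros(4)
        state, t_total = 0, 0.0
        while t_total < 3e5:
            out = np.array([k[state, j] if j != state else 0.0 for j in range(4)])
            rate = out.sum()
            dwell = rng.exponential(1 / rate)
            occupancy[state] += dwell
            t_total += dwell
            state = rng.choice(4, p=out / rate)
        occupancy /= occupancy.sum()
        assert occupancy == pytest.approx(ap.stationary_composition(k), abs=0.02)


@st.composite
def random_specs(draw):
    raw = draw(
        st.lists(st.floats(0.05, 1.0), min_size=N_STATES, max_size=N_STATES)
    )
    z = np.array(raw) / np.sum(raw)
    z = tuple(np.round(z / z.sum(), 12))
    z = (*z[:3], 1.0 - sum(z[:3]))  # force exact unit sum
    # keep each pair's shuttle inside the feasible region (the mass leaving a
    # state over one cycle must stay below z_i) and keep the chain connected
    # via a strictly positive spanning set of pairs
    spanning = [(1, 2), (1, 3), (2, 4)]
    shuttle = {}
    for i, j in [(1, 2), (1, 3), (2, 3), (2, 4), (3, 4)]:
        lo = 0.05 if (i, j) in spanning else 0.0
        shuttle[(i, j)] = draw(st.floats(lo, 1.0)) * 0.5 * min(z[i - 1], z[j - 1])
    return ap.TransitionSpec(z_star=z, shuttle=shuttle, t_d=draw(st.floats(1.0, 50.0)))


class TestRoundTripProperty:
    @given(random_specs())
    def test_stationary_composition_recovers_spec(self, spec):
        """Detailed-balance construction makes z_star stationary for any spec."""
        rm = ap.build_rate_matrices(spec)
        z = ap.stationary_composition(rm.k)
        assert z == pytest.approx(np.asarray(spec.z_star), abs=1e-9)

    @given(random_specs())
    def test_combined_matrix_is_rates_plus_growth(self, spec):
        rm = ap.build_rate_matrices(spec)
        assert np.allclose(rm.a, rm.k + np.diag(rm.lam))


class TestEvolveFractions:
    def test_stationary_point_is_fixed(self, spec, rates):
        z = ap.evolve_fractions(spec.z_star, rates, 500.0)
        assert z == pytest.approx(np.asarray(spec.z_star), abs=1e-10)

    def test_reconstitution_timescale(self, rates):
        """Uniform type-1 ensemble approaches equilibrium within 100 h."""
        z100 = ap.evolve_fractions([1, 0, 0, 0], rates, 100.0)
        assert np.max(np.abs(z100 - [0.14, 0.28, 0.28, 0.30])) < 0.01

    def test_matches_fine_step_integration(self, rates):
        """Matrix exponential vs explicit Runge-Kutta steps at dt = 0.01 h."""
        z = np.array([1.0, 0.0, 0.0, 0.0])
        dt = 0.01
        k = rates.k
        for _ in range(int(10 / dt)):
            k1 = z @ k
            k2 = (z + 0.5 * dt * k1) @ k
            k3 = (z + 0.5 * dt * k2) @ k
            k4 = (z + dt * k3) @ k
            z = z + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert ap.evolve_fractions([1, 0, 0, 0], rates, 10.0) == pytest.approx(z, abs=1e-9)

    def test_conserves_total_fraction(self, rates):
        for t in (0.0, 1.0, 17.3, 250.0):
            assert ap.evolve_fractions([0.4, 0.1, 0.2, 0.3], rates, t).sum() == pytest.approx(
                1.0, abs=1e-9
            )

    def test_monotone_convergence_to_equilibrium(self, rates):
        z_star = ap.stationary_composition(rates.k)
        # beyond the slowest relaxation time the deviation shrinks monotonically
        times = np.arange(30.0, 200.0, 10.0)
        devs = [
            np.linalg.norm(ap.evolve_fractions([0, 0, 0, 1], rates, t) - z_star) for t in times
        ]
        assert np.all(np.diff(devs) <= 1e-12)
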