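"""Kinetic Monte Carlo engine: growth, division, partitioning, event loop."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import allelopop as ap
from allelopop.engine import ExtinctionError, initialize_population


class TestGrowth:
    def test_exponential_size_growth(self):
        assert ap.grow_size(0.3, 0.0, 10.0) == 0.3
        assert ap.grow_size(0.3, 10.0, 10.0) == pytest.approx(0.6)
        assert ap.grow_size(0.2325, 10.0, 10.0) == pytest.approx(0.465)


class TestDivisionHazard:
    def test_value_at_mean_division_size(self, div):
        # r_v * pdf / survival at v = mu: growth 0.0693*0.465, pdf 3.8365, sf 0.5
        assert ap.division_hazard(0.465, 10.0, div) == pytest.approx(0.2473, abs=2e-4)

    def test_vanishes_for_small_cells(self, div):
        assert ap.division_hazard(1e-6, 10.0, div) == pytest.approx(0.0, abs=1e-9)

    def test_increasing_over_working_range(self, div):
        v = np.linspace(div.mu - 2 * div.sigma, div.mu + 3 * div.sigma, 400)
        gamma = ap.division_hazard(v, 10.0, div)
        assert np.all(np.diff(gamma) > 0)

    def test_capped_when_survival_underflows(self, div):
        assert ap.division_hazard(50.0, 10.0, div) == div.hazard_cap


class TestPartitioning:
    def test_symmetric_beta_moments(self, div):
        rng = np.random.default_rng(10)
        x = ap.sample_partition_fraction(div.q, rng, size=100_000)
        assert x.mean() == pytest.approx(0.5, abs=0.001)
        assert x.std() == pytest.approx(0.5 / math.sqrt(2 * div.q + 1), rel=0.02)

    def test_infinite_q_forces_even_split(self):
        rng = np.random.default_rng(11)
        assert ap.sample_partition_fraction(math.inf, rng) == 0.5

    def test_sharpens_with_q(self):
        rng = np.random.default_rng(12)
        stds = [ap.sample_partition_fraction(q, rng, size=20_000).std() for q in (10, 39, 400)]
        assert stds[0] > stds[1] > stds[2]


class TestDivideCell:
    @given(
        n1=st.floats(0.0, 1e4),
        n2=st.floats(0.0, 1e4),
        v=st.floats(1e-3, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_conservation_and_inheritance(self, n1, n2, v, seed):
        mother = ap.CellState(
            n1=n1, n2=n2, v=v, r1=n1 / 2, r2=0.0, pattern=ap.AllelePattern.from_type(4)
        )
        da, db = ap.divide_cell(mother, ap.DivisionParams(), np.random.default_rng(seed))
        assert da.n1 + db.n1 == pytest.approx(n1, abs=1e-12 * max(1, n1))
        assert da.n2 + db.n2 == pytest.approx(n2, abs=1e-12 * max(1, n2))
        assert da.r1 + db.r1 == pytest.approx(n1 / 2, abs=1e-12 * max(1, n1))
        assert da.v + db.v == pytest.approx(v, abs=1e-15)
        assert da.pattern.type_id == db.pattern.type_id == 4

    def test_daughter_size_ratio_moments(self, div):
        rng = np.random.default_rng(13)
        mother = ap.CellState(n1=100.0, n2=0.0, v=0.5, pattern=ap.AllelePattern.from_type(2))
        ratios = np.array(
            [ap.divide_cell(mother, div, rng)[0].v / mother.v for _ in range(10_000)]
        )
        assert ratios.mean() == pytest.approx(0.5, abs=0.005)
        assert ratios.std() == pytest.approx(0.05625, rel=0.05)


class TestEventRates:
    def test_single_type4_cell_constant_rate(self, rates, expr, div):
        pop = initialize_population(1, (0, 0, 0, 1.0), expr, div, 10.0, np.random.default_rng(0))
        e = ap.build_event_rates(pop, rates, division_mode="constant_rate")
        row = dict(zip(e.targets[0], e.rates[0, :3]))
        assert row[1] == 0.0  # no direct 4 -> 1 transition
        assert row[2] == pytest.approx(rates.k[3, 1])
        assert row[3] == pytest.approx(rates.k[3, 2])
        assert e.rates[0, 3] == pytest.approx(math.log(2) / 10)
        assert e.total_rate == pytest.approx(e.rates.sum())

    def test_no_switching_leaves_only_division(self, expr, div):
        from allelopop.scenarios import no_switching_rates

        pop = initialize_population(1, (1.0, 0, 0, 0), expr, div, 10.0, np.random.default_rng(0))
        e = ap.build_event_rates(pop, no_switching_rates(10.0), division_mode="constant_rate")
        assert e.total_rate == pytest.approx(math.log(2) / 10)

    def test_total_rate_additive_over_identical_cells(self, rates, expr, div):
        pop1 = initialize_population(1, (0, 1.0, 0, 0), expr, div, 10.0, np.random.default_rng(1))
        pop100 = initialize_population(
            100, (0, 1.0, 0, 0), expr, div, 10.0, np.random.default_rng(1)
        )
        e1 = ap.build_event_rates(pop1, rates, division_mode="constant_rate")
        e100 = ap.build_event_rates(pop100, rates, division_mode="constant_rate")
        assert e100.total_rate == pytest.approx(100 * e1.total_rate)

    def test_empty_population_signals_extinction(self, rates):
        pop = ap.Population(10)
        with pytest.raises(ExtinctionError):
            ap.build_event_rates(pop, rates)


class TestQuiescence:
    def test_exponential_mean(self):
        rng = np.random.default_rng(14)
        draws = np.array([ap.sample_quiescence(2.0, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(0.5, rel=0.02)

    def test_seeded_reproducibility(self):
        a = [ap.sample_quiescence(1.0, np.random.default_rng(7)) for _ in range(3)]
        b = [ap.sample_quiescence(1.0, np.random.default_rng(7)) for _ in range(3)]
        assert a == b

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            ap.sample_quiescence(0.0, np.random.default_rng(0))


class TestSelectEvent:
    def _matrix(self, rows):
        rows = np.asarray(rows, dtype=float)
        targets = np.tile(np.array([2, 3, 4]), (rows.shape[0], 1))
        return ap.EventRateMatrix(rates=rows, targets=targets, total_rate=float(rows.sum()))

    def test_single_division_channel(self):
        e = self._matrix([[0, 0, 0, 0.07]])
        for ran2 in (0.0, 0.5, 0.99):
            ev = ap.select_event(e, ran2)
            assert (ev.cell_index, ev.kind) == (0, "divide")

    def test_two_equal_cells_split_proportionally(self):
        e = self._matrix([[0, 0, 0, 1.0], [0, 0, 0, 1.0]])
        assert ap.select_event(e, 0.25).cell_index == 0
        assert ap.select_event(e, 0.75).cell_index == 1

    def test_switch_target_resolution(self):
        e = self._matrix([[0.5, 0.5, 0, 0]])
        assert ap.select_event(e, 0.1).target_state == 2
        assert ap.select_event(e, 0.9).target_state == 3

    def test_empirical_frequencies_match_weights(self):
        e = self._matrix([[0.1, 0.2, 0.0, 0.3], [0.0, 0.0, 0.1, 0.3]])
        rng = np.random.default_rng(15)
        counts = np.zeros((2, 4))
        n = 100_000
        for ran2 in rng.random(n):
            ev = ap.select_event(e, ran2)
            col = 3 if ev.kind == "divide" else {2: 0, 3: 1, 4: 2}[ev.target_state]
            counts[ev.cell_index, col] += 1
        assert np.allclose(counts / n, e.rates / e.total_rate, atol=0.005)


class TestSimulationRun:
    def test_decoupled_exponential_growth(self, base_config):
        """No switching, constant division rate, even splits: clean doubling."""
        from allelopop.scenarios import no_switching_rates

        cfg = replace(
            base_config.sim,
            n_initial=400,
            n_cap=100_000,
            t_end=50.0,
            seed=21,
            division_mode="constant_rate",
        )
        div = ap.DivisionParams(q=math.inf)
        res = ap.run(
            no_switching_rates(10.0),
            base_config.expr,
            div,
            cfg,
            initial_composition=(0, 1.0, 0, 0),
        )
        sizes = np.array([len(s) for s in res.snapshots])
        times = np.array([s.time_h for s in res.snapshots])
        rate = np.polyfit(times, np.log(sizes), 1)[0]
        assert rate == pytest.approx(math.log(2) / 10, rel=0.05)
        # composition static: every cell still type 2
        assert np.all(res.final.state == 2)

    def test_constant_number_cap_respected(self, base_config, rates):
        cfg = replace(base_config.sim, n_initial=100, n_cap=300, t_end=40.0, seed=22)
        res = ap.run(rates, base_config.expr, base_config.div, cfg)
        assert max(len(s) for s in res.snapshots) <= 300
        assert len(res.final) == 300

    def test_identical_seeds_bit_identical(self, base_config, rates):
        cfg = replace(base_config.sim, n_initial=200, n_cap=200, t_end=20.0, seed=23)
        res_a = ap.run(rates, base_config.expr, base_config.div, cfg)
        res_b = ap.run(rates, base_config.expr, base_config.div, cfg)
        assert res_a.event_counts == res_b.event_counts
        for sa, sb in zip(res_a.snapshots, res_b.snapshots):
            assert np.array_equal(sa.n1, sb.n1)
            assert np.array_equal(sa.v, sb.v)
            assert np.array_equal(sa.state, sb.state)

    def test_division_conserves_content_in_engine(self, base_config, rates):
        """Engine-level division: daughters sum to mother, machine precision."""
        sim = ap.Simulation(
            rates,
            base_config.expr,
            base_config.div,
            replace(base_config.sim, n_initial=5, n_cap=10, seed=24),
        )
        i = 2
        before = np.array(
            [sim.pop.n1[i], sim.pop.n2[i], sim.pop.r1[i], sim.pop.r2[i], sim.pop.v[i]]
        )
        sim._divide(i, t=1.0)
        j = 5  # appended slot (constant-volume phase)
        after = np.array(
            [
                sim.pop.n1[i] + sim.pop.n1[j],
                sim.pop.n2[i] + sim.pop.n2[j],
                sim.pop.r1[i] + sim.pop.r1[j],
                sim.pop.r2[i] + sim.pop.r2[j],
                sim.pop.v[i] + sim.pop.v[j],
            ]
        )
        for got, want in zip(after, before):
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_interdivision_time_near_doubling_time(self, equilibrium_run):
        """Size-hazard division reproduces the doubling time within 15%."""
        ages = equilibrium_run.extras["result"].division_ages
        assert len(ages) > 1000
        assert ages.mean() == pytest.approx(10.0, rel=0.15)

    def test_composition_converges_regardless_of_initial_type(self, base_config, rates):
        cfg = replace(base_config.sim, n_initial=1500, n_cap=1500, t_end=120.0, seed=25)
        res = ap.run(rates, base_config.expr, base_config.div, cfg, initial_composition=(0, 0, 0, 1.0))
        comp = ap.composition_fractions(res.final)
        assert comp == pytest.approx([0.14, 0.28, 0.28, 0.30], abs=0.05)


class TestInitialization:
    def test_contents_start_at_pattern_steady_state(self, expr, div):
        pop = initialize_population(
            50, (0, 0, 1.0, 0), expr, div, 10.0, np.random.default_rng(30)
        )
        assert np.allclose(pop.n1[:50], expr.s_off / expr.gamma_n)
        assert np.allclose(pop.n2[:50], expr.s_on / expr.gamma_n)
        assert np.all(pop.r1[:50] == 0)  # no reporter inserted

    def test_knockout_silences_allele1_content(self, expr, div):
        pop = initialize_population(
            50, (1.0, 0, 0, 0), expr, div, 10.0, np.random.default_rng(31), allele1_deleted=True
        )
        assert np.allclose(pop.n1[:50], expr.s_off / expr.gamma_n)

    def test_invalid_composition_rejected(self, expr, div):
        with pytest.raises(ValueError):
            initialize_population(10, (0.5, 0.5, 0.5, 0), expr, div, 10.0, np.random.default_rng(0))
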