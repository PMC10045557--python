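"""Occupation statistics, chemical-potential solve, phase labels, condensation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fieldnet import (
    GrowthConfig,
    GrownNetwork,
    classify_phase,
    condensate_fraction,
    critical_gamma,
    dynamic_exponent,
    occupation_be,
    occupation_fd,
    occupation_mb,
    phase_report,
    solve_chemical_potential,
)

ZETA_32 = 2.612375348685488


class TestOccupations:
    def test_dynamic_exponent_unity_at_mu(self):
        assert dynamic_exponent(2.5, beta=3.0, mu=2.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("gap, expected", [(math.log(2), 0.5), (-math.log(2), 2.0)])
    def test_dynamic_exponent_values(self, gap, expected):
        assert dynamic_exponent(gap, beta=1.0, mu=0.0) == pytest.approx(expected)

    def test_be_values(self):
        assert occupation_be(math.log(2), 1.0, 0.0) == pytest.approx(1.0)
        assert occupation_be(1.0, 1.0, 0.0) == pytest.approx(1 / (math.e - 1), rel=1e-12)
        assert occupation_be(60.0, 1.0, 0.0) == pytest.approx(0.0, abs=1e-20)

    def test_be_diverges_below_mu(self):
        with pytest.raises(ValueError, match="condensation"):
            occupation_be(0.0, 1.0, 0.5)

    def test_mb_values(self):
        assert occupation_mb(0.0, 2.0, 0.0) == pytest.approx(1.0)
        assert occupation_mb(math.log(2), 1.0, 0.0) == pytest.approx(0.5)
        assert occupation_mb(1.0, 1.0, 0.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_fd_values(self):
        assert occupation_fd(0.0, 5.0, 0.0) == pytest.approx(0.5)
        assert occupation_fd(math.log(2), 1.0, 0.0) == pytest.approx(1 / 3)

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(1e-3, 25.0), beta=st.floats(0.1, 10.0))
    def test_strict_ordering(self, x, beta):
        eps = x / beta  # keep beta*(eps-mu) = x > 0
        fd = occupation_fd(eps, beta, 0.0)
        mb = occupation_mb(eps, beta, 0.0)
        be = occupation_be(eps, beta, 0.0)
        assert fd < mb < be

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(1e-3, 50.0))
    def test_fd_exclusion_bound(self, x):
        assert 0.0 < occupation_fd(x, 1.0, 0.0) < 1.0

    def test_classical_limit_at_large_gap(self):
        x = 20.0
        mb = occupation_mb(x, 1.0, 0.0)
        assert abs(occupation_be(x, 1.0, 0.0) - mb) / mb < 1e-8
        assert abs(occupation_fd(x, 1.0, 0.0) - mb) / mb < 1e-8


class TestChemicalPotential:
    def test_mb_single_level_closed_form(self):
        # exp(-beta (eps - mu)) * 1 = n  =>  mu = eps + ln(n)/beta
        res = solve_chemical_potential([1.2], beta=2.0, total_occupation=3.0, statistics="mb")
        assert res.mu == pytest.approx(1.2 + math.log(3.0) / 2.0, rel=1e-9)

    @pytest.mark.parametrize("statistics", ["be", "mb", "fd"])
    def test_round_trip(self, statistics):
        rng = np.random.default_rng(0)
        eps = rng.uniform(0.0, 3.0, size=40)
        target = 20.0 if statistics != "fd" else 10.0
        res = solve_chemical_potential(eps, 1.5, target, statistics=statistics)
        assert res.occupations.sum() == pytest.approx(target, rel=1e-8)

    def test_occupation_sum_monotone_in_mu(self):
        eps = np.array([0.5, 1.0, 2.0])
        for stats, mus in [
            ("be", [-3.0, -1.0, 0.0]),
            ("mb", [-1.0, 0.0, 1.0]),
            ("fd", [-1.0, 0.0, 1.0]),
        ]:
            func = {"be": occupation_be, "mb": occupation_mb, "fd": occupation_fd}[stats]
            sums = [np.sum(func(eps, 1.0, mu)) for mu in mus]
            assert sums[0] < sums[1] < sums[2]

    def test_be_condensation_flag_by_construction(self):
        eps = np.array([0.0, 1.0, 2.0])
        capacity = sum(1 / (math.exp(e) - 1) for e in eps[1:])
        res = solve_chemical_potential(eps, 1.0, capacity * 10, statistics="be")
        assert res.condensed
        assert res.condensate_occupation == pytest.approx(capacity * 10 - capacity, rel=1e-9)
        assert res.occupations.sum() == pytest.approx(capacity * 10, rel=1e-9)

    def test_non_finite_energies_rejected(self):
        with pytest.raises(ValueError):
            solve_chemical_potential([0.0, math.inf], 1.0, 1.0)


class TestPhaseLabels:
    @pytest.mark.parametrize(
        "f, label",
        [(1.0, "bose-einstein"), (1e-3, "maxwell-boltzmann"), (1e3, "fermi-dirac"),
         (0.5, "crossover")],
    )
    def test_representative_values(self, f, label):
        assert classify_phase([f]) == label

    def test_median_is_representative(self):
        assert classify_phase([0.99, 1.0, 1.01, 5.0]) == "bose-einstein"


class TestCriticalGamma:
    def test_unit_density_cancellation(self):
        assert critical_gamma(3.7, ZETA_32, 1.0) == pytest.approx(3.7, rel=1e-9)

    def test_density_scaling(self):
        g1 = critical_gamma(1.0, 2.0)
        g8 = critical_gamma(1.0, 16.0)
        assert g8 == pytest.approx(g1 / 4.0, rel=1e-12)

    def test_reference_value(self):
        assert critical_gamma(1.0, 1.0, 1.0) == pytest.approx(ZETA_32 ** (2 / 3), rel=1e-10)

    def test_domain(self):
        with pytest.raises(ValueError):
            critical_gamma(-1.0, 1.0)


class TestCondensateFraction:
    def test_star_hub_holds_half(self):
        import networkx as nx

        g = nx.star_graph(10)
        for n in g.nodes():
            g.nodes[n]["eta"] = 0.5
            g.nodes[n]["eps"] = 1.0
            g.nodes[n]["birth_time"] = 1
        g.nodes[0]["eps"] = 0.0  # hub carries the minimum energy
        net = GrownNetwork(graph=g, config=GrowthConfig(n_nodes=11, m=1, beta=1.0))
        assert condensate_fraction(net) == pytest.approx(0.5)

    def test_relabeling_invariance(self, small_net):
        import networkx as nx

        mapping = {n: (n * 7919) % 10007 for n in small_net.graph.nodes()}
        relabeled = nx.relabel_nodes(small_net.graph, mapping)
        net2 = GrownNetwork(graph=relabeled, config=small_net.config)
        assert condensate_fraction(net2) == pytest.approx(condensate_fraction(small_net))

    def test_decays_with_size_for_equal_fitness(self):
        fracs = []
        for n in (100, 800):
            vals = []
            for seed in range(5):
                net_cfg = GrowthConfig(
                    n_nodes=n, m=2, beta=1.0, fitness_dist="dirac", seed=seed,
                    track_history=False,
                )
                from fieldnet import simulate_growth

                vals.append(condensate_fraction(simulate_growth(net_cfg)))
            fracs.append(np.mean(vals))
        assert fracs[1] < fracs[0]


class TestPhaseReport:
    def test_report_fields_consistent(self, small_net):
        rep = phase_report(small_net, statistics="be")
        assert rep.normalization == pytest.approx(small_net.degree_array().sum(), rel=1e-6)
        assert np.all(rep.occupations >= 0)
        assert 0.0 <= rep.condensate_fraction <= 1.0
        assert rep.phase_label in {
            "bose-einstein", "maxwell-boltzmann", "fermi-dirac", "crossover", "condensate",
        }
        payload = rep.to_json()
        assert "phase_label" in payload
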