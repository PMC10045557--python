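"""Graph topology invariants and trajectory dynamics classification."""

import math

import networkx as nx
import numpy as np
import pytest

from fieldnet import (
    Trajectory,
    betti_numbers,
    classify_dynamics,
    classify_trajectory,
    coherence,
    delay_embed,
    euler_characteristic,
    make_trajectory,
    wolfram_class,
    winding_numbers,
)
from fieldnet.dynamics import dominant_frequency


class TestTopology:
    def test_tree(self):
        g = nx.random_labeled_tree(12, seed=0)
        assert betti_numbers(g) == (1, 0)
        assert euler_characteristic(g) == 1

    def test_cycle(self):
        assert betti_numbers(nx.cycle_graph(9)) == (1, 1)
        assert euler_characteristic(nx.cycle_graph(9)) == 0

    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
        assert betti_numbers(g) == (2, 2)

    def test_chi_equals_v_minus_e_on_random_graphs(self):
        for seed in range(20):
            g = nx.gnp_random_graph(15, 0.2, seed=seed)
            assert euler_characteristic(g) == g.number_of_nodes() - g.number_of_edges()

    def test_chi_relabeling_invariance(self):
        g = nx.gnp_random_graph(10, 0.3, seed=1)
        h = nx.relabel_nodes(g, {n: n * 31 % 101 for n in g.nodes()})
        assert euler_characteristic(g) == euler_characteristic(h)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            betti_numbers(nx.Graph())


class TestTrajectoryContainer:
    def test_length_and_finiteness_validation(self):
        t = np.arange(10) / 10
        with pytest.raises(ValueError):
            Trajectory(t=t, x=t, y=t, z=t, fs=10)
        t = np.arange(100) / 10
        bad = t.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError):
            Trajectory(t=t, x=bad, y=t, z=t, fs=10)

    def test_csv_round_trip(self, tmp_path):
        traj = make_trajectory("periodic", fs=100, duration=6, seed=0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert back.fs == pytest.approx(traj.fs)
        assert np.allclose(back.x, traj.x)


class TestWinding:
    def test_integer_triple_recovery(self):
        traj = make_trajectory("periodic", fs=100, duration=20, seed=0, noise_sd=0.01)
        ratios, verdict = winding_numbers(traj)
        assert verdict == "rational"
        assert np.allclose(ratios, (1.0, 1.5, 2.5), atol=1e-3)

    def test_identical_signals_unity_ratio(self):
        t = np.arange(2000) / 100
        s = np.sin(2 * math.pi * 3.0 * t)
        traj = Trajectory(t=t, x=s, y=s.copy(), z=s.copy(), fs=100)
        ratios, verdict = winding_numbers(traj)
        assert verdict == "rational"
        assert np.allclose(ratios, 1.0, atol=1e-6)

    def test_golden_ratio_triple_is_irrational(self):
        traj = make_trajectory("quasiperiodic", fs=100, duration=40, seed=1, noise_sd=0.01)
        _, verdict = winding_numbers(traj)
        assert verdict == "irrational"

    @pytest.mark.parametrize("num, den", [(2, 1), (3, 2), (5, 4), (7, 8)])
    def test_small_denominator_recovery_with_noise(self, num, den):
        # 20 dB signal-to-noise: noise sd = 10^(-20/20) * signal rms
        fs, dur = 100.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        rng = np.random.default_rng(5)
        sd = math.sqrt(0.5) * 0.1
        base = 4.0
        x = np.sin(2 * math.pi * base * t) + rng.normal(0, sd, len(t))
        y = np.sin(2 * math.pi * base * num / den * t) + rng.normal(0, sd, len(t))
        z = np.sin(2 * math.pi * base * 2 * t) + rng.normal(0, sd, len(t))
        ratios, verdict = winding_numbers(Trajectory(t=t, x=x, y=y, z=z, fs=fs))
        assert verdict == "rational"
        freqs = np.array([base, base * num / den, base * 2])
        expected = freqs / freqs.min()
        assert np.allclose(ratios, expected, atol=1e-3)

    def test_constant_dimension_rejected(self):
        t = np.arange(1000) / 100
        s = np.sin(2 * math.pi * t)
        with pytest.raises(ValueError):
            winding_numbers(Trajectory(t=t, x=s, y=np.ones_like(t), z=s, fs=100))

    def test_dominant_frequency_accuracy(self):
        t = np.arange(4000) / 100
        f_true = 7.37
        assert dominant_frequency(np.sin(2 * math.pi * f_true * t), 100.0) == pytest.approx(
            f_true, abs=1e-3
        )


class TestCoherence:
    def test_identical_signals_maximal(self):
        t = np.arange(2000) / 100
        s = np.sin(2 * math.pi * 5 * t)
        traj = Trajectory(t=t, x=s, y=s.copy(), z=s.copy(), fs=100)
        assert coherence(traj) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        n = 10_000
        traj = Trajectory(
            t=np.arange(n) / 100,
            x=rng.normal(size=n),
            y=rng.normal(size=n),
            z=rng.normal(size=n),
            fs=100,
        )
        assert coherence(traj) < 0.05

    def test_bounded_on_random_trajectories(self):
        rng = np.random.default_rng(17)
        n = 720
        t = np.arange(n) / 100
        for _ in range(500):
            freqs = rng.uniform(1.0, 40.0, size=3)
            amps = rng.uniform(0.5, 2.0, size=3)
            noise = rng.uniform(0.0, 1.0)
            dims = [
                a * np.sin(2 * math.pi * f * t + rng.uniform(0, 2 * math.pi))
                + noise * rng.normal(size=n)
                for a, f in zip(amps, freqs)
            ]
            k = coherence(Trajectory(t=t, x=dims[0], y=dims[1], z=dims[2], fs=100))
            assert 0.0 <= k <= 1.0

    def test_too_short_rejected(self):
        t = np.arange(64) / 100
        s = np.sin(2 * math.pi * 5 * t)
        with pytest.raises(ValueError):
            coherence(Trajectory(t=t, x=s, y=s, z=s, fs=100))


class TestClassification:
    @pytest.mark.parametrize(
        "rationality, k, expected",
        [
            ("rational", 0.9, "periodic"),
            ("irrational", 0.1, "quasiperiodic"),
            ("irrational", 0.6, "chaotic"),
        ],
    )
    def test_decision_table(self, rationality, k, expected):
        assert classify_dynamics(rationality, k) == expected

    def test_fixed_point_short_circuits(self):
        assert classify_dynamics("rational", 0.0, fixed_point=True) == "fixed-point"

    @pytest.mark.parametrize(
        "dclass, wclass",
        [
            ("fixed-point", "I"),
            ("periodic", "II"),
            ("chaotic", "III"),
            ("quasiperiodic", "IV"),
        ],
    )
    def test_wolfram_mapping(self, dclass, wclass):
        assert wolfram_class(dclass) == wclass

    def test_wolfram_rejects_unknown(self):
        with pytest.raises(ValueError):
            wolfram_class("strange")

    def test_fixed_point_fixture_class_one(self):
        rep = classify_trajectory(make_trajectory("fixed-point", fs=100, duration=6))
        assert rep.dynamics_class == "fixed-point"
        assert rep.wolfram_class == "I"

    def test_periodic_fixture_class_two(self):
        rep = classify_trajectory(make_trajectory("periodic", fs=100, duration=20, noise_sd=0.01))
        assert rep.dynamics_class == "periodic"
        assert rep.wolfram_class == "II"

    def test_quasiperiodic_fixture_class_four(self):
        rep = classify_trajectory(
            make_trajectory("quasiperiodic", fs=100, duration=40, seed=2, noise_sd=0.01)
        )
        assert rep.dynamics_class == "quasiperiodic"
        assert rep.wolfram_class == "IV"


class TestDelayEmbedding:
    def test_dim_one_is_identity(self):
        x = np.arange(50.0)
        assert np.array_equal(delay_embed(x, 1, 3)[:, 0], x)

    def test_shape_arithmetic(self):
        emb = delay_embed(np.arange(100.0), 3, 10)
        assert emb.shape == (80, 3)

    def test_bounded_values_preserved(self):
        t = np.arange(500) / 100
        emb = delay_embed(np.sin(2 * math.pi * 2 * t), 3, 7)
        assert np.max(np.abs(emb)) <= 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            delay_embed(np.arange(10.0), 3, 5)
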