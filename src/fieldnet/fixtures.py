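"""Deterministic synthetic inputs: fitness samples, trajectories, rate series, graphs.

Everything the analysis surface consumes can be generated here with a fixed
seed; identical specs produce identical output, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dynamics import Trajectory
from .kinetics import arrhenius_rate, RateParams

__all__ = [
    "FixtureSpec",
    "make_fitness_samples",
    "make_trajectory",
    "make_rate_series",
    "make_graph",
    "GOLDEN_RATIO",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

#: chaotic-coupled fixture: three identical time-scaled Rossler oscillators,
#: diffusively coupled in x above the phase-coherence onset (but below complete
#: synchronization, so the three dominant frequencies stay distinct).  All
#: values pinned so the fixture, and everything computed from it, is
#: deterministic.
ROSSLER_PARAMS = (0.28, 0.1, 8.5)  # (a, b, c): funnel (non-phase-coherent) regime
ROSSLER_TIMESCALE = 50.0  # natural-time units per second of signal
CHAOTIC_COUPLING = 0.085
CHAOTIC_ICS = np.array(
    [
        [1.0, 1.0, 0.1],
        [-3.0, 2.0, 0.2],
        [4.0, -1.5, 0.3],
    ]
)
CHAOTIC_TRANSIENT = 5.0  # seconds of signal discarded before recording


@dataclass
class FixtureSpec:
    """What to generate: kind, per-kind parameters, and the RNG seed."""

    kind: str  # fitness-dist | trajectory | rate-series | graph
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def make_fitness_samples(spec: FixtureSpec | None = None, *, family: str | None = None,
                         n: int = 100, seed: int = 0, **params) -> np.ndarray:
    """Sample node fitness values from a named family.

    Families: ``uniform`` on (0, 1]; ``exponential(rate)``; ``dirac(value)``;
    ``truncated-power(exponent)``: reference energy drawn with power density
    ``(theta+1) eps^theta`` on [0, 1] and mapped through ``eta = exp(-eps)``,
    packing all fitness mass into [1/e, 1] (condensation-prone).
    """
    if spec is not None:
        family = spec.parameters.get("family", family)
        n = spec.parameters.get("n", n)
        seed = spec.seed
        params = {k: v for k, v in spec.parameters.items() if k not in ("family", "n")}
    rng = np.random.default_rng(seed)
    if family == "uniform":
        return 1.0 - rng.random(n)
    if family == "exponential":
        rate = float(params.get("rate", 1.0))
        return rng.exponential(1.0 / rate, size=n)
    if family == "dirac":
        return np.full(n, float(params.get("value", 1.0)))
    if family == "truncated-power":
        theta = float(params.get("exponent", 1.0))
        return np.exp(-(rng.random(n) ** (1.0 / (theta + 1.0))))
    raise ValueError(f"unknown fitness family {family!r}")


def _coupled_rossler(fs: float, duration: float, coupling: float) -> np.ndarray:
    """Fixed-step RK4 integration of three x-coupled Rossler oscillators.

    Returns the x-components, shape (n_samples, 3).  Deterministic: fixed
    initial conditions, fixed step, no noise.
    """
    a, b, c = ROSSLER_PARAMS
    omega = ROSSLER_TIMESCALE
    n_record = int(round(fs * duration))
    n_transient = int(round(fs * CHAOTIC_TRANSIENT))
    dt_signal = 1.0 / fs
    # keep the natural-time RK4 step near 0.02 for accuracy
    n_sub = max(1, int(math.ceil(omega * dt_signal / 0.02)))
    h = dt_signal / n_sub

    state = CHAOTIC_ICS.copy()  # rows: oscillators; cols: (x, y, z)

    def rhs(s: np.ndarray) -> np.ndarray:
        x, y, z = s[:, 0], s[:, 1], s[:, 2]
        # all-to-all diffusive coupling in x
        coup = coupling * (x.sum() - 3 * x)
        dx = -y - z + coup
        dy = x + a * y
        dz = b + z * (x - c)
        return omega * np.column_stack([dx, dy, dz])

    out = np.empty((n_record, 3))
    for i in range(n_transient + n_record):
        for _ in range(n_sub):
            k1 = rhs(state)
            k2 = rhs(state + 0.5 * h * k1)
            k3 = rhs(state + 0.5 * h * k2)
            k4 = rhs(state + h * k3)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= n_transient:
            out[i - n_transient] = state[:, 0]
    return out


def make_trajectory(kind: str, fs: float = 100.0, duration: float = 20.0,
                    seed: int = 0, noise_sd: float = 0.0) -> Trajectory:
    """Generate a 3-D state-space trajectory of a named dynamics class.

    ``fixed-point``: constant coordinates.  ``periodic``: sinusoids at
    2 : 3 : 5 frequency ratio.  ``quasiperiodic``: incommensurate frequencies
    (1, phi, phi^2) scaled to a 4 Hz base.  ``chaotic-coupled``: three
    diffusively coupled identical chaotic oscillators (deterministic; the
    seed only affects optional measurement noise).
    """
    n = int(round(fs * duration))
    if n < 512:
        raise ValueError("need fs * duration >= 512 samples")
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    if kind == "fixed-point":
        x = np.full(n, 1.0)
        y = np.full(n, -0.5)
        z = np.full(n, 2.0)
        return Trajectory(t=t, x=x, y=y, z=z, fs=fs)
    if kind == "periodic":
        base = 1.0  # 2, 3, 5 Hz at the default sampling rate
        fx, fy, fz = 2.0 * base, 3.0 * base, 5.0 * base
    elif kind == "quasiperiodic":
        base = 4.0
        fx, fy, fz = base, base * GOLDEN_RATIO, base * GOLDEN_RATIO**2
    elif kind == "chaotic-coupled":
        xyz = _coupled_rossler(fs, duration, CHAOTIC_COUPLING)
        if noise_sd > 0:
            xyz = xyz + rng.normal(0.0, noise_sd * xyz.std(), xyz.shape)
        return Trajectory(t=t, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2], fs=fs)
    else:
        raise ValueError(f"unknown trajectory class {kind!r}")

    if max(fx, fy, fz) >= fs / 2:
        raise ValueError("sampling rate too low for the generated frequencies")
    x = np.sin(2 * math.pi * fx * t)
    y = np.sin(2 * math.pi * fy * t + 0.7)
    z = np.sin(2 * math.pi * fz * t + 1.9)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
        y = y + rng.normal(0.0, noise_sd, n)
        z = z + rng.normal(0.0, noise_sd, n)
    return Trajectory(t=t, x=x, y=y, z=z, fs=fs)


def make_rate_series(e_a: float, a_prefactor: float, temps,
                     tunneling_floor: float = 0.0, r_gas: float = 1.0) -> np.ndarray:
    """Arrhenius rate series ``k(T) = A exp(-E_a / (R T)) + floor``.

    A zero floor gives exactly classical kinetics; a temperature-independent
    tunneling floor makes the Arrhenius plot curve at low temperature.
    """
    temps = np.asarray(temps, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive")
    if np.any(np.diff(temps) < 0):
        raise ValueError("temperatures must be sorted ascending")
    rates = np.array(
        [
            arrhenius_rate(RateParams(a_prefactor=a_prefactor, e_a=e_a,
                                      r_gas=r_gas, temp=float(T)))
            for T in temps
        ]
    )
    return rates + tunneling_floor


def make_graph(kind: str, n: int = 8, seed: int = 0, p: float = 0.3) -> nx.Graph:
    """Small labelled test graphs: tree, cycle, path, star, disjoint-triangles, gnp."""
    if kind == "tree":
        g = nx.random_labeled_tree(n, seed=seed)
    elif kind == "cycle":
        g = nx.cycle_graph(n)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "star":
        g = nx.star_graph(n)
    elif kind == "disjoint-triangles":
        g = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
    elif kind == "gnp":
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    rng = np.random.default_rng(seed)
    for node in g.nodes():
        eta = 1.0 - rng.random()
        g.nodes[node]["eta"] = eta
        g.nodes[node]["eps"] = -math.log(eta)
        g.nodes[node]["birth_time"] = 1
    return g
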