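"""Fitness-driven preferential-attachment growth of neural-field networks.

Each node ``i`` carries a fitness ``eta_i >= 0`` and an energy level
``eps_i = -(1/beta) * log(eta_i)``; the probability that an entrant links to an
existing node is ``Pi_i = eta_i * k_i / sum_l eta_l * k_l``.  Inverse
temperature ``beta`` controls the statistical phase of the grown network:
small ``beta`` flattens fitness differences towards classical (Barabasi-Albert)
preferential attachment, large ``beta`` amplifies them towards a
winner-take-most condensate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np

__all__ = [
    "FieldNode",
    "GrowthConfig",
    "GrownNetwork",
    "fitness_to_energy",
    "energy_to_fitness",
    "attachment_probabilities",
    "grow_step",
    "simulate_growth",
    "expected_degree",
    "fitness_from_payoff",
]

_FITNESS_FAMILIES = ("uniform", "exponential", "dirac", "truncated-power")


def fitness_to_energy(eta: float, beta: float) -> float:
    """Map a fitness value onto its energy level, ``eps = -(1/beta) * ln(eta)``.

    Parameters
    ----------
    eta : float
        Node fitness, must be strictly positive (a zero-fitness node has no
        finite energy level).
    beta : float
        Inverse temperature, strictly positive.
    """
    eta = float(eta)
    beta = float(beta)
    if eta <= 0:
        raise ValueError("zero-fitness node has no finite energy (eta must be > 0)")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return -math.log(eta) / beta


def energy_to_fitness(eps: float, beta: float) -> float:
    """Inverse of :func:`fitness_to_energy`: ``eta = exp(-beta * eps)``."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return math.exp(-beta * float(eps))


def fitness_from_payoff(p_i: float, P_i: float) -> float:
    """Fitness allocated from a selection probability and a perceived payoff.

    ``eta_i = |p_i * P_i|`` where ``p_i`` is the (Bayesian) probability that
    the node is chosen and ``P_i`` the signed perceived net payoff.
    """
    p_i = float(p_i)
    if not 0.0 <= p_i <= 1.0:
        raise ValueError("selection probability p_i must lie in [0, 1]")
    return abs(p_i * float(P_i))


@dataclass
class FieldNode:
    """A network node: integer id, fitness, energy, degree and birth step."""

    id: int
    eta: float
    eps: float
    degree: int = 0
    birth_time: int = 1

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("fitness eta must be >= 0")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.birth_time < 1:
            raise ValueError("birth_time must be >= 1")


@dataclass
class GrowthConfig:
    """Configuration of a growth run.

    ``fitness_dist`` names the quenched-disorder family sampled at reference
    inverse temperature beta = 1 (equivalently an energy density through
    ``eps = -ln(eta0)``); the operative fitness at inverse temperature ``beta``
    is ``eta = eta0 ** beta``, so ``eps = -(1/beta) ln(eta)`` always holds.
    Exactly one of ``beta`` or ``gamma`` must be given; when the annealing
    parameter ``gamma`` is used, ``beta = 1/gamma``.
    """

    n_nodes: int
    m: int = 1
    beta: float | None = None
    gamma: float | None = None
    fitness_dist: str = "uniform"
    dist_params: tuple = ()
    seed: int = 0
    track_history: bool = True
    track_probabilities: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_nodes <= self.m:
            raise ValueError("n_nodes must exceed m")
        if (self.beta is None) == (self.gamma is None):
            raise ValueError("exactly one of beta or gamma must be set")
        if self.gamma is not None:
            if self.gamma <= 0:
                raise ValueError("gamma must be > 0")
            self.beta = 1.0 / self.gamma
        if self.beta is None or self.beta <= 0:
            raise ValueError("beta must be > 0")
        family = self.fitness_dist.split(":")[0]
        if family not in _FITNESS_FAMILIES:
            raise ValueError(
                f"unknown fitness family {family!r}; expected one of {_FITNESS_FAMILIES}"
            )


@dataclass
class GrownNetwork:
    """An evolving graph plus per-step degree records.

    ``degree_history`` stores one ``(step, node_id, degree)`` event for every
    degree change, from which the complete per-step degree of every node can be
    reconstructed (see :meth:`degree_matrix`).  ``prob_history`` records the
    attachment-probability vector seen by each entrant (padded with zeros for
    nodes born later).  Node ids are consecutive integers starting at 0.
    """

    graph: nx.Graph
    config: GrowthConfig
    degree_history: list = field(default_factory=list)
    prob_history: list = field(default_factory=list)
    step: int = 0
    # growth-loop caches, kept in step with the graph by grow_step
    _eta: list = field(default_factory=list, repr=False)
    _eps: list = field(default_factory=list, repr=False)
    _deg: list = field(default_factory=list, repr=False)

    @property
    def nodes(self) -> list[FieldNode]:
        return [
            FieldNode(
                id=n,
                eta=d["eta"],
                eps=d["eps"],
                degree=self.graph.degree(n),
                birth_time=max(d["birth_time"], 1),
            )
            for n, d in self.graph.nodes(data=True)
        ]

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for e in self.graph.edges()]

    def eta_array(self) -> np.ndarray:
        if self._eta:
            return np.asarray(self._eta, dtype=float)
        return np.array([d["eta"] for _, d in self.graph.nodes(data=True)], dtype=float)

    def eps_array(self) -> np.ndarray:
        if self._eps:
            return np.asarray(self._eps, dtype=float)
        return np.array([d["eps"] for _, d in self.graph.nodes(data=True)], dtype=float)

    def degree_array(self) -> np.ndarray:
        if self._deg:
            return np.asarray(self._deg, dtype=np.int64)
        return np.array([self.graph.degree(n) for n in self.graph.nodes()], dtype=np.int64)

    def birth_times(self) -> np.ndarray:
        return np.array([d["birth_time"] for _, d in self.graph.nodes(data=True)], dtype=np.int64)

    def degree_matrix(self) -> np.ndarray:
        """Reconstruct the (n_steps + 1) x n_nodes per-step degree table.

        Row ``s`` holds every node's degree after growth step ``s`` (row 0 is
        the seed graph); nodes not yet born have degree 0.
        """
        n = self.graph.number_of_nodes()
        mat = np.zeros((self.step + 1, n), dtype=np.int64)
        for s, node, deg in self.degree_history:
            mat[s:, node] = deg
        return mat

    def degree_at(self, node: int, step: int) -> int:
        """Degree of ``node`` after growth step ``step`` (0 = seed graph)."""
        deg = 0
        for s, nid, d in self.degree_history:
            if s > step:
                break
            if nid == node:
                deg = d
        return deg

    def prob_matrix(self) -> np.ndarray:
        """Attachment-probability history as a steps x nodes array, zero-padded."""
        n = self.graph.number_of_nodes()
        mat = np.zeros((len(self.prob_history), n))
        for s, vec in enumerate(self.prob_history):
            mat[s, : len(vec)] = vec
        return mat


def _sampler(config: GrowthConfig) -> Callable[[np.random.Generator], float]:
    """Return a single-draw sampler of the reference fitness eta0."""
    parts = config.fitness_dist.split(":")
    family = parts[0]
    if config.dist_params:
        params: tuple = tuple(config.dist_params)
    elif len(parts) > 1:
        params = tuple(float(x) for x in parts[1].split(","))
    else:
        params = ()

    if family == "uniform":
        # uniform on (0, 1]
        return lambda rng: 1.0 - rng.random()
    if family == "exponential":
        rate = float(params[0]) if params else 1.0
        return lambda rng: rng.exponential(1.0 / rate)
    if family == "dirac":
        value = float(params[0]) if params else 1.0
        return lambda rng: value
    if family == "truncated-power":
        # condensation-prone family: reference energy eps0 with power density
        # (theta+1) * eps^theta on [0, 1] (vanishing at the band bottom), so
        # eta0 = exp(-eps0) packs all fitness mass into [1/e, 1], hugging the
        # maximum while the density still vanishes exactly at eta = 1 -- the
        # condition for Bose-Einstein condensation at low temperature
        theta = float(params[0]) if params else 1.0
        return lambda rng: math.exp(-(rng.random() ** (1.0 / (theta + 1.0))))
    raise ValueError(f"unknown fitness family {family!r}")


def _draw_fitness(config: GrowthConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (eta, eps) at the configured inverse temperature."""
    eta0 = _sampler(config)(rng)
    if eta0 <= 0:
        eta0 = float(np.finfo(float).tiny)
    eps0 = -math.log(eta0)  # quenched reference-temperature energy
    eta = math.exp(-config.beta * eps0)
    eps = eps0  # eps = -(1/beta) ln eta  ==  eps0 exactly
    return eta, eps


def attachment_probabilities(network: GrownNetwork) -> np.ndarray:
    """Per-node probability of receiving the next link, ``eta_i k_i / sum``."""
    w = network.eta_array() * network.degree_array()
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate network: all eta_i * k_i are zero")
    return w / total


def _ensure_cache(network: GrownNetwork) -> None:
    if not network._eta:
        for _, d in network.graph.nodes(data=True):
            network._eta.append(d["eta"])
            network._eps.append(d["eps"])
        for n in network.graph.nodes():
            network._deg.append(network.graph.degree(n))


def grow_step(network: GrownNetwork, rng: np.random.Generator) -> GrownNetwork:
    """Add one entrant node with ``m`` distinct edges sampled by fitness.

    Targets are drawn without replacement with probability proportional to
    ``eta_i * k_i``; repeat selections never create multi-edges or self-loops.
    Mutates and returns ``network``.
    """
    _ensure_cache(network)
    g = network.graph
    m = network.config.m
    eta = np.asarray(network._eta)
    deg = np.asarray(network._deg, dtype=float)
    w = eta * deg
    attachable = int((w > 0).sum())
    if attachable < m:
        raise RuntimeError(f"fewer than m={m} attachable targets ({attachable})")

    total = w.sum()
    if network.config.track_probabilities:
        network.prob_history.append(w / total)

    targets: list[int] = []
    for _ in range(m):
        cum = np.cumsum(w)
        u = rng.random() * cum[-1]
        idx = int(np.searchsorted(cum, u, side="right"))
        idx = min(idx, len(w) - 1)
        targets.append(idx)
        w[idx] = 0.0  # without replacement: no multi-edges

    network.step += 1
    new_id = len(network._eta)
    eta_new, eps_new = _draw_fitness(network.config, rng)
    g.add_node(new_id, eta=eta_new, eps=eps_new, birth_time=network.step)
    network._eta.append(eta_new)
    network._eps.append(eps_new)
    network._deg.append(0)
    for t in targets:
        g.add_edge(new_id, t)
        network._deg[t] += 1
        network._deg[new_id] += 1

    if network.config.track_history:
        for t in targets:
            network.degree_history.append((network.step, t, network._deg[t]))
        network.degree_history.append((network.step, new_id, network._deg[new_id]))
    return network


def simulate_growth(config: GrowthConfig) -> GrownNetwork:
    """Grow a network from a complete seed graph on ``m + 1`` nodes.

    Seed nodes receive fitness drawn from the configured family and birth
    time 1; every subsequent step adds one node with ``m`` edges, so after
    ``t`` steps the edge count is ``m(m+1)/2 + m*t``.  Two runs with the same
    config (and seed) produce identical networks.
    """
    rng = np.random.default_rng(config.seed)
    g = nx.Graph()
    net = GrownNetwork(graph=g, config=config)
    for i in range(config.m + 1):
        eta, eps = _draw_fitness(config, rng)
        g.add_node(i, eta=eta, eps=eps, birth_time=1)
        net._eta.append(eta)
        net._eps.append(eps)
        net._deg.append(0)
    for i in range(config.m + 1):
        for j in range(i + 1, config.m + 1):
            g.add_edge(i, j)
            net._deg[i] += 1
            net._deg[j] += 1

    if config.track_history:
        for i in range(config.m + 1):
            net.degree_history.append((0, i, net._deg[i]))

    while g.number_of_nodes() < config.n_nodes:
        grow_step(net, rng)
    return net


def expected_degree(m: int, t: float, t_i: float, f_eps: float) -> float:
    """Ensemble-expected degree ``m * (t / t_i) ** f_eps`` of a node born at ``t_i``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if t_i < 1 or t < t_i:
        raise ValueError("need t >= t_i >= 1")
    if f_eps < 0:
        raise ValueError("dynamic exponent must be >= 0")
    return m * (t / t_i) ** f_eps
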