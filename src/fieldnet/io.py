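"""Reading and writing networks, histories and reports.

GraphML is the canonical attribute-rich network format (node attributes
``eta``, ``eps``, ``birth_time``, optional layout ``x``/``y``); a plain
two-column edge list plus node-attribute CSV is the lightweight dialect.
Every writer embeds provenance metadata (package version, seed, config).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .growth import GrowthConfig, GrownNetwork, fitness_to_energy, energy_to_fitness

__all__ = [
    "write_network",
    "read_network",
    "write_degree_history",
    "read_rate_series",
]


def _provenance(config: GrowthConfig | None) -> dict:
    meta = {"fieldnet_version": __version__}
    if config is not None:
        meta["seed"] = config.seed
        meta["config"] = json.dumps(
            {
                "n_nodes": config.n_nodes,
                "m": config.m,
                "beta": config.beta,
                "fitness_dist": config.fitness_dist,
                "seed": config.seed,
            }
        )
    return meta


def write_network(network: GrownNetwork | nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or as edge-list + node-attribute CSV pair."""
    g = network.graph if isinstance(network, GrownNetwork) else network
    config = network.config if isinstance(network, GrownNetwork) else None
    path = Path(path)
    if fmt == "graphml":
        g = g.copy()
        for key, val in _provenance(config).items():
            g.graph[key] = val
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in g.edges()),
                             columns=["source", "target"])
        edges.to_csv(path, index=False)
        nodes = pd.DataFrame(
            [
                {"id": n, **{k: d.get(k) for k in ("eta", "eps", "birth_time")}}
                for n, d in g.nodes(data=True)
            ]
        )
        nodes.to_csv(path.with_suffix(".nodes.csv"), index=False)
    else:
        raise ValueError("fmt must be 'graphml' or 'edgelist'")


def read_network(path, fmt: str = "graphml", beta: float | None = None) -> GrownNetwork:
    """Read a network; derive ``eps`` from ``eta`` (or vice versa) when beta given.

    Duplicate edges in an edge list are deduplicated; a file carrying neither
    ``eta`` nor ``eps`` raises a schema error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        for n, d in raw.nodes(data=True):
            g.add_node(int(n) if str(n).lstrip("-").isdigit() else n, **d)
        for u, v in raw.edges():
            cu = int(u) if str(u).lstrip("-").isdigit() else u
            cv = int(v) if str(v).lstrip("-").isdigit() else v
            g.add_edge(cu, cv)
    elif fmt == "edgelist":
        edges = pd.read_csv(path)
        g = nx.Graph()
        g.add_edges_from(
            edges[["source", "target"]].itertuples(index=False, name=None)
        )
        nodes_path = path.with_suffix(".nodes.csv")
        if nodes_path.exists():
            for row in pd.read_csv(nodes_path).itertuples(index=False):
                attrs = {
                    k: v for k, v in row._asdict().items()
                    if k != "id" and v is not None and not (isinstance(v, float) and np.isnan(v))
                }
                if row.id not in g:
                    g.add_node(row.id)
                g.nodes[row.id].update(attrs)
    else:
        raise ValueError("fmt must be 'graphml' or 'edgelist'")

    for n, d in g.nodes(data=True):
        has_eta = "eta" in d and d["eta"] is not None
        has_eps = "eps" in d and d["eps"] is not None
        if not has_eta and not has_eps:
            raise ValueError(f"node {n!r} carries neither eta nor eps")
        if has_eta and not has_eps:
            if beta is None:
                raise ValueError("deriving eps from eta requires beta")
            d["eps"] = fitness_to_energy(float(d["eta"]), beta)
        if has_eps and not has_eta:
            if beta is None:
                raise ValueError("deriving eta from eps requires beta")
            d["eta"] = energy_to_fitness(float(d["eps"]), beta)
        d.setdefault("birth_time", 1)

    cfg_beta = beta if beta is not None else 1.0
    config = GrowthConfig(
        n_nodes=max(g.number_of_nodes(), 2), m=1, beta=cfg_beta, track_history=False
    )
    return GrownNetwork(graph=g, config=config)


def write_degree_history(network: GrownNetwork, path) -> None:
    """Long-format CSV of the per-step degree record (step, node_id, degree)."""
    pd.DataFrame(network.degree_history,
                 columns=["step", "node_id", "degree"]).to_csv(path, index=False)


def read_rate_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column CSV (temperature, rate) -> (temps, rates)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    tcol = "temperature" if "temperature" in cols else cols[0]
    kcol = "rate" if "rate" in cols else cols[1]
    return df[tcol].to_numpy(dtype=float), df[kcol].to_numpy(dtype=float)
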