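"""Potential landscapes, geodesic path lengths, and Laplacian eigenmodes.

A grown network is laid out in the plane (deterministic force-directed
embedding unless coordinates are supplied) and its node energies are
interpolated into a potential surface ``V(x, y)`` that passes exactly through
every node's energy level.  Path lengths under a supplied Riemannian metric
``g_ij`` are evaluated segment-wise, and spatial structure is decomposed into
eigenmodes of the combinatorial graph Laplacian (or a 5-point grid Laplacian),
the discrete counterparts of Helmholtz modes ``-lap u = k^2 u``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import eigh

__all__ = [
    "Landscape",
    "MetricField",
    "EigenmodeSet",
    "landscape",
    "geodesic_length",
    "laplacian_eigenmodes",
    "grid_laplacian",
    "force_layout",
]


@dataclass
class Landscape:
    """Gridded potential surface anchored at per-node energies."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    potential: np.ndarray
    node_layout: np.ndarray  # n x 2 planar coordinates
    node_values: np.ndarray  # eps at each node
    bandwidth: float

    def value_at(self, points) -> np.ndarray:
        """Evaluate the interpolant at arbitrary planar points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        phi = _kernel_matrix(pts, self.node_layout, self.bandwidth)
        return phi @ self.node_values


@dataclass
class MetricField:
    """A (possibly position-dependent) symmetric positive-definite metric."""

    metric: np.ndarray | callable

    def at(self, point: np.ndarray) -> np.ndarray:
        g = self.metric(point) if callable(self.metric) else self.metric
        g = np.asarray(g, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("metric must be a square matrix")
        if not np.allclose(g, g.T, atol=1e-12):
            raise ValueError("metric must be symmetric")
        if np.any(np.linalg.eigvalsh(g) <= 0):
            raise ValueError("metric must be positive-definite")
        return g


@dataclass
class EigenmodeSet:
    """Ascending Laplacian eigenpairs; zero eigenvalues count components."""

    eigenvalues: np.ndarray
    modes: np.ndarray  # columns are eigenvectors
    operator_kind: str  # graph-laplacian | grid-laplacian

    def n_zero(self, tol: float = 1e-10) -> int:
        return int(np.sum(self.eigenvalues < tol))


def force_layout(graph: nx.Graph, seed: int = 0) -> np.ndarray:
    """Deterministic seeded force-directed planar embedding."""
    pos = nx.spring_layout(graph, seed=seed)
    return np.array([pos[n] for n in graph.nodes()])


def _kernel_matrix(pts_a: np.ndarray, pts_b: np.ndarray, bandwidth: float) -> np.ndarray:
    """Normalized singular-Gaussian (modified Shepard) kernel weights.

    Rows form a convex combination over the anchors, and the ``1/d^2``
    singularity makes the interpolant pass exactly through every anchor value
    at any bandwidth — no linear solve, so no conditioning failure.
    """
    d2 = np.sum((pts_a[:, None, :] - pts_b[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore", over="ignore"):
        phi = np.exp(-d2 / (2.0 * bandwidth**2)) / d2
    hit = d2 < 1e-24  # evaluation point coincides with an anchor
    rows_hit = hit.any(axis=1)
    phi[rows_hit] = 0.0
    phi[hit] = 1.0
    # far-field underflow: fall back to the nearest anchor
    row_sums = phi.sum(axis=1, keepdims=True)
    dead = ~np.isfinite(row_sums[:, 0]) | (row_sums[:, 0] == 0)
    if dead.any():
        nearest = np.argmin(d2[dead], axis=1)
        phi[dead] = 0.0
        phi[np.nonzero(dead)[0], nearest] = 1.0
        row_sums = phi.sum(axis=1, keepdims=True)
    return phi / row_sums


def landscape(
    network,
    layout: np.ndarray | None = None,
    bandwidth: float | None = None,
    grid_size: int = 64,
    seed: int = 0,
    padding: float = 0.15,
) -> Landscape:
    """Interpolate node energies into a potential surface ``V(x, y)``.

    Normalized singular-Gaussian kernels are anchored at the node coordinates,
    so the surface passes through each node's energy exactly at any bandwidth
    and, being a convex combination of node energies, never dips below the
    band bottom.  Bandwidth defaults to half the median nearest-neighbour
    distance of the layout.
    """
    g = network if isinstance(network, nx.Graph) else network.graph
    eps = np.array([d["eps"] for _, d in g.nodes(data=True)], dtype=float)
    if eps.size == 0 or not np.all(np.isfinite(eps)):
        raise ValueError("every node needs a finite energy eps")
    if layout is None:
        layout = force_layout(g, seed=seed)
    layout = np.asarray(layout, dtype=float)

    if bandwidth is None:
        if len(layout) > 1:
            d2 = np.sum((layout[:, None] - layout[None, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            nn = np.sqrt(d2.min(axis=1))
            bandwidth = max(float(np.median(nn)) / 2.0, 1e-12)
        else:
            bandwidth = 1.0

    span_x = np.ptp(layout[:, 0]) or 1.0
    span_y = np.ptp(layout[:, 1]) or 1.0
    xs = np.linspace(layout[:, 0].min() - padding * span_x,
                     layout[:, 0].max() + padding * span_x, grid_size)
    ys = np.linspace(layout[:, 1].min() - padding * span_y,
                     layout[:, 1].max() + padding * span_y, grid_size)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    v = (_kernel_matrix(pts, layout, bandwidth) @ eps).reshape(gx.shape)

    return Landscape(
        grid_x=gx, grid_y=gy, potential=v,
        node_layout=layout, node_values=eps, bandwidth=bandwidth,
    )


def geodesic_length(metric: MetricField, path) -> float:
    """Polyline length ``sum_segments sqrt(dx^T g dx)``, g at segment midpoints.

    Reduces to Euclidean length under the identity metric.
    """
    pts = np.atleast_2d(np.asarray(path, dtype=float))
    if len(pts) < 2:
        raise ValueError("path needs at least two points")
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        g = metric.at((a + b) / 2.0)
        dx = b - a
        if g.shape[0] != dx.shape[0]:
            raise ValueError("metric dimension does not match path dimension")
        total += float(np.sqrt(dx @ g @ dx))
    return total


def grid_laplacian(nx_pts: int, ny_pts: int) -> np.ndarray:
    """Dense 5-point Laplacian of a rectangular grid graph."""
    g = nx.grid_2d_graph(nx_pts, ny_pts)
    return nx.laplacian_matrix(g).toarray().astype(float)


def laplacian_eigenmodes(network_or_grid, n_modes: int | None = None) -> EigenmodeSet:
    """Ascending eigenpairs of the combinatorial (or grid) Laplacian.

    The multiplicity of the zero eigenvalue equals the number of connected
    components; on a path graph, eigenvector ``j`` changes sign exactly ``j``
    times (low eigenvalues <-> spatially smooth, globally uniform modes; high
    eigenvalues <-> locally discrete structure).
    """
    if isinstance(network_or_grid, np.ndarray):
        lap = np.asarray(network_or_grid, dtype=float)
        kind = "grid-laplacian"
    else:
        g = (network_or_grid if isinstance(network_or_grid, nx.Graph)
             else network_or_grid.graph)
        if g.number_of_nodes() == 0:
            raise ValueError("empty graph has no eigenmodes")
        lap = nx.laplacian_matrix(g, nodelist=sorted(g.nodes())).toarray().astype(float)
        kind = "graph-laplacian"
    n = lap.shape[0]
    if n_modes is None:
        n_modes = n
    if n_modes > n:
        raise ValueError(f"requested {n_modes} modes from a {n}-node structure")
    vals, vecs = eigh(lap, subset_by_index=(0, n_modes - 1))
    return EigenmodeSet(eigenvalues=vals, modes=vecs, operator_kind=kind)
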