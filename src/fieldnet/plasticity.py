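"""Hebbian, nonlinear and quantum plasticity rules, plus attachment coupling.

The classical Hebbian rule averages pattern co-activations into a symmetric
weight matrix; the activation rules reduce weighted input sums (with an
optional bounded "state-overlap" normalization for the quantum variant); and
the covariance of attachment probabilities over growth steps labels node pairs
as strengthening (Hebbian-like), weakening (anti-Hebbian-like) or neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrainingSet",
    "WeightMatrix",
    "CouplingMatrix",
    "hebbian_weights",
    "activation",
    "quantum_activation",
    "attachment_covariance",
]


@dataclass
class TrainingSet:
    """p training patterns over k inputs, signed values, all finite."""

    patterns: np.ndarray

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        p, k = self.patterns.shape
        if p < 1 or k < 2:
            raise ValueError("need p >= 1 patterns over k >= 2 inputs")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("pattern values must be finite")

    @property
    def p(self) -> int:
        return self.patterns.shape[0]

    @property
    def k(self) -> int:
        return self.patterns.shape[1]


@dataclass
class WeightMatrix:
    """k x k signed connection strengths; symmetric when Hebbian-produced."""

    weights: np.ndarray


@dataclass
class CouplingMatrix:
    """Covariance of attachment probabilities over steps, with pair labels."""

    cov: np.ndarray
    labels: np.ndarray  # object array: strengthening / weakening / neutral


def hebbian_weights(training: TrainingSet, zero_diagonal: bool = False) -> WeightMatrix:
    """Outer-product Hebbian average ``w_ij = (1/p) sum_patterns x_i x_j``.

    The diagonal (``w_ii`` = mean of ``x_i**2``) is kept by default; set
    ``zero_diagonal=True`` to remove self-connections.
    """
    x = training.patterns
    w = x.T @ x / training.p
    w = (w + w.T) / 2.0  # exact symmetry against fp asymmetry
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)
    return WeightMatrix(weights=w)


def activation(weights, x, b: float = 0.0, polarity: int = +1) -> float:
    """Linear activation ``z = +/- (sum_i w_i x_i + b)``.

    The sign convention of the rule is exposed as ``polarity`` (default +1).
    """
    w = np.asarray(weights, dtype=float)
    xv = np.asarray(x, dtype=float)
    if w.shape != xv.shape:
        raise ValueError(f"shape mismatch: weights {w.shape} vs inputs {xv.shape}")
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    return polarity * float(w @ xv + b)


def quantum_activation(weights, x, b: float = 0.0) -> float:
    """Bounded activation ``z = (w . x + b) / (N + 1)``.

    Interpreted as the overlap of two state vectors; when all entries are in
    {-1, +1} and ``|b| <= 1`` the result is guaranteed to lie in [-1, 1].
    """
    w = np.asarray(weights, dtype=float)
    xv = np.asarray(x, dtype=float)
    if w.shape != xv.shape:
        raise ValueError(f"shape mismatch: weights {w.shape} vs inputs {xv.shape}")
    n = w.shape[-1]
    return float(w @ xv + b) / (n + 1)


def attachment_covariance(prob_history, tol: float = 1e-9) -> CouplingMatrix:
    """Sample covariance of per-step attachment probabilities across node pairs.

    ``prob_history`` is a steps x nodes array (or a list of per-step vectors;
    shorter early vectors are zero-padded for nodes born later).  Pairs are
    labelled ``strengthening`` when the covariance exceeds ``tol`` (rising
    together: Hebbian-like coupling), ``weakening`` below ``-tol``
    (anti-Hebbian-like), ``neutral`` otherwise.
    """
    if isinstance(prob_history, np.ndarray) and prob_history.ndim == 2:
        mat = np.asarray(prob_history, dtype=float)
    else:
        rows = [np.asarray(v, dtype=float) for v in prob_history]
        if len(rows) < 2:
            raise ValueError("need at least 2 steps of history")
        n = max(len(v) for v in rows)
        mat = np.zeros((len(rows), n))
        for i, v in enumerate(rows):
            mat[i, : len(v)] = v
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 steps of history")

    cov = np.cov(mat, rowvar=False)
    cov = np.atleast_2d(cov)
    labels = np.full(cov.shape, "neutral", dtype=object)
    labels[cov > tol] = "strengthening"
    labels[cov < -tol] = "weakening"
    return CouplingMatrix(cov=cov, labels=labels)
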