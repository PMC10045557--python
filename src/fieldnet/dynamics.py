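"""Topological invariants and dynamical classification of state-space trajectories.

Networks are treated as 1-complexes: ``B0`` counts connected components,
``B1 = E - V + B0`` counts independent cycles, and the Euler characteristic is
``chi = B0 - B1 = V - E``.  Three-dimensional trajectories are classified by
the winding-number ratio of their per-dimension dominant frequencies (rational
ratio -> periodic) together with a [0, 1] spectral coherence ``K`` among the
three dimensions (irrational ratio with ``K`` above the chaos bound ->
chaotic, otherwise quasiperiodic); the four outcomes map onto Wolfram's
computation classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "Trajectory",
    "SpectralSummary",
    "DynamicsReport",
    "TopologySummary",
    "betti_numbers",
    "euler_characteristic",
    "dominant_frequency",
    "winding_numbers",
    "coherence",
    "classify_dynamics",
    "classify_trajectory",
    "wolfram_class",
    "delay_embed",
]

#: printed chaos bound on the nonlinear coherence
CHAOS_THRESHOLD = 0.25
#: rationality decision: largest denominator tried and absolute ratio tolerance
MAX_DENOMINATOR = 32
RATIO_TOL = 1e-3

_WOLFRAM = {"fixed-point": "I", "periodic": "II", "chaotic": "III", "quasiperiodic": "IV"}


@dataclass
class Trajectory:
    """A uniformly sampled 3-D state-space time series."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("t, x, y, z must have equal lengths")
        if n < 64:
            raise ValueError("trajectory must hold at least 64 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        for arr in (self.t, self.x, self.y, self.z):
            if not np.all(np.isfinite(arr)):
                raise ValueError("trajectory values must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dims(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.x, self.y, self.z

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "z": self.z})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        t = df["t"].to_numpy(dtype=float)
        if fs is None:
            dt = np.diff(t)
            fs = 1.0 / float(np.median(dt))
        return cls(t=t, x=df["x"].to_numpy(), y=df["y"].to_numpy(), z=df["z"].to_numpy(), fs=fs)


@dataclass
class SpectralSummary:
    dominant_freqs: tuple[float, float, float]
    autospectra: tuple[float, float, float]
    cross_term: float


@dataclass
class DynamicsReport:
    winding: tuple[float, float, float]
    rationality: str  # rational | irrational
    coherence: float
    dynamics_class: str
    wolfram_class: str
    spectral: SpectralSummary | None = None


@dataclass
class TopologySummary:
    betti: tuple[int, int]
    euler: int
    compared_space: "TopologySummary | None" = None

    def invariant_with(self, other: "TopologySummary") -> bool:
        """Two spaces are reported algebraically invariant at equal chi."""
        return self.euler == other.euler


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def betti_numbers(network) -> tuple[int, int]:
    """Graph Betti numbers ``(B0, B1)``: components and cycle rank ``E - V + B0``."""
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no Betti numbers")
    b0 = nx.number_connected_components(g)
    b1 = g.number_of_edges() - g.number_of_nodes() + b0
    return b0, b1


def euler_characteristic(network) -> int:
    """Euler characteristic ``chi = B0 - B1`` (equals ``V - E`` for a 1-complex)."""
    b0, b1 = betti_numbers(network)
    return b0 - b1


def topology_summary(network, compared=None) -> TopologySummary:
    b = betti_numbers(network)
    summ = TopologySummary(betti=b, euler=b[0] - b[1])
    if compared is not None:
        summ.compared_space = topology_summary(compared)
    return summ


def _smooth(x: np.ndarray) -> np.ndarray:
    """Cubic smoothing (Savitzky-Golay, local cubic least squares) to tame noise."""
    win = min(11, len(x) - (1 - len(x) % 2))
    if win < 5:
        return x
    return sp_signal.savgol_filter(x, window_length=win, polyorder=3)


def dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Dominant frequency of a scalar series, refined off the periodogram grid.

    Cubic smoothing, Hann-windowed periodogram, peak bin (ties broken toward
    the lower frequency), then golden-section refinement of the windowed
    DTFT magnitude within one bin of the peak.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("degenerate trajectory dimension: zero variance")
    xs = _smooth(x - x.mean())
    n = len(xs)
    w = np.hanning(n)
    spec = np.abs(np.fft.rfft(xs * w))
    spec[0] = 0.0  # exclude DC
    k = int(np.argmax(spec))  # argmax returns the first (lowest-frequency) tie
    df = fs / n
    tt = np.arange(n) / fs
    xw = xs * w

    def neg_mag(f: float) -> float:
        return -abs(np.sum(xw * np.exp(-2j * math.pi * f * tt)))

    lo = max(df * (k - 1), df * 0.5)
    hi = min(df * (k + 1), fs / 2)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_mag, bounds=(lo, hi), method="bounded",
                          options={"xatol": df * 1e-6})
    return float(res.x)


def _rational_ratio(r: float, max_denominator: int = MAX_DENOMINATOR,
                    tol: float = RATIO_TOL) -> tuple[bool, Fraction]:
    frac = Fraction(r).limit_denominator(max_denominator)
    return abs(float(frac) - r) <= tol, frac


def winding_numbers(
    traj: Trajectory,
    max_denominator: int = MAX_DENOMINATOR,
    tol: float = RATIO_TOL,
) -> tuple[tuple[float, float, float], str]:
    """Winding-number ratio ``f_X : f_Y : f_Z`` reduced by its smallest member.

    Each reduced ratio is compared against its best rational approximation
    with denominator at most ``max_denominator`` (continued-fraction
    convergents); the triple is rational only if every ratio sits within
    ``tol`` (absolute) of such a fraction.
    """
    freqs = np.array([dominant_frequency(d, traj.fs) for d in traj.dims])
    ratios = tuple(freqs / freqs.min())
    rational = all(_rational_ratio(r, max_denominator, tol)[0] for r in ratios)
    return ratios, ("rational" if rational else "irrational")


def _welch_nperseg(n: int) -> int:
    # at least ~8 half-overlapping segments; capped so long records average
    # enough segments to push the independent-signal coherence bias below 0.05
    return max(16, min(512, (2 * n) // 9))


def coherence(
    traj: Trajectory,
    estimator: str = "normalized",
    band_bins: int = 2,
) -> float:
    """Nonlinear coherence ``K`` in [0, 1] among the three dimensions.

    Normalized estimator (default): the geometric mean of the three pairwise
    magnitude-squared spectral coherences (Welch, 50% overlap), each averaged
    over a small band centred on the pair's dominant frequencies.  Identical
    signals give 1, independent signals tend to 0, and by construction the
    value lies in [0, 1].

    ``estimator="literal"`` instead evaluates the un-normalized triple ratio
    ``|C_XYZ| / (|A_X| |A_Y| |A_Z|)`` at the shared dominant band, with no
    [0, 1] guarantee.
    """
    n = len(traj)
    nperseg = _welch_nperseg(n)
    n_segments = max(1, (n - nperseg // 2) // (nperseg // 2))
    if n_segments < 8:
        raise ValueError("trajectory too short for 8 averaging segments")

    dims = traj.dims
    variances = [np.var(d) for d in dims]
    if all(v == 0 for v in variances):
        return 0.0
    freqs_dom = [
        dominant_frequency(d, traj.fs) if v > 0 else 0.0
        for d, v in zip(dims, variances)
    ]

    if estimator == "literal":
        f, pxx = sp_signal.welch(dims[0], fs=traj.fs, nperseg=nperseg)
        spectra = []
        for d in dims:
            _, p = sp_signal.welch(d, fs=traj.fs, nperseg=nperseg)
            spectra.append(p)
        # triple product cross-term at the shared dominant band
        idx = np.argmin(np.abs(f - np.median(freqs_dom)))
        specs = []
        for d in dims:
            _, _, z = sp_signal.stft(d, fs=traj.fs, nperseg=nperseg)
            specs.append(z[idx])
        c_xyz = np.mean(specs[0] * np.conj(specs[1]) * specs[2])
        a = [math.sqrt(abs(p[idx])) for p in spectra]
        denom = a[0] * a[1] * a[2]
        if denom == 0:
            return 0.0
        return float(abs(c_xyz) / denom)

    if estimator != "normalized":
        raise ValueError("estimator must be 'normalized' or 'literal'")

    pairs = [(0, 1), (0, 2), (1, 2)]
    msc_vals = []
    for i, j in pairs:
        f, cxy = sp_signal.coherence(
            dims[i], dims[j], fs=traj.fs, nperseg=nperseg, noverlap=nperseg // 2
        )
        sel = np.zeros(len(f), dtype=bool)
        for fd in (freqs_dom[i], freqs_dom[j]):
            k = int(np.argmin(np.abs(f - fd)))
            sel[max(0, k - band_bins): k + band_bins + 1] = True
        sel[0] = False  # never judge coupling from the DC bin
        if not sel.any():
            sel[1:] = True
        msc_vals.append(float(np.mean(cxy[sel])))
    msc_vals = [min(max(v, 0.0), 1.0) for v in msc_vals]
    return float(np.prod(msc_vals) ** (1.0 / 3.0))


def classify_dynamics(rationality: str, k_coherence: float,
                      fixed_point: bool = False,
                      chaos_threshold: float = CHAOS_THRESHOLD) -> str:
    """Decision table: fixed-point; rational -> periodic; irrational ->
    quasiperiodic or (``K`` above the chaos bound) chaotic."""
    if fixed_point:
        return "fixed-point"
    if rationality == "rational":
        return "periodic"
    if rationality != "irrational":
        raise ValueError("rationality must be 'rational' or 'irrational'")
    return "chaotic" if k_coherence > chaos_threshold else "quasiperiodic"


def wolfram_class(dynamics_class: str) -> str:
    """Map a dynamics class onto its Wolfram computation class."""
    try:
        return _WOLFRAM[dynamics_class]
    except KeyError:
        raise ValueError(f"unknown dynamics class {dynamics_class!r}") from None


def classify_trajectory(traj: Trajectory,
                        chaos_threshold: float = CHAOS_THRESHOLD) -> DynamicsReport:
    """Full pipeline: winding ratio, coherence, dynamics and Wolfram class."""
    if all(np.var(d) == 0 for d in traj.dims):
        report = DynamicsReport(
            winding=(1.0, 1.0, 1.0),
            rationality="rational",
            coherence=0.0,
            dynamics_class="fixed-point",
            wolfram_class=wolfram_class("fixed-point"),
        )
        return report
    ratios, rationality = winding_numbers(traj)
    k = coherence(traj)
    dclass = classify_dynamics(rationality, k, chaos_threshold=chaos_threshold)
    freqs = [dominant_frequency(d, traj.fs) for d in traj.dims]
    spectral = SpectralSummary(
        dominant_freqs=tuple(freqs),
        autospectra=tuple(float(np.var(d)) for d in traj.dims),
        cross_term=k,
    )
    return DynamicsReport(
        winding=ratios,
        rationality=rationality,
        coherence=k,
        dynamics_class=dclass,
        wolfram_class=wolfram_class(dclass),
        spectral=spectral,
    )


def delay_embed(series, dim: int, lag: int) -> np.ndarray:
    """Takens delay-coordinate embedding: rows ``(x_t, x_{t+lag}, ...)``."""
    x = np.asarray(series, dtype=float)
    if dim < 1 or lag < 1 and dim > 1:
        raise ValueError("need dim >= 1 and lag >= 1")
    span = (dim - 1) * lag
    if len(x) <= span:
        raise ValueError("series too short for the requested embedding")
    n_rows = len(x) - span
    return np.column_stack([x[i * lag: i * lag + n_rows] for i in range(dim)])
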