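"""Arrhenius and quantum transition kinetics with work-energy accounting.

State switches between network nodes are treated as first-order reactions:
the classical rate is ``k = A exp(-E_a / (R T))`` and the quantum (tunneling)
rate is ``k = (k_B Gamma / h) f(eps)``.  A rate-temperature series whose
Arrhenius plot (ln k versus 1/T) is linear is classified classical; curvature
(for instance from a temperature-independent tunneling floor) marks the
quantum regime.  The module also prices state resets via the Landauer bound
and reports work, power, efficiency and coefficient of performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RateParams",
    "ThermoState",
    "TransitionRecord",
    "arrhenius_rate",
    "quantum_rate",
    "activation_energy",
    "arrhenius_linearity",
    "landauer_energy",
    "work_free_energy",
    "engine_metrics",
    "transition_classify",
]

#: operational reading of "linear Arrhenius plot" on finite noisy series
DEFAULT_R2_THRESHOLD = 0.995


@dataclass
class RateParams:
    """Kinetic parameters; natural units (k_B = h = R = 1) by default."""

    a_prefactor: float = 1.0
    e_a: float = 0.0
    r_gas: float = 1.0
    temp: float | None = None
    gamma: float | None = None
    k_b: float = 1.0
    h_planck: float = 1.0

    def __post_init__(self) -> None:
        if self.a_prefactor <= 0:
            raise ValueError("prefactor A must be > 0")
        if (self.temp is None or self.temp <= 0) and (self.gamma is None or self.gamma <= 0):
            raise ValueError("one of temp or gamma must be > 0")


@dataclass
class ThermoState:
    """Work-energy bookkeeping for one state switch or engine stroke."""

    delta_h: float = 0.0
    delta_s: float = 0.0
    work: float = 0.0
    e_free: float = 0.0
    power: float | None = None
    efficiency: float | None = None
    cop: float | None = None


@dataclass
class TransitionRecord:
    """An energy-level switch with its thermochemical direction."""

    eps_from: float
    eps_to: float
    delta_e: float
    direction: str  # endothermic | exothermic | neutral


def arrhenius_rate(params: RateParams) -> float:
    """Classical first-order rate ``k = A exp(-E_a / (R T))``."""
    if params.temp is None or params.temp <= 0:
        raise ValueError("temp must be > 0")
    if params.r_gas <= 0:
        raise ValueError("gas constant must be > 0")
    return params.a_prefactor * math.exp(-params.e_a / (params.r_gas * params.temp))


def quantum_rate(gamma: float, f_eps: float, k_b: float = 1.0, h_planck: float = 1.0) -> float:
    """Tunneling-regime rate ``k = (k_B Gamma / h) f(eps)``, linear in both factors."""
    if gamma <= 0:
        raise ValueError("annealing parameter gamma must be > 0")
    if f_eps < 0:
        raise ValueError("dynamic exponent must be >= 0")
    return (k_b * gamma / h_planck) * f_eps


def activation_energy(
    rate: float,
    params: RateParams,
    regime: str = "classical",
    f_eps: float | None = None,
    use_gamma: bool = False,
) -> float:
    """Invert the rate law for the activation energy, ``E_a = -R T ln(k / A)``.

    In the quantum regime the rate is first formed from the tunneling law
    ``(k_B Gamma / h) f(eps)`` and then inverted identically; ``use_gamma``
    substitutes the annealing parameter for T in the inversion.
    """
    if params.a_prefactor <= 0:
        raise ValueError("prefactor A must be > 0")
    if regime == "quantum":
        if f_eps is None:
            raise ValueError("quantum regime requires f_eps")
        rate = quantum_rate(params.gamma, f_eps, params.k_b, params.h_planck)
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t_like = params.gamma if use_gamma else params.temp
    if t_like is None or t_like <= 0:
        raise ValueError("a positive temperature (or gamma) is required")
    return -params.r_gas * t_like * math.log(rate / params.a_prefactor)


@dataclass
class ArrheniusFit:
    """Diagnostics of the ln(k) vs 1/T regression."""

    regime: str  # classical | quantum
    slope: float  # -E_a / R
    intercept: float  # ln A
    r_squared: float

    @property
    def e_a(self) -> float:
        """Activation energy implied by the slope (R = 1 working units)."""
        return -self.slope

    @property
    def a_prefactor(self) -> float:
        return math.exp(self.intercept)


def arrhenius_linearity(
    rates, temps, r2_threshold: float = DEFAULT_R2_THRESHOLD
) -> ArrheniusFit:
    """Classify a rate-temperature series as classical or quantum kinetics.

    Least-squares line of ``ln(rate)`` on ``1/temp``; a coefficient of
    determination at or above ``r2_threshold`` marks classical (linear
    Arrhenius) behaviour, anything less marks the quantum (tunneling) regime.
    """
    k = np.asarray(rates, dtype=float)
    t = np.asarray(temps, dtype=float)
    if k.size < 4:
        raise ValueError("need at least 4 rate-temperature points")
    if np.any(k <= 0) or np.any(t <= 0):
        raise ValueError("rates and temperatures must be positive")
    fit = stats.linregress(1.0 / t, np.log(k))
    r2 = float(fit.rvalue**2)
    regime = "classical" if r2 >= r2_threshold else "quantum"
    return ArrheniusFit(
        regime=regime, slope=float(fit.slope), intercept=float(fit.intercept), r_squared=r2
    )


def landauer_energy(eta: float, beta: float, parse: str = "ln2x") -> float:
    """Landauer reset energy of a node of fitness ``eta``.

    Default parse: ``eps = -(1/beta) ln(2 eta)`` (the inserted factor 2 yields
    the ln 2 Landauer quantum at eta = 1); the alternative reading
    ``parse="log2"`` gives ``eps = -(1/beta) log2(eta)``.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if parse == "ln2x":
        return -math.log(2.0 * eta) / beta
    if parse == "log2":
        return -math.log2(eta) / beta
    raise ValueError("parse must be 'ln2x' or 'log2'")


def work_free_energy(
    delta_h: float, temp_or_gamma: float, delta_s: float, mode: str = "classical"
) -> ThermoState:
    """Extractable work ``W = dH - T dS`` (classical) or ``W = dH - Gamma dS`` (hybrid).

    Per the work-energy chain of equalities, ``W = dE = dE_free`` is recorded
    identically in ``work`` and ``e_free``.
    """
    if mode not in ("classical", "hybrid"):
        raise ValueError("mode must be 'classical' or 'hybrid'")
    w = delta_h - temp_or_gamma * delta_s
    return ThermoState(delta_h=delta_h, delta_s=delta_s, work=w, e_free=w)


def engine_metrics(
    delta_w: float, delta_t: float, e_input: float, e_output: float
) -> ThermoState:
    """Engine figures of merit: ``P = dW/dt``, ``Phi = W/E_in``, ``COP = E_out/W``."""
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    if e_input <= 0:
        raise ValueError("e_input must be > 0 for the efficiency")
    if delta_w == 0:
        raise ValueError("delta_w must be nonzero for the COP")
    return ThermoState(
        work=delta_w,
        e_free=delta_w,
        power=delta_w / delta_t,
        efficiency=delta_w / e_input,
        cop=e_output / delta_w,
    )


def transition_classify(eps_from: float, eps_to: float) -> TransitionRecord:
    """Direction of a state switch: uphill in energy absorbs (endothermic),
    downhill dissipates (exothermic)."""
    if not (math.isfinite(eps_from) and math.isfinite(eps_to)):
        raise ValueError("energies must be finite")
    delta_e = eps_to - eps_from
    if delta_e > 0:
        direction = "endothermic"
    elif delta_e < 0:
        direction = "exothermic"
    else:
        direction = "neutral"
    return TransitionRecord(eps_from=eps_from, eps_to=eps_to, delta_e=delta_e, direction=direction)
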