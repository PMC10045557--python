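"""Occupation statistics, chemical potential, and condensation detection.

Link endpoints on a grown network are treated as non-interacting particles
occupying per-node energy levels.  The dynamic exponent
``f(eps) = exp(-beta (eps - mu))`` selects the operative statistics:
``f = 1`` Bose-Einstein, ``f << 1`` Maxwell-Boltzmann, ``f >> 1`` Fermi-Dirac.
When no chemical potential below the band bottom can accommodate the particle
budget under Bose-Einstein statistics, the excess condenses onto the
minimum-energy node (the network analogue of Bose-Einstein condensation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import zeta

from .growth import GrownNetwork

__all__ = [
    "PhaseReport",
    "dynamic_exponent",
    "occupation_be",
    "occupation_mb",
    "occupation_fd",
    "solve_chemical_potential",
    "classify_phase",
    "critical_gamma",
    "condensate_fraction",
    "phase_report",
]

#: operational reading of "f << 1" / "f >> 1": order-of-magnitude thresholds
DEFAULT_THRESHOLDS = (0.1, 0.05, 10.0)  # (f_lo, delta, f_hi)


def dynamic_exponent(eps, beta: float, mu: float):
    """Dynamic exponent ``f(eps) = exp(-beta (eps - mu))``; equals 1 iff eps = mu."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return np.exp(-beta * (np.asarray(eps, dtype=float) - mu))


def occupation_be(eps, beta: float, mu: float):
    """Bose-Einstein occupation ``1 / (exp(beta (eps - mu)) - 1)``.

    Diverges as ``eps -> mu`` from above; ``eps <= mu`` signals that the
    chemical potential has reached the band bottom (condensation).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    x = beta * (np.asarray(eps, dtype=float) - mu)
    if np.any(x <= 0):
        raise ValueError(
            "Bose-Einstein occupation diverges for eps <= mu (condensation)"
        )
    return 1.0 / np.expm1(x)


def occupation_mb(eps, beta: float, mu: float):
    """Maxwell-Boltzmann occupation ``exp(-beta (eps - mu))``."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return np.exp(-beta * (np.asarray(eps, dtype=float) - mu))


def occupation_fd(eps, beta: float, mu: float):
    """Fermi-Dirac occupation ``1 / (exp(beta (eps - mu)) + 1)``, in (0, 1)."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    x = beta * (np.asarray(eps, dtype=float) - mu)
    return 1.0 / (np.exp(x) + 1.0)


_OCCUPATIONS = {"be": occupation_be, "mb": occupation_mb, "fd": occupation_fd}


@dataclass
class ChemicalPotentialResult:
    """Outcome of the mu solve: root, occupations, and condensation bookkeeping."""

    mu: float
    occupations: np.ndarray
    condensed: bool = False
    condensate_occupation: float = 0.0
    normalization: float = 0.0  # sum of occupations actually placed


def solve_chemical_potential(
    energies,
    beta: float,
    total_occupation: float,
    statistics: str = "be",
    rtol: float = 1e-10,
) -> ChemicalPotentialResult:
    """Solve ``sum_i n(eps_i; beta, mu) = total_occupation`` for ``mu``.

    The occupation sum is strictly increasing in ``mu`` for all three
    statistics, so a bracketing root solve is robust.  Under Bose-Einstein
    statistics ``mu`` is confined below the band bottom ``min(eps)``; when
    even ``mu -> min(eps)`` cannot place the requested budget on the excited
    levels, the result is flagged condensed and the excess occupation is
    assigned to the minimum-energy level.
    """
    eps = np.asarray(energies, dtype=float)
    if eps.size == 0:
        raise ValueError("energies must be non-empty")
    if not np.all(np.isfinite(eps)):
        raise ValueError("energies must be finite")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if total_occupation <= 0:
        raise ValueError("total_occupation must be > 0")
    if statistics not in _OCCUPATIONS:
        raise ValueError("statistics must be one of 'be', 'mb', 'fd'")

    e_min = float(eps.min())

    if statistics == "be":
        ground = eps == e_min
        excited = ~ground
        n_ground_levels = int(ground.sum())

        # capacity of the excited spectrum with mu pinned at the band bottom;
        # the ground level diverges there, so condensation is decided from the
        # excited levels alone
        excited_capacity = (
            float(np.sum(1.0 / np.expm1(beta * (eps[excited] - e_min))))
            if excited.any()
            else 0.0
        )
        hi = e_min - 1e-12
        lo = e_min - 50.0 / beta

        def total_at(mu: float) -> float:
            return float(np.sum(1.0 / np.expm1(beta * (eps - mu))))

        if excited_capacity < total_occupation:
            # condensation: place what the excited spectrum can hold at the
            # band bottom, the rest condenses onto the minimum-energy level
            occ = np.empty_like(eps)
            if excited.any():
                occ[excited] = 1.0 / np.expm1(beta * (eps[excited] - e_min))
            excess = total_occupation - excited_capacity
            occ[ground] = excess / n_ground_levels
            return ChemicalPotentialResult(
                mu=e_min,
                occupations=occ,
                condensed=True,
                condensate_occupation=float(excess),
                normalization=float(occ.sum()),
            )
        while total_at(lo) > total_occupation:
            lo = e_min - 2 * (e_min - lo)
        mu = brentq(lambda x: total_at(x) - total_occupation, lo, hi, rtol=rtol)
        occ = 1.0 / np.expm1(beta * (eps - mu))
        return ChemicalPotentialResult(
            mu=float(mu), occupations=occ, normalization=float(occ.sum())
        )

    if statistics == "fd" and total_occupation >= eps.size:
        raise ValueError(
            "Fermi-Dirac occupations are < 1 per level; the target exceeds the "
            f"capacity of {eps.size} levels"
        )
    func = _OCCUPATIONS[statistics]

    def total_at(mu: float) -> float:
        return float(np.sum(func(eps, beta, mu)))

    # expanding bracket around the band; MB has a closed form we use to centre
    lo = e_min - 1.0 / beta
    hi = float(eps.max()) + 1.0 / beta
    while total_at(lo) > total_occupation:
        lo -= (hi - lo)
    while total_at(hi) < total_occupation:
        hi += (hi - lo)
    mu = brentq(lambda x: total_at(x) - total_occupation, lo, hi, rtol=rtol)
    occ = func(eps, beta, mu)
    return ChemicalPotentialResult(
        mu=float(mu), occupations=np.asarray(occ), normalization=float(np.sum(occ))
    )


def classify_phase(f_values, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS) -> str:
    """Label the computational phase from the per-node dynamic exponents.

    The representative exponent is the median of ``f_values``:
    ``|f - 1| <= delta`` -> ``"bose-einstein"``, ``f <= f_lo`` ->
    ``"maxwell-boltzmann"``, ``f >= f_hi`` -> ``"fermi-dirac"``, otherwise
    ``"crossover"``.
    """
    f = np.asarray(f_values, dtype=float)
    if f.size == 0:
        raise ValueError("f_values must be non-empty")
    if np.any(f < 0):
        raise ValueError("dynamic exponents must be non-negative")
    f_lo, delta, f_hi = thresholds
    rep = float(np.median(f))
    if abs(rep - 1.0) <= delta:
        return "bose-einstein"
    if rep <= f_lo:
        return "maxwell-boltzmann"
    if rep >= f_hi:
        return "fermi-dirac"
    return "crossover"


def critical_gamma(t_c: float, n_density: float, k_b: float = 1.0) -> float:
    """Critical annealing parameter ``Gamma_C = T_C k_B / (n / zeta(3/2))^(2/3)``."""
    if t_c <= 0 or n_density <= 0 or k_b <= 0:
        raise ValueError("t_c, n_density and k_b must be > 0")
    zeta_32 = float(zeta(1.5))  # 2.612375348685488, >= 10 significant digits
    return (t_c * k_b) / (n_density / zeta_32) ** (2.0 / 3.0)


def condensate_fraction(network: GrownNetwork) -> float:
    """Share of all link endpoints held by the minimum-energy node."""
    total = int(network.degree_array().sum())
    if total == 0:
        raise ValueError("network has no edges")
    eps = network.eps_array()
    k_min = int(network.degree_array()[int(np.argmin(eps))])
    return k_min / total


@dataclass
class PhaseReport:
    """Full statistical characterization of a grown network at one beta."""

    mu: float
    f_values: np.ndarray
    occupations: np.ndarray
    normalization: float
    phase_label: str
    condensate_fraction: float
    gamma_c: float | None = None
    condensed: bool = False
    beta: float = 1.0
    statistics: str = "be"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["f_values"] = np.asarray(self.f_values).tolist()
        d["occupations"] = np.asarray(self.occupations).tolist()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def phase_report(
    network: GrownNetwork,
    beta: float | None = None,
    statistics: str = "be",
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    t_c: float | None = None,
    n_density: float | None = None,
) -> PhaseReport:
    """Characterize a grown network: solve mu, label the phase, measure condensation.

    The particle budget is the total number of link endpoints (2E).  When
    ``t_c`` and ``n_density`` are supplied the critical annealing parameter is
    reported as well.
    """
    if beta is None:
        beta = network.config.beta
    eps = network.eps_array()
    total = float(network.degree_array().sum())
    res = solve_chemical_potential(eps, beta, total, statistics=statistics)
    f_vals = dynamic_exponent(eps, beta, res.mu)
    label = classify_phase(f_vals, thresholds)
    frac = condensate_fraction(network)
    if res.condensed:
        label = "condensate"
    gamma_c = (
        critical_gamma(t_c, n_density) if t_c is not None and n_density is not None else None
    )
    return PhaseReport(
        mu=res.mu,
        f_values=f_vals,
        occupations=res.occupations,
        normalization=res.normalization,
        phase_label=label,
        condensate_fraction=frac,
        gamma_c=gamma_c,
        condensed=res.condensed,
        beta=beta,
        statistics=statistics,
    )
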