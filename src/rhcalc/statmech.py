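"""Discrete two-phase Boltzmann model demonstrating Raoult's law.

A collection of ``N`` solvent units in thermal equilibrium distributes
itself over two ladders of energy levels: liquid states, and vapour states
raised above them by a work function ``W`` (all energies in units of
``kT``).  The number of levels per energy interval in each phase is
proportional to that phase's volume, as for particle waves confined in a
box.  Three consequences fall out of the Boltzmann occupancy and are
checked by this module:

* the fraction of units found in the vapour carries a suppression factor
  ``exp(-W)`` (:func:`vapour_fraction`);
* replacing a fraction ``x`` of solvent by an ideal solute — which changes
  neither the level structure nor the work function — scales the vapour
  count by exactly ``(1 - x)``: Raoult's law
  (:func:`vapour_count_after_dilution`);
* at equilibrium the vapour concentration is independent of how the fixed
  container volume is split between liquid and vapour, because level
  densities track their phase volumes
  (:func:`vapour_concentration_vs_volume`).

The model is a pedagogical verifier of the derivation, not a predictor:
levels are evenly spaced with volume-proportional degeneracy, and the
units are classical distinguishable particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, TruncationError

__all__ = [
    "TwoPhaseSystem",
    "VolumeSplitPoint",
    "partition_sums",
    "vapour_fraction",
    "vapour_count_after_dilution",
    "vapour_concentration_vs_volume",
]

#: Largest allowed ratio of the last retained Boltzmann weight to the first.
_TAIL_WEIGHT_LIMIT = 1e-12


@dataclass(frozen=True)
class TwoPhaseSystem:
    """A truncated two-ladder Boltzmann system.

    Energies are in units of ``kT``; volumes in arbitrary units (only
    ratios matter).  ``n_levels_per_phase`` truncates each ladder; the
    truncation must be deep enough that the last retained weight is below
    1e-12 of the first, so truncated sums stand in for the infinite ones.
    """

    n_total: float = 1e6
    dilution_x: float = 0.0
    work_function_W: float = 2.0
    liquid_volume: float = 1.0
    vapour_volume: float = 1.0
    level_spacing: float = 0.05
    n_levels_per_phase: int = 1000

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise DomainError(f"n_total must be > 0, got {self.n_total}")
        if not 0.0 <= self.dilution_x < 1.0:
            raise DomainError(
                f"dilution_x must lie in [0, 1), got {self.dilution_x}"
            )
        if self.work_function_W < 0:
            raise DomainError(
                f"work_function_W must be >= 0, got {self.work_function_W}"
            )
        if self.liquid_volume <= 0 or self.vapour_volume <= 0:
            raise DomainError("phase volumes must be > 0")
        if self.level_spacing <= 0:
            raise DomainError(
                f"level_spacing must be > 0, got {self.level_spacing}"
            )
        if self.n_levels_per_phase < 2:
            raise DomainError("n_levels_per_phase must be >= 2")
        tail = math.exp(
            -(self.n_levels_per_phase - 1) * self.level_spacing
        )
        if tail >= _TAIL_WEIGHT_LIMIT:
            raise TruncationError(
                f"last retained Boltzmann weight is {tail:.3g} of the first "
                f"(limit {_TAIL_WEIGHT_LIMIT:g}); increase n_levels_per_phase "
                f"above {math.ceil(27.7 / self.level_spacing) + 1} or widen "
                "level_spacing"
            )


def partition_sums(sys: TwoPhaseSystem) -> tuple:
    """Truncated partition sums ``(Z_liquid, Z_vapour)``.

    Each phase contributes ``sum_i g * exp(-i * spacing)`` over its
    retained levels, with degeneracy ``g`` equal to the phase volume;
    vapour levels carry the extra suppression ``exp(-W)`` from the work
    function offset.
    """
    weights = np.exp(
        -sys.level_spacing * np.arange(sys.n_levels_per_phase)
    )
    ladder = float(weights.sum())
    z_liq = sys.liquid_volume * ladder
    z_vap = math.exp(-sys.work_function_W) * sys.vapour_volume * ladder
    return z_liq, z_vap


def vapour_fraction(sys: TwoPhaseSystem) -> float:
    """Equilibrium fraction of solvent units in the vapour phase.

    ``y = Z_vap / (Z_vap + Z_liq)``; strictly decreasing in the work
    function and equal to 1/2 for symmetric phases with ``W = 0``.
    """
    z_liq, z_vap = partition_sums(sys)
    return z_vap / (z_vap + z_liq)


def vapour_count_after_dilution(sys: TwoPhaseSystem) -> float:
    """Number of solvent units in the vapour after ideal dilution.

    Replacing a fraction ``x`` of solvent units by ideal solute changes
    neither the level structure nor the work function, so the vapour
    fraction per solvent unit is unchanged and the count is exactly
    ``(1 - x) * N * y``, linear in ``(1 - x)``: Raoult's law.
    """
    y = vapour_fraction(replace(sys, dilution_x=0.0))
    return (1.0 - sys.dilution_x) * sys.n_total * y


@dataclass(frozen=True)
class VolumeSplitPoint:
    """Equilibrium state for one liquid/vapour split of the container."""

    liquid_fraction: float
    vapour_count: float
    vapour_concentration: float
    depleted: bool


def vapour_concentration_vs_volume(
    sys: TwoPhaseSystem, liquid_fractions: Sequence[float]
) -> List[VolumeSplitPoint]:
    """Vapour concentration for several liquid/vapour splits.

    The container volume ``V = liquid_volume + vapour_volume`` is fixed.
    The system's reference state defines the (incompressible) liquid
    number density ``rho = n_total / liquid_volume``.  For each requested
    fraction ``fL`` the container is loaded with ``rho * fL * V`` units of
    liquid, which then equilibrates: units evaporate until the Boltzmann
    occupancy ratio ``N_vap / N_liq = Z_vap / Z_liq`` holds, with the
    liquid volume tracking its remaining content (``V_liq = N_liq / rho``)
    and the level degeneracies tracking the phase volumes.  Because of
    that tracking, the equilibrium vapour concentration is the same for
    every split — until the liquid is exhausted, after which the point is
    flagged ``depleted`` (all loaded units are vapour) rather than raised
    as an error.

    Requires ``W > 0``; at ``W = 0`` liquid and vapour are degenerate and
    the split has no equilibrium to settle to.
    """
    if sys.work_function_W <= 0:
        raise DomainError(
            "volume-split equilibrium requires work_function_W > 0"
        )
    v_total = sys.liquid_volume + sys.vapour_volume
    rho = sys.n_total / sys.liquid_volume
    out: List[VolumeSplitPoint] = []
    for f_liq in liquid_fractions:
        f = float(f_liq)
        if not 0.0 < f < 1.0:
            raise DomainError(
                f"liquid fraction must lie in (0, 1), got {f!r}"
            )
        n_loaded = rho * f * v_total

        def imbalance(n_liq: float) -> float:
            """Occupancy imbalance (Z-weighted), zero at equilibrium."""
            v_liq = n_liq / rho
            geom = replace(
                sys,
                liquid_volume=v_liq,
                vapour_volume=v_total - v_liq,
            )
            z_liq, z_vap = partition_sums(geom)
            # (N_vap * Z_liq - N_liq * Z_vap) / N_liq, to drop the
            # trivial root at N_liq = 0.
            return (n_loaded - n_liq) * z_liq / n_liq - z_vap

        lo = n_loaded * 1e-12
        if imbalance(lo) <= 0.0:
            # Even a trace of residual liquid evaporates: depletion.
            v_vap = v_total
            out.append(
                VolumeSplitPoint(
                    liquid_fraction=f,
                    vapour_count=n_loaded,
                    vapour_concentration=n_loaded / v_vap,
                    depleted=True,
                )
            )
            continue
        n_liq = brentq(
            imbalance, lo, n_loaded * (1.0 - 1e-15),
            xtol=1e-300, rtol=8.9e-16, maxiter=300,
        )
        n_vap = n_loaded - n_liq
        v_vap = v_total - n_liq / rho
        out.append(
            VolumeSplitPoint(
                liquid_fraction=f,
                vapour_count=n_vap,
                vapour_concentration=n_vap / v_vap,
                depleted=False,
            )
        )
    return out
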