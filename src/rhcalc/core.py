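"""Closed-form equilibrium relative-humidity models for solutions.

At liquid--vapour equilibrium the relative humidity (RH) of the air above a
solution equals the water activity of that solution.  For an ideal solution
Raoult's law gives the activity as the solvent mole fraction.  When solvent
and solute molecules pre-empt different volumes the activity picks up two
factors: the solvent *volume fraction* (a concentration ratio) and an
exponential factor embodying the difference in work functions for removing
a solvent molecule from the solution versus from pure solvent.  Their
product coincides with the Flory--Huggins solvent activity
``a1 = phi1 * exp[(1 - 1/r) * phi2]`` with ``r = v2/v1``.

Two practical front-ends cover the solutions used in macromolecular
crystallization:

* :func:`salt_rh` -- RH above a dissociating salt at a given molarity,
  parametrized by the ion count ``x`` and a specific-volume factor ``y``;
* :func:`polymer_rh` -- RH above a polymer (PEG) solution at a given mass
  fraction, on a lattice model where each monomer unit of effective mass
  ``m`` occupies one solvent-sized site.

All functions take and return RH as a fraction in (0, 1]; conversion to
percent happens only at I/O boundaries.  :func:`solve_concentration`
inverts either front-end (target RH -> concentration) by bracketed root
finding on the strictly monotone forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

from scipy.optimize import brentq

from .errors import DomainError, RangeError

__all__ = [
    "RHValue",
    "SolventSpec",
    "SaltParams",
    "PolymerParams",
    "GeneralizedMixture",
    "WATER",
    "raoult_rh",
    "volume_fraction_factor",
    "work_function_factor",
    "generalized_rh",
    "salt_rh",
    "mass_fraction_to_mole_ratio",
    "polymer_rh",
    "solve_concentration",
]


class RHValue(float):
    """A relative humidity held as a fraction in (0, 1].

    Subclasses :class:`float` so results participate in arithmetic
    directly; :attr:`percent` renders the conventional percent view.
    """

    def __new__(cls, fraction: float) -> "RHValue":
        if not 0.0 < fraction <= 1.0:
            raise DomainError(
                f"RH must be a fraction in (0, 1], got {fraction!r}"
            )
        return super().__new__(cls, fraction)

    @property
    def percent(self) -> float:
        """RH expressed in percent (fraction x 100)."""
        return 100.0 * float(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RHValue({float(self)!r})"


@dataclass(frozen=True)
class SolventSpec:
    """The solvent; water by default.

    Parameters
    ----------
    name : str
        Display name.
    molar_mass : float
        Molar mass in g/mol.  Water is taken as exactly 18, which fixes
        the molar concentration of pure water at 1000/18 ~= 55.56 mol/L.
    molar_volume : float
        Molar volume in L/mol (water: 0.018).
    """

    name: str = "water"
    molar_mass: float = 18.0
    molar_volume: float = 0.018

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise DomainError(f"molar_mass must be > 0, got {self.molar_mass}")
        if self.molar_volume <= 0:
            raise DomainError(
                f"molar_volume must be > 0, got {self.molar_volume}"
            )

    @property
    def molarity_pure(self) -> float:
        """Moles of solvent per litre of pure solvent (55.56 for water)."""
        return 1.0 / self.molar_volume


#: Water with the conventional round molar mass of 18 g/mol.
WATER = SolventSpec()


@dataclass(frozen=True)
class SaltParams:
    """A dissociating salt.

    ``x_ions`` is the number of independently drifting particles one
    formula unit contributes on dissolution (2 for NaCl; non-integer
    values are allowed to represent effective, partial dissociation).
    ``y_volume`` (L/mol) is the volume one mole of dissolved salt
    pre-empts, so ``1 - y*M`` litres of each litre of an ``M``-molar
    solution remain for water.
    """

    name: str
    x_ions: float
    y_volume: float

    def __post_init__(self) -> None:
        if self.x_ions < 1:
            raise DomainError(
                f"{self.name}: x_ions must be >= 1, got {self.x_ions}"
            )
        if self.y_volume < 0:
            raise DomainError(
                f"{self.name}: y_volume must be >= 0, got {self.y_volume}"
            )


@dataclass(frozen=True)
class PolymerParams:
    """A polymer solute on the lattice picture.

    ``n_mw`` is the polymer molecular weight in g/mol (PEG 6000 -> 6000);
    ``m_monomer`` the effective mass of one lattice-site monomer unit in
    g/mol.  The chain-to-solvent size ratio is ``r = n_mw / m_monomer``.
    The default ``m = 38`` is the value that best reproduces measured RH
    curves for PEGs.
    """

    name: str
    n_mw: float
    m_monomer: float = 38.0

    def __post_init__(self) -> None:
        if self.n_mw <= 0:
            raise DomainError(f"{self.name}: n_mw must be > 0, got {self.n_mw}")
        if self.m_monomer <= 0:
            raise DomainError(
                f"{self.name}: m_monomer must be > 0, got {self.m_monomer}"
            )
        if self.n_mw < self.m_monomer:
            raise DomainError(
                f"{self.name}: n_mw ({self.n_mw}) < m_monomer "
                f"({self.m_monomer}) would mean a polymer smaller than its "
                "monomer unit"
            )

    @property
    def r_ratio(self) -> float:
        """Polymer-to-solvent size ratio r = n/m."""
        return self.n_mw / self.m_monomer


@dataclass(frozen=True)
class GeneralizedMixture:
    """A binary mixture of molecules with unequal specific volumes.

    ``n1`` solvent units of specific volume ``v1`` and ``n2`` solute units
    of specific volume ``v2``.  Counts may be real-valued (they only ever
    enter as ratios).  Temperature does not appear: the ``kT`` in the
    work-function difference cancels the ``kT`` of the Boltzmann factor.
    """

    n1: float
    v1: float
    n2: float
    v2: float

    def __post_init__(self) -> None:
        if self.n1 <= 0:
            raise DomainError(f"n1 must be > 0, got {self.n1}")
        if self.n2 < 0:
            raise DomainError(f"n2 must be >= 0, got {self.n2}")
        if self.v1 <= 0:
            raise DomainError(f"v1 must be > 0, got {self.v1}")
        if self.v2 <= 0:
            raise DomainError(f"v2 must be > 0, got {self.v2}")

    @property
    def total_volume(self) -> float:
        return self.n1 * self.v1 + self.n2 * self.v2


def raoult_rh(mole_fraction_solute: float) -> RHValue:
    """Ideal-solution RH: ``1 - x`` for solute mole fraction ``x``.

    Raises :class:`DomainError` unless ``0 <= x < 1``.
    """
    x = float(mole_fraction_solute)
    if not 0.0 <= x < 1.0:
        raise DomainError(
            f"solute mole fraction must lie in [0, 1), got {x!r}"
        )
    return RHValue(1.0 - x)


def volume_fraction_factor(mix: GeneralizedMixture) -> float:
    """Solvent volume fraction ``n1 v1 / (n1 v1 + n2 v2)``.

    This is the concentration-ratio factor in the vapour-pressure ratio;
    it reduces to the solvent mole fraction when ``v1 == v2``.
    """
    return mix.n1 * mix.v1 / mix.total_volume


def work_function_factor(mix: GeneralizedMixture) -> float:
    """Exponential factor ``exp[n2 (v2 - v1) / (n1 v1 + n2 v2)]``.

    Embodies the difference in work functions for removing a solvent
    molecule from the solution versus from pure solvent, which arises from
    the cohesive-pressure work of swapping molecules of unequal volume.
    Temperature-independent because the ``kT`` in the work difference
    cancels the ``kT`` of the Boltzmann factor.  Equals 1 exactly when
    ``v1 == v2`` or ``n2 == 0``.
    """
    return math.exp(mix.n2 * (mix.v2 - mix.v1) / mix.total_volume)


def generalized_rh(mix: GeneralizedMixture) -> RHValue:
    """RH above a mixture of unequal-sized molecules.

    The product of :func:`volume_fraction_factor` and
    :func:`work_function_factor`; identical to the Flory--Huggins solvent
    activity ``exp[ln phi1 + (1 - 1/r) phi2]`` with ``r = v2/v1``.
    Reduces to Raoult's law when ``v1 == v2`` and in the limit of extreme
    dilution for any ``r``.
    """
    return RHValue(volume_fraction_factor(mix) * work_function_factor(mix))


def salt_rh(
    molarity: float,
    salt: SaltParams,
    solvent: SolventSpec = WATER,
) -> RHValue:
    """RH above a salt solution of the given molarity (mol/L).

    One litre of solution holds ``M`` moles of salt occupying ``y*M``
    litres, leaving ``W = (1000/molar_mass) * (1 - y*M)`` moles of water,
    and ``x*M`` moles of free ions.  The RH is the water mole fraction
    ``W / (W + x*M)``.  Strictly decreasing in ``M``; the initial slope
    ``-x / (1000/molar_mass)`` per mol/L is set by the dissociation count.
    """
    m = float(molarity)
    if m < 0:
        raise DomainError(f"molarity must be >= 0, got {m}")
    water_fraction_left = 1.0 - salt.y_volume * m
    if water_fraction_left <= 0.0:
        raise DomainError(
            f"salt volume exceeds solution volume: y*M = "
            f"{salt.y_volume * m:.4g} >= 1 for {salt.name} at {m} mol/L"
        )
    moles_water = solvent.molarity_pure * water_fraction_left
    return RHValue(moles_water / (moles_water + salt.x_ions * m))


def mass_fraction_to_mole_ratio(
    mass_fraction: float,
    polymer: PolymerParams,
    solvent: SolventSpec = WATER,
) -> float:
    """Solute-to-solvent mole ratio ``N2/N1`` from a mass fraction (w/w).

    ``N2/N1 = [w / (1 - w)] * (molar_mass_solvent / n_mw)``.
    """
    w = float(mass_fraction)
    if not 0.0 <= w < 1.0:
        raise DomainError(f"mass fraction must lie in [0, 1), got {w!r}")
    return (w / (1.0 - w)) * (solvent.molar_mass / polymer.n_mw)


def polymer_rh(
    mass_fraction: float,
    polymer: PolymerParams,
    solvent: SolventSpec = WATER,
) -> RHValue:
    """RH above a polymer solution at the given mass fraction (w/w).

    On the lattice picture each monomer unit of mass ``m`` occupies one
    solvent-sized site, so ``r = n/m`` and the site ratio is
    ``f = r * N2/N1 = (molar_mass_solvent/m) * w/(1 - w)`` (independent of
    the chain length ``n``).  Then

        ``RH = 1/(1 + f) * exp[(1 - 1/r) * f/(1 + f)]``

    which is the generalized model with ``phi2 = f/(1+f)``.  As ``n``
    grows at fixed ``m`` the RH becomes independent of ``n``.
    """
    mole_ratio = mass_fraction_to_mole_ratio(mass_fraction, polymer, solvent)
    r = polymer.r_ratio
    f = r * mole_ratio
    phi2 = f / (1.0 + f)
    return RHValue((1.0 / (1.0 + f)) * math.exp((1.0 - 1.0 / r) * phi2))


SoluteParams = Union[SaltParams, PolymerParams]


def _forward_and_bracket(
    solute: SoluteParams, solvent: SolventSpec
) -> tuple:
    """Forward model and concentration bracket for the inverse solver."""
    margin = 1e-9
    if isinstance(solute, SaltParams):
        if solute.y_volume > 0:
            upper = (1.0 - margin) / solute.y_volume
        else:
            # No volume exclusion: RH -> 0 only as M -> infinity; a cap of
            # 1e6 mol/L is far beyond any physical solution.
            upper = 1e6
        return (lambda c: float(salt_rh(c, solute, solvent))), 0.0, upper
    if isinstance(solute, PolymerParams):
        upper = 1.0 - margin
        return (lambda c: float(polymer_rh(c, solute, solvent))), 0.0, upper
    raise TypeError(f"unsupported solute type: {type(solute).__name__}")


def solve_concentration(
    target_rh: float,
    solute: SoluteParams,
    solvent: SolventSpec = WATER,
) -> float:
    """Concentration at which the forward model equals ``target_rh``.

    Returns molarity (mol/L) for a :class:`SaltParams` solute and mass
    fraction (w/w) for a :class:`PolymerParams` solute.  The forward
    models are strictly decreasing, so the root is unique; it is found by
    Brent's method on ``[0, domain boundary - 1e-9]`` to an absolute
    tolerance of 1e-10 on RH.  Raises :class:`RangeError` if the target
    lies outside the attainable RH interval.
    """
    t = float(target_rh)
    if not 0.0 < t < 1.0:
        raise RangeError(
            f"target RH must be a fraction in (0, 1), got {t!r}"
        )
    forward, lo, hi = _forward_and_bracket(solute, solvent)
    rh_lo = forward(hi)  # lowest attainable RH (at the domain boundary)
    if t < rh_lo:
        raise RangeError(
            f"target RH {t:.6g} below attainable range "
            f"({rh_lo:.6g}, 1.0) for {solute.name}"
        )
    if t >= 1.0:  # pragma: no cover - excluded by the range check above
        raise RangeError("target RH must be below 1")
    conc = brentq(
        lambda c: forward(c) - t, lo, hi, xtol=1e-14, rtol=8.9e-16,
        maxiter=200,
    )
    return float(conc)
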