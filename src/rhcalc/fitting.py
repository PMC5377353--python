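"""Least-squares estimation of solute parameters from RH curves.

Fits the salt model's ion count ``x`` and specific-volume factor ``y``,
or the polymer lattice model's effective monomer mass ``m``, to measured
(concentration, RH) tables.  Because published RH curves are typically
available only as figures, the module ships a synthetic-curve generator:
it evaluates the forward model on a concentration grid and adds
homoscedastic Gaussian noise on RH, emulating repeated equilibrium-point
readings from a humidity-control device.  The generator is seeded and
deterministic, which makes parameter-recovery tests exact contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core import (
    PolymerParams,
    SaltParams,
    SolventSpec,
    WATER,
    polymer_rh,
    salt_rh,
)
from .errors import DomainError
from .registry import SoluteRecord

__all__ = [
    "RHCurve",
    "FitResult",
    "generate_synthetic_curve",
    "fit_salt",
    "fit_polymer_m",
]

#: Box bounds for the salt fit: x in [1, 5] ions, y in [0, 0.5] L/mol.
SALT_BOUNDS = ((1.0, 0.0), (5.0, 0.5))
#: Bounds for the effective monomer mass m (g/mol).
MONOMER_BOUNDS = (10.0, 200.0)


@dataclass(frozen=True)
class RHCurve:
    """A (concentration, RH) table for one solute.

    ``unit`` is ``"M"`` (molarity, for salts) or ``"ww"`` (mass fraction,
    for polymers).  Concentrations must be nonnegative and strictly
    increasing; RH values are fractions in (0, 1].  ``noise_sd`` records
    the generating noise level when known.
    """

    solute_name: str
    points: Tuple[Tuple[float, float], ...]
    unit: str
    noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.unit not in ("M", "ww"):
            raise DomainError(f"unit must be 'M' or 'ww', got {self.unit!r}")
        conc = [c for c, _ in self.points]
        if any(c < 0 for c in conc):
            raise DomainError("concentrations must be nonnegative")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise DomainError("concentrations must be strictly increasing")
        for c, rh in self.points:
            if not 0.0 < rh <= 1.0:
                raise DomainError(
                    f"RH must lie in (0, 1]; point ({c}, {rh}) violates this"
                )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def rh(self) -> np.ndarray:
        return np.array([r for _, r in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit.

    ``estimates`` maps parameter names to fitted values; ``residual_rms``
    is the root-mean-square RH residual.  ``converged`` is False when the
    optimizer failed, in which case ``message`` carries its diagnostics —
    a failed fit is always reported, never silently returned.
    """

    estimates: Dict[str, float]
    residual_rms: float
    n_points: int
    converged: bool
    message: str = ""
    seed: Optional[int] = None


def _forward(record: SoluteRecord, conc: np.ndarray,
             solvent: SolventSpec) -> np.ndarray:
    if record.kind == "salt":
        return np.array([
            float(salt_rh(c, record.params, solvent)) for c in conc
        ])
    return np.array([
        float(polymer_rh(c, record.params, solvent)) for c in conc
    ])


def generate_synthetic_curve(
    solute: SoluteRecord,
    concentrations: Sequence[float],
    noise_sd: float,
    seed: int,
    solvent: SolventSpec = WATER,
) -> RHCurve:
    """Forward-model curve with seeded Gaussian noise on RH.

    ``rh_i = model(c_i) + eps_i`` with ``eps_i ~ N(0, noise_sd)``
    independent, clipped to (0, 1].  The same seed always reproduces the
    same curve.  Concentrations outside the solute's domain raise
    :class:`DomainError` naming the offending point.
    """
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    conc = np.asarray(list(concentrations), dtype=float)
    try:
        clean = _forward(solute, conc, solvent)
    except DomainError as exc:
        raise DomainError(
            f"concentration grid leaves the domain of {solute.name}: {exc}"
        )
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=conc.shape)
    noisy = np.clip(noisy, np.finfo(float).tiny, 1.0)
    unit = "M" if solute.kind == "salt" else "ww"
    return RHCurve(
        solute_name=solute.name,
        points=tuple(zip(conc.tolist(), noisy.tolist())),
        unit=unit,
        noise_sd=noise_sd,
    )


def _run_least_squares(residual, theta0, bounds):
    """Bounded trust-region least squares with tight tolerances."""
    return least_squares(
        residual, theta0, bounds=bounds, method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )


def fit_salt(
    curve: RHCurve,
    fix_x: Optional[float] = None,
    solvent: SolventSpec = WATER,
) -> FitResult:
    """Estimate the salt parameters (x, y) from an RH curve.

    Minimizes the sum of squared RH residuals over ``x in [1, 5]`` and
    ``y in [0, 0.5]``.  At low molarity the curve's slope is governed by
    ``x`` alone and the curvature at higher molarity by ``y``, so both
    are identifiable from a curve spanning a few mol/L.  ``fix_x`` pins
    the ion count (e.g. to its known integer value) and fits ``y`` only,
    which sharpens the ``y`` estimate on noisy data.
    """
    min_points = 2 if fix_x is not None else 3
    if len(curve) < min_points:
        raise DomainError(
            f"need at least {min_points} points to fit, got {len(curve)}"
        )
    if curve.unit != "M":
        raise DomainError("salt fits require a molarity ('M') curve")
    conc, rh_obs = curve.concentrations, curve.rh

    def model(x: float, y: float) -> np.ndarray:
        params = SaltParams(name=curve.solute_name, x_ions=x, y_volume=y)
        return np.array([
            float(salt_rh(c, params, solvent)) for c in conc
        ])

    if fix_x is not None:
        if fix_x < 1:
            raise DomainError(f"fix_x must be >= 1, got {fix_x}")
        res = _run_least_squares(
            lambda th: model(fix_x, th[0]) - rh_obs,
            [0.05], ([SALT_BOUNDS[0][1]], [SALT_BOUNDS[1][1]]),
        )
        estimates = {"x_ions": float(fix_x), "y_volume": float(res.x[0])}
    else:
        res = _run_least_squares(
            lambda th: model(th[0], th[1]) - rh_obs,
            [2.0, 0.05],
            (list(SALT_BOUNDS[0]), list(SALT_BOUNDS[1])),
        )
        estimates = {"x_ions": float(res.x[0]), "y_volume": float(res.x[1])}
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return FitResult(
        estimates=estimates,
        residual_rms=rms,
        n_points=len(curve),
        converged=bool(res.success),
        message="" if res.success else res.message,
    )


def fit_polymer_m(
    curve: RHCurve,
    n_mw: float,
    solvent: SolventSpec = WATER,
) -> FitResult:
    """Estimate the effective monomer mass m from a polymer RH curve.

    Minimizes squared RH residuals over ``m in [10, 200]`` at the known
    polymer molecular weight ``n_mw``.  This reproduces the calibration
    by which a single m is chosen to describe a family of PEG curves.
    """
    if len(curve) < 2:
        raise DomainError(f"need at least 2 points to fit, got {len(curve)}")
    if curve.unit != "ww":
        raise DomainError("polymer fits require a mass-fraction ('ww') curve")
    conc, rh_obs = curve.concentrations, curve.rh

    def residual(theta: np.ndarray) -> np.ndarray:
        params = PolymerParams(
            name=curve.solute_name, n_mw=n_mw, m_monomer=theta[0]
        )
        pred = np.array([
            float(polymer_rh(c, params, solvent)) for c in conc
        ])
        return pred - rh_obs

    res = _run_least_squares(
        residual, [50.0], ([MONOMER_BOUNDS[0]], [MONOMER_BOUNDS[1]])
    )
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return FitResult(
        estimates={"m_monomer": float(res.x[0])},
        residual_rms=rms,
        n_points=len(curve),
        converged=bool(res.success),
        message="" if res.success else res.message,
    )
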