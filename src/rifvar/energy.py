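"""Parametric model of the specific-energy spread, SD_rel(V, D).

For photon irradiation of micrometre-scale targets the relative standard
deviation of the specific-energy distribution follows

    SD_rel(V, D) = k1 / sqrt(V**k2 * D)

with V the target volume in um^3 and D the macroscopic dose in Gy.  k1 and k2
are beam-quality constants; they are only meaningful under the (Gy, um^3)
unit convention, which is recorded on the model object.  The relation forces
a 1/sqrt(2) drop of SD_rel per dose doubling, which is exactly the fold
change observed for both specific energy and foci counts.

Since the macroscopic dose D is the expectation of f(z), the full normal
description of the specific-energy distribution at (V, D) is
Normal(D, D * SD_rel(V, D)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpecificEnergyModel",
    "EnergyDistributionSpec",
    "CalibrationResult",
    "sd_rel",
    "calibrate",
    "invert_target_volume",
    "energy_distribution",
    "sample_specific_energy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecificEnergyModel:
    """(k1, k2) parametrization of SD_rel(V, D) for one beam quality.

    Attributes
    ----------
    k1 : float
        Calibration constant, > 0, under the convention V in um^3, D in Gy.
    k2 : float
        Calibration exponent, > 0, dimensionless.
    beam_label : str
        Free-text beam identifier, e.g. "Co-60".
    units : str
        Unit convention the constants are valid under (fixed).
    """

    k1: float
    k2: float
    beam_label: str = "Co-60"
    units: str = "V in um^3, D in Gy"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k1) and self.k1 > 0):
            raise ValueError("k1 must be finite and > 0")
        if not (np.isfinite(self.k2) and self.k2 > 0):
            raise ValueError("k2 must be finite and > 0")

    def sd_rel(self, V, D):
        return sd_rel(self, V, D)


@dataclass(frozen=True)
class EnergyDistributionSpec:
    """Normal description of the specific-energy distribution at one (V, D).

    ``mean_z`` equals the macroscopic dose D (the expectation of f(z));
    ``sd_rel`` is derived as sd_z / mean_z.  V and D are carried along when
    known so reports can label the distribution.
    """

    mean_z: float
    sd_z: float
    V: float | None = None
    D: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_z):
            raise ValueError("mean_z must be finite")
        if not np.isfinite(self.sd_z) or self.sd_z < 0:
            raise ValueError("sd_z must be finite and >= 0")
        if self.D is not None and abs(self.mean_z - self.D) > 1e-12 * max(1.0, abs(self.D)):
            raise ValueError("mean_z must equal the macroscopic dose D")

    @property
    def sd_rel(self) -> float:
        if self.mean_z == 0:
            return float("nan")
        return self.sd_z / self.mean_z


def sd_rel(model: SpecificEnergyModel, V, D):
    """Relative SD of the specific-energy distribution at volume V, dose D.

    Strictly decreasing in both arguments; satisfies
    sd_rel(V, 2D) = sd_rel(V, D) / sqrt(2) exactly.
    """
    V = np.asarray(V, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(V <= 0) or np.any(D <= 0):
        raise ValueError("V and D must be > 0")
    out = model.k1 / np.sqrt(V**model.k2 * D)
    return float(out) if out.ndim == 0 else out


def invert_target_volume(model: SpecificEnergyModel, sd_rel_obs: float, D: float) -> float:
    """Target volume whose energy spread equals an observed relative SD.

    Closed-form inversion V = (k1 / (sd_rel_obs * sqrt(D)))**(2 / k2);
    the exact round-trip inverse of :func:`sd_rel` in its first argument.
    """
    if sd_rel_obs <= 0:
        raise ValueError("sd_rel_obs must be > 0")
    if D <= 0:
        raise ValueError("D must be > 0")
    return float((model.k1 / (sd_rel_obs * np.sqrt(D))) ** (2.0 / model.k2))


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted model plus least-squares diagnostics in log space."""

    model: SpecificEnergyModel
    residuals_log: np.ndarray
    rmse_log: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "k1": self.model.k1,
            "k2": self.model.k2,
            "beam_label": self.model.beam_label,
            "units": self.model.units,
            "residuals_log": [float(r) for r in self.residuals_log],
            "rmse_log": self.rmse_log,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def calibrate(points, beam_label: str = "Co-60") -> CalibrationResult:
    """Fit (k1, k2) to observed (V, D, sd_rel) triples.

    The model is linear in log space,
    ln(sd_rel) = ln(k1) - (k2/2) ln(V) - (1/2) ln(D),
    so only the intercept ln(k1) and the ln(V) coefficient are free; the
    dose dependence is fixed at -1/2.  Fitted by ordinary least squares of
    y = ln(sd_rel) + (1/2) ln(D) on ln(V).

    Parameters
    ----------
    points : iterable of (V, D, sd_rel)
        At least two triples spanning at least two distinct volumes.
    """
    pts = [(float(v), float(d), float(s)) for v, d, s in points]
    if len(pts) < 2:
        raise ValueError("calibration needs at least two points")
    V = np.array([p[0] for p in pts])
    D = np.array([p[1] for p in pts])
    s = np.array([p[2] for p in pts])
    if np.any(V <= 0) or np.any(D <= 0) or np.any(s <= 0):
        raise ValueError("V, D and sd_rel must all be > 0")
    if np.unique(V).size < 2:
        raise ValueError(
            "calibration points span a single volume; k1 and k2 are not "
            "jointly identifiable (rank-deficient design)"
        )
    y = np.log(s) + 0.5 * np.log(D)
    X = np.column_stack([np.ones_like(y), np.log(V)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    k1 = float(np.exp(coef[0]))
    k2 = float(-2.0 * coef[1])
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationResult(
        model=SpecificEnergyModel(k1=k1, k2=k2, beam_label=beam_label),
        residuals_log=resid,
        rmse_log=float(np.sqrt(np.mean(resid**2))),
        r_squared=r2,
        n_points=len(pts),
    )


def energy_distribution(model: SpecificEnergyModel, V: float, D: float) -> EnergyDistributionSpec:
    """Normal specific-energy distribution Normal(D, D * sd_rel(V, D))."""
    rel = sd_rel(model, V, D)
    return EnergyDistributionSpec(mean_z=float(D), sd_z=float(D) * rel, V=float(V), D=float(D))


def sample_specific_energy(
    spec: EnergyDistributionSpec,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n specific energies (Gy) from Normal(mean_z, sd_z), z >= 0.

    Negative draws are resampled (not clipped), preserving unimodality; the
    resampled fraction is logged, with a warning above 1%.  Deterministic for
    a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.sd_z == 0:
        return np.full(n, spec.mean_z)
    z = rng.normal(spec.mean_z, spec.sd_z, n)
    n_resampled = 0
    neg = z < 0
    while neg.any():
        n_resampled += int(neg.sum())
        z[neg] = rng.normal(spec.mean_z, spec.sd_z, int(neg.sum()))
        neg = z < 0
    frac = n_resampled / n
    if frac > 0.01:
        logger.warning(
            "resampled %.2f%% of specific-energy draws at z < 0 "
            "(mean %.3g Gy, sd %.3g Gy); truncation bias may not be negligible",
            100 * frac, spec.mean_z, spec.sd_z,
        )
    elif n_resampled:
        logger.debug("resampled %d/%d negative specific-energy draws", n_resampled, n)
    return z
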