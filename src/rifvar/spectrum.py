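"""Discrete single-track spectra and the compound track-number model.

The energy a photon field deposits in a micrometre-scale target is the sum of
the contributions of a Poisson-distributed number of particle tracks, each
depositing specific energy according to the single-track frequency
distribution f1(z).  This module provides an exact discrete engine for that
compound distribution: the nu-fold self-convolution of f1(z), the mixture over
the Poisson track-number law, and the normal (Gaussian) approximation whose
moments are n*mean_z1 and sqrt(n*(mean_z1**2 + sd_z1**2)).

Spectra are represented on an explicit grid of specific-energy values (Gy)
with a probability mass per grid point.  Exactness of the discrete arithmetic
is preferred over speed; these objects are meant for desk-scale validation of
the closed-form moment relations, not for transport-code workloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SingleTrackSpectrum",
    "TrackNumberModel",
    "single_track_moments",
    "convolve_tracks",
    "compound_distribution",
    "normal_approximation",
]

_PMF_TOL = 1e-9

# hard cap on grid length so a runaway support fails loudly
_MAX_GRID_POINTS = 2**24


@dataclass(frozen=True)
class SingleTrackSpectrum:
    """A discrete specific-energy spectrum: grid of z values (Gy) and pmf.

    Also used for the nu-track and compound distributions, which live on the
    same kind of grid.

    Parameters
    ----------
    z_grid : array-like of float
        Strictly ascending specific-energy values, all >= 0, in Gy.
    pmf : array-like of float
        Probability mass per grid point; non-negative, summing to 1 within
        1e-9.
    """

    z_grid: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        p = np.asarray(self.pmf, dtype=float)
        if z.size == 0:
            raise ValueError("spectrum must contain at least one grid point")
        if z.shape != p.shape or z.ndim != 1:
            raise ValueError("z_grid and pmf must be 1-D arrays of equal length")
        if not np.all(np.isfinite(z)) or not np.all(np.isfinite(p)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(z < 0):
            raise ValueError("specific energies must be non-negative")
        if z.size > 1 and np.any(np.diff(z) <= 0):
            raise ValueError("z_grid must be strictly ascending")
        if np.any(p < 0):
            raise ValueError("pmf values must be non-negative")
        if abs(p.sum() - 1.0) > _PMF_TOL:
            raise ValueError(f"pmf must sum to 1 within {_PMF_TOL}; got {p.sum()!r}")
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "pmf", p)

    @property
    def mean(self) -> float:
        """pmf-weighted mean specific energy (Gy)."""
        return float(np.dot(self.z_grid, self.pmf))

    @property
    def sd(self) -> float:
        """pmf-weighted standard deviation of specific energy (Gy)."""
        m = self.mean
        var = float(np.dot((self.z_grid - m) ** 2, self.pmf))
        return float(np.sqrt(max(var, 0.0)))

    def resample_uniform(self, dz: float) -> "SingleTrackSpectrum":
        """Rebin onto a uniform grid 0, dz, 2*dz, ... covering the support.

        Each atom's mass is split linearly between the two bracketing grid
        points, which preserves the mean exactly and the variance to
        O(dz**2).
        """
        if dz <= 0:
            raise ValueError("dz must be positive")
        n_bins = int(np.ceil(self.z_grid[-1] / dz)) + 1
        if n_bins > _MAX_GRID_POINTS:
            raise ValueError(
                f"uniform grid would need {n_bins} points (> {_MAX_GRID_POINTS}); "
                "increase dz"
            )
        pmf = np.zeros(n_bins + 1)
        idx = self.z_grid / dz
        lo = np.floor(idx).astype(int)
        frac = idx - lo
        np.add.at(pmf, lo, self.pmf * (1.0 - frac))
        np.add.at(pmf, lo + 1, self.pmf * frac)
        # drop a trailing zero bin if the top atom sat exactly on the grid
        while pmf.size > 1 and pmf[-1] == 0.0:
            pmf = pmf[:-1]
        grid = np.arange(pmf.size) * dz
        return SingleTrackSpectrum(grid, pmf / pmf.sum())

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        if self.z_grid.size < 2:
            return self.z_grid[0] == 0.0
        steps = np.diff(self.z_grid)
        return bool(
            self.z_grid[0] == 0.0 and np.allclose(steps, steps[0], rtol=rtol)
        )


@dataclass(frozen=True)
class TrackNumberModel:
    """Poisson law for the number of tracks traversing the target.

    Parameters
    ----------
    n : float
        Mean number of tracks, >= 0.
    approximation_threshold : float
        Above this mean the Poisson law is well approximated by
        Normal(n, sqrt(n)); flagged by :attr:`normal_regime`.
    """

    n: float
    approximation_threshold: float = 20.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.n) or self.n < 0:
            raise ValueError("mean track number n must be finite and >= 0")

    @property
    def normal_regime(self) -> bool:
        """True where Normal(n, sqrt(n)) replaces the exact Poisson law."""
        return self.n > self.approximation_threshold

    def probabilities(self, mass_tolerance: float = 1e-9) -> np.ndarray:
        """Poisson pmf over nu = 0, 1, ... truncated once the cumulative
        mass reaches ``1 - mass_tolerance``."""
        if not 0.0 < mass_tolerance <= 1e-3:
            raise ValueError("mass_tolerance must be in (0, 1e-3]")
        if self.n == 0:
            return np.array([1.0])
        # generous upper bound on the truncation point
        nu_hi = int(self.n + 12.0 * np.sqrt(self.n) + 20.0)
        while stats.poisson.cdf(nu_hi, self.n) < 1.0 - mass_tolerance:
            nu_hi *= 2
        p = stats.poisson.pmf(np.arange(nu_hi + 1), self.n)
        cut = int(np.searchsorted(np.cumsum(p), 1.0 - mass_tolerance)) + 1
        return p[:cut]


def single_track_moments(spectrum: SingleTrackSpectrum) -> tuple[float, float]:
    """Mean and standard deviation (both in Gy) of a single-track spectrum."""
    return spectrum.mean, spectrum.sd


def _point_mass_at_zero() -> SingleTrackSpectrum:
    return SingleTrackSpectrum(np.array([0.0]), np.array([1.0]))


def convolve_tracks(
    spectrum: SingleTrackSpectrum,
    nu: int,
    dz: float | None = None,
    z_max: float | None = None,
) -> SingleTrackSpectrum:
    """nu-fold self-convolution f_nu(z) of a single-track spectrum.

    The distribution of the specific energy deposited by exactly ``nu``
    independent tracks.  ``nu = 0`` is the point mass at z = 0; ``nu = 1``
    returns the (uniform-grid) input.  Mean and variance scale as
    nu * mean_z1 and nu * sd_z1**2 up to grid-discretization error.

    Parameters
    ----------
    spectrum : SingleTrackSpectrum
    nu : int
        Number of tracks, >= 0.
    dz : float, optional
        Uniform grid step; defaults to mean_z1 / 50.
    z_max : float, optional
        If given, the support of f_nu may not exceed it; exceeding it raises
        rather than silently truncating.
    """
    if nu != int(nu) or nu < 0:
        raise ValueError("nu must be a non-negative integer")
    nu = int(nu)
    if nu == 0:
        return _point_mass_at_zero()
    if dz is None:
        dz = spectrum.mean / 50.0 if spectrum.mean > 0 else 1.0
    support_top = nu * spectrum.z_grid[-1]
    if z_max is not None and support_top > z_max:
        raise ValueError(
            f"support of the {nu}-track distribution extends to {support_top:g} Gy, "
            f"beyond z_max={z_max:g}; enlarge the grid or use the normal approximation"
        )
    if support_top / dz > _MAX_GRID_POINTS:
        raise ValueError(
            f"{nu}-fold convolution needs more than {_MAX_GRID_POINTS} grid points "
            "at this dz; use normal_approximation instead"
        )
    base = spectrum if spectrum.is_uniform() else spectrum.resample_uniform(dz)
    # binary exponentiation over pmf convolution
    result = np.array([1.0])
    power = base.pmf
    k = nu
    while k:
        if k & 1:
            result = np.convolve(result, power)
        k >>= 1
        if k:
            power = np.convolve(power, power)
    step = base.z_grid[1] - base.z_grid[0] if base.z_grid.size > 1 else dz
    grid = np.arange(result.size) * step
    return SingleTrackSpectrum(grid, result / result.sum())


def compound_distribution(
    spectrum: SingleTrackSpectrum,
    tracks: TrackNumberModel,
    mass_tolerance: float = 1e-9,
    dz: float | None = None,
) -> SingleTrackSpectrum:
    """Compound distribution f(z, D) = sum_nu p(nu) * f_nu(z).

    Mixes the nu-track convolutions over the Poisson track-number law,
    truncating the nu sum once the cumulative Poisson mass reaches
    ``1 - mass_tolerance``.  The exact moments of the full compound law are
    mean = n * mean_z1 and variance = n * (mean_z1**2 + sd_z1**2); the
    returned discrete distribution matches them within truncation plus grid
    error.
    """
    p_nu = tracks.probabilities(mass_tolerance)
    if p_nu.size == 1:  # n == 0
        return _point_mass_at_zero()
    if dz is None:
        dz = spectrum.mean / 50.0 if spectrum.mean > 0 else 1.0
    nu_max = p_nu.size - 1
    support_top = nu_max * spectrum.z_grid[-1]
    if support_top / dz > _MAX_GRID_POINTS:
        raise ValueError(
            f"compound support at n={tracks.n:g} needs more than "
            f"{_MAX_GRID_POINTS} grid points; use normal_approximation instead"
        )
    base = spectrum if spectrum.is_uniform() else spectrum.resample_uniform(dz)
    step = base.z_grid[1] - base.z_grid[0] if base.z_grid.size > 1 else dz
    total = np.zeros(int(np.ceil(support_top / step)) + 2)
    total[0] = p_nu[0]
    f_nu = np.array([1.0])
    for nu in range(1, nu_max + 1):
        f_nu = np.convolve(f_nu, base.pmf)
        total[: f_nu.size] += p_nu[nu] * f_nu
    while total.size > 1 and total[-1] == 0.0:
        total = total[:-1]
    grid = np.arange(total.size) * step
    return SingleTrackSpectrum(grid, total / total.sum())


def normal_approximation(
    spectrum: SingleTrackSpectrum, tracks: TrackNumberModel
):
    """Gaussian approximation of the compound distribution.

    Returns an :class:`~rifvar.energy.EnergyDistributionSpec` with
    mean n * mean_z1 and sd sqrt(n * (mean_z1**2 + sd_z1**2)) — the limit the
    repeated convolution converges to for large track numbers.
    """
    from .energy import EnergyDistributionSpec  # avoid import cycle

    if tracks.n <= 0:
        raise ValueError("normal approximation requires a positive mean track number")
    m1, s1 = single_track_moments(spectrum)
    mean = tracks.n * m1
    sd = float(np.sqrt(tracks.n * (m1**2 + s1**2)))
    return EnergyDistributionSpec(mean_z=mean, sd_z=sd)
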