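"""Lineal-energy spectra and their microdosimetric moments.

The lineal energy ``y`` (keV/μm) is the energy imparted to a microscopic
site divided by the mean chord length of the site — the stochastic
analogue of LET at the scale of a cell nucleus or chromosome domain.
Two probability densities describe a radiation field at that scale:

* ``f(y)`` — the frequency density: the probability that a single
  energy-deposition event has lineal energy in ``[y, y + dy)``;
* ``d(y)`` — the dose density: the fraction of absorbed dose delivered
  by events with lineal energy in ``[y, y + dy)``; ``d(y) ∝ y f(y)``.

This module provides the spectrum container, the frequency- and
dose-mean moments (ȳ_F, ȳ_D), the saturation-corrected dose-mean lineal
energy y* that phenomenologically accounts for the overkill effect at
very high lineal energies, and dose-weighted mixing of spectra from
different particle species.

Spectra are represented either on a continuous grid (trapezoidal
quadrature) or as discrete line spectra (exact sums); moments and the
saturation correction use the same code path via per-point quadrature
weights, so discrete spectra incur no quadrature error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError, CompositionError

__all__ = [
    "LinealEnergySpectrum",
    "MicrodoseSummary",
    "dose_distribution",
    "frequency_mean",
    "dose_mean",
    "saturation_corrected",
    "summarize",
    "mix_spectra",
    "default_log_grid",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

#: Default log-spaced evaluation grid, keV/μm.
DEFAULT_GRID_MIN = 1e-2
DEFAULT_GRID_MAX = 1e3
DEFAULT_GRID_POINTS = 256

#: Saturation parameters (keV/μm) conventionally used with y*.
STANDARD_Y0_VALUES = (100.0, 150.0, 200.0)

#: Constructor tolerance: densities whose integral deviates from 1 by less
#: than this are silently renormalised; larger deviations raise (they almost
#: always indicate a unit mistake, e.g. keV instead of keV/μm).
_NORMALIZATION_SLACK = 0.01


def default_log_grid(
    y_min: float = DEFAULT_GRID_MIN,
    y_max: float = DEFAULT_GRID_MAX,
    n: int = DEFAULT_GRID_POINTS,
) -> np.ndarray:
    """Log-spaced lineal-energy grid in keV/μm."""
    return np.geomspace(y_min, y_max, n)


@dataclass(frozen=True)
class LinealEnergySpectrum:
    """A tabulated lineal-energy probability density.

    Parameters
    ----------
    y_grid :
        Lineal energy values, keV/μm; strictly increasing and positive.
    f_density :
        Probability density per keV/μm on ``y_grid`` (or, for
        ``discrete=True``, probability weights per line).  Must integrate
        (sum) to 1 within 1%; the constructor renormalises exactly and
        records the raw integral.
    discrete :
        If True the spectrum is a set of discrete lines and all moments
        are exact sums.
    site_diameter :
        Diameter of the sensitive site, μm (metadata only; 1 μm is the
        conventional chromosome-domain scale).
    label :
        Free-text description.
    """

    y_grid: np.ndarray
    f_density: np.ndarray
    discrete: bool = False
    site_diameter: float = 1.0
    label: str = ""
    raw_integral: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y_grid, dtype=float)
        f = np.asarray(self.f_density, dtype=float)
        if y.ndim != 1 or f.shape != y.shape or y.size == 0:
            raise InvalidInputError("y_grid and f_density must be equal-length 1-D arrays")
        if not self.discrete and y.size < 2:
            raise InvalidInputError("a continuous spectrum needs at least two grid points")
        if not np.all(np.isfinite(y)) or not np.all(y > 0):
            raise InvalidInputError("y_grid values must be positive and finite")
        if np.any(np.diff(y) <= 0):
            raise InvalidInputError("y_grid must be strictly increasing")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise InvalidInputError("f_density values must be non-negative and finite")
        integral = float(np.sum(self._weights_for(y) * f))
        if integral <= 0:
            raise InvalidInputError("spectrum density integrates to zero")
        if abs(integral - 1.0) >= _NORMALIZATION_SLACK:
            raise InvalidInputError(
                f"spectrum density integrates to {integral:.6g}, not 1; "
                "check units (use from_unnormalized for raw tallies)"
            )
        object.__setattr__(self, "y_grid", y)
        object.__setattr__(self, "f_density", f / integral)
        object.__setattr__(self, "raw_integral", integral * self.raw_integral)

    # -- quadrature ----------------------------------------------------

    def _weights_for(self, y: np.ndarray) -> np.ndarray:
        if self.discrete:
            return np.ones_like(y)
        w = np.empty_like(y)
        w[0] = 0.5 * (y[1] - y[0])
        w[-1] = 0.5 * (y[-1] - y[-2])
        w[1:-1] = 0.5 * (y[2:] - y[:-2])
        return w

    @property
    def quadrature_weights(self) -> np.ndarray:
        """Trapezoidal weights (or unit weights for a line spectrum)."""
        return self._weights_for(self.y_grid)

    def integral(self, values: np.ndarray) -> float:
        """∫ values(y) dy on this spectrum's grid (Σ for line spectra)."""
        return float(np.sum(self.quadrature_weights * values))

    # -- constructors --------------------------------------------------

    @classmethod
    def from_unnormalized(
        cls,
        y_grid: Sequence[float],
        density: Sequence[float],
        *,
        discrete: bool = False,
        site_diameter: float = 1.0,
        label: str = "",
    ) -> "LinealEnergySpectrum":
        """Build a spectrum from a raw (unnormalised) non-negative density."""
        y = np.asarray(y_grid, dtype=float)
        f = np.asarray(density, dtype=float)
        if y.ndim != 1 or f.shape != y.shape or y.size == 0:
            raise InvalidInputError("y_grid and density must be equal-length 1-D arrays")
        probe = cls.__new__(cls)
        object.__setattr__(probe, "discrete", discrete)
        integral = float(np.sum(probe._weights_for(y) * f))
        if not np.isfinite(integral) or integral <= 0:
            raise InvalidInputError("raw density must have a positive finite integral")
        spec = cls(
            y_grid=y,
            f_density=f / integral,
            discrete=discrete,
            site_diameter=site_diameter,
            label=label,
        )
        return replace(spec, raw_integral=integral)

    @classmethod
    def single_line(cls, y: float, **kwargs) -> "LinealEnergySpectrum":
        """Degenerate spectrum with all probability at one lineal energy."""
        return cls(np.asarray([y], dtype=float), np.asarray([1.0]), discrete=True, **kwargs)


# ---------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------

def frequency_mean(spec: LinealEnergySpectrum) -> float:
    """Frequency-mean lineal energy ȳ_F = ∫ y f(y) dy, keV/μm."""
    return spec.integral(spec.y_grid * spec.f_density)


def dose_mean(spec: LinealEnergySpectrum) -> float:
    """Dose-mean lineal energy ȳ_D = ∫ y² f(y) dy / ∫ y f(y) dy, keV/μm.

    Equivalently the first moment of the dose density d(y); the
    dose-weighted average lineal energy with which dose is delivered.
    """
    y_f = frequency_mean(spec)
    if y_f <= 0:
        raise InvalidInputError("degenerate spectrum: frequency mean is zero")
    return spec.integral(spec.y_grid**2 * spec.f_density) / y_f


def dose_distribution(spec: LinealEnergySpectrum) -> LinealEnergySpectrum:
    """Dose density d(y) = y f(y) / ȳ_F on the same grid.

    The result is itself a normalised `LinealEnergySpectrum` (its
    ``f_density`` field holds d(y)); its *frequency* mean is the
    dose-mean of the input.
    """
    y_f = frequency_mean(spec)
    if y_f <= 0:
        raise InvalidInputError("degenerate spectrum: frequency mean is zero")
    d = spec.y_grid * spec.f_density / y_f
    return LinealEnergySpectrum(
        spec.y_grid,
        d,
        discrete=spec.discrete,
        site_diameter=spec.site_diameter,
        label=(spec.label + " [dose-weighted]").strip(),
    )


def saturation_corrected(spec: LinealEnergySpectrum, y0: float) -> float:
    """Saturation-corrected dose-mean lineal energy y*, keV/μm.

    y* = y0² ∫ (1 − exp(−y²/y0²)) f(y) dy / ∫ y f(y) dy

    The exponential saturation kernel down-weights lineal energies well
    above the saturation parameter ``y0``, emulating the overkill
    effect: single events that deposit far more energy than needed to
    kill a cell do not produce proportionally more biological effect.
    ``y0`` is conventionally set at or above 100 keV/μm.

    y* is monotone non-decreasing in ``y0``, bounded above by ȳ_D, and
    converges to ȳ_D as ``y0 → ∞``.
    """
    if not np.isfinite(y0) or y0 <= 0:
        raise InvalidParameterError(f"saturation parameter y0 must be > 0, got {y0}")
    y_f = frequency_mean(spec)
    if y_f <= 0:
        raise InvalidInputError("degenerate spectrum: frequency mean is zero")
    x = np.square(spec.y_grid / y0)
    kernel = -np.expm1(-x)  # 1 − exp(−y²/y0²), accurate for small arguments
    return y0**2 * spec.integral(kernel * spec.f_density) / y_f


@dataclass(frozen=True)
class MicrodoseSummary:
    """Moments of one lineal-energy spectrum.

    Invariants (Cauchy–Schwarz and the saturation bound): ``y_F ≤ y_D``
    and ``y_star ≤ min(y_D, y0²/y_F)``.
    """

    y_F: float
    y_D: float
    y_star: float
    y0: float


def summarize(spec: LinealEnergySpectrum, y0: float = 150.0) -> MicrodoseSummary:
    """Compute ȳ_F, ȳ_D and y* of one spectrum in a single pass."""
    return MicrodoseSummary(
        y_F=frequency_mean(spec),
        y_D=dose_mean(spec),
        y_star=saturation_corrected(spec, y0),
        y0=y0,
    )


# ---------------------------------------------------------------------
# Mixing
# ---------------------------------------------------------------------

def _resample_density(spec: LinealEnergySpectrum, grid: np.ndarray) -> np.ndarray:
    """Linearly interpolate f(y) onto ``grid`` (zero outside support)."""
    return np.interp(grid, spec.y_grid, spec.f_density, left=0.0, right=0.0)


def mix_spectra(
    spectra: Sequence[LinealEnergySpectrum],
    dose_fractions: Sequence[float],
    y0: float = 150.0,
    n_grid: int = 1024,
) -> tuple[LinealEnergySpectrum, MicrodoseSummary]:
    """Dose-weighted mixture of per-species spectra.

    Each component is converted to its dose density d_s(y) and the
    mixture dose density is d_mix = Σ w_s d_s, with w_s the relative
    dose contribution of species s.  Because ȳ_D is the *first* moment
    of d(y), the mixture satisfies ȳ_D,mix = Σ w_s ȳ_D,s exactly (on
    the common resampling grid).

    Returns the mixed dose spectrum and its `MicrodoseSummary`
    (ȳ_F and y* are recovered from f_mix = d_mix/y after
    renormalisation).
    """
    if len(spectra) == 0:
        raise InvalidInputError("mix_spectra needs at least one component")
    w = np.asarray(dose_fractions, dtype=float)
    if w.shape != (len(spectra),) or np.any(w < 0) or not np.all(np.isfinite(w)):
        raise CompositionError("dose fractions must be non-negative, one per spectrum")
    if abs(w.sum() - 1.0) > 1e-6:
        raise CompositionError(f"dose fractions sum to {w.sum():.8g}, expected 1")

    if all(s.discrete for s in spectra):
        # Exact branch: merge lines, no quadrature error.
        y_all = np.concatenate([s.y_grid for s in spectra])
        d_all = np.concatenate(
            [ws * dose_distribution(s).f_density for s, ws in zip(spectra, w)]
        )
        order = np.argsort(y_all, kind="stable")
        y_sorted, d_sorted = y_all[order], d_all[order]
        y_unique, inverse = np.unique(y_sorted, return_inverse=True)
        d_merged = np.zeros_like(y_unique)
        np.add.at(d_merged, inverse, d_sorted)
        mixed = LinealEnergySpectrum(y_unique, d_merged, discrete=True, label="mixture [dose-weighted]")
        f_unnorm = d_merged / y_unique
        f_mix = LinealEnergySpectrum.from_unnormalized(y_unique, f_unnorm, discrete=True)
    else:
        # reuse a shared grid when possible (then the identity
        # ȳ_D,mix = Σ w_s ȳ_D,s is exact against the inputs themselves);
        # otherwise resample to a common log grid spanning all supports
        shared = len(spectra) == 1 or all(
            not s.discrete and np.array_equal(s.y_grid, spectra[0].y_grid)
            for s in spectra
        )
        if shared:
            grid = spectra[0].y_grid
            components = list(spectra)
        else:
            lo = min(float(s.y_grid[0]) for s in spectra)
            hi = max(float(s.y_grid[-1]) for s in spectra)
            grid = np.geomspace(lo, hi, n_grid)
            components = [
                LinealEnergySpectrum.from_unnormalized(
                    grid, _resample_density(s, grid), label=s.label
                )
                for s in spectra
            ]
        d_mix = np.zeros_like(grid, dtype=float)
        for s, ws in zip(components, w):
            d_mix += ws * dose_distribution(s).f_density
        mixed = LinealEnergySpectrum.from_unnormalized(
            grid, d_mix, label="mixture [dose-weighted]"
        )
        f_mix = LinealEnergySpectrum.from_unnormalized(grid, mixed.f_density / grid)

    return mixed, summarize(f_mix, y0=y0)


# ---------------------------------------------------------------------
# I/O — spectrum CSV: columns `y_keV_um, f_density`, '#' comments.
# ---------------------------------------------------------------------

def read_spectrum_csv(path, **kwargs) -> LinealEnergySpectrum:
    """Read a spectrum from CSV with columns ``y_keV_um, f_density``."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = {"y_keV_um", "f_density"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"spectrum CSV missing columns: {sorted(missing)}")
    return LinealEnergySpectrum(
        df["y_keV_um"].to_numpy(float), df["f_density"].to_numpy(float), **kwargs
    )


def write_spectrum_csv(spec: LinealEnergySpectrum, path) -> None:
    """Write a spectrum as CSV with columns ``y_keV_um, f_density``."""
    pd.DataFrame({"y_keV_um": spec.y_grid, "f_density": spec.f_density}).to_csv(
        path, index=False
    )
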