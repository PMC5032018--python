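"""Energy-dependent neutron RBE models and regulatory reference curves.

RBE (relative biological effectiveness) is the ratio of the absorbed
dose of a low-LET reference photon field to the absorbed dose of the
test radiation producing the same effect.  Two complementary models
are provided:

* a **phenomenological** model: RBE(E) = y*_n(E) / y*_ref — the ratio of
  the saturation-corrected dose-mean lineal energy of the neutron field
  to that of the reference photon field, at a shared saturation
  parameter y0;
* a **mechanistic** model: RBE(E) = Y_n(E) / Y_ref — the ratio of DSB
  cluster yields per Gy per cell, justified by the linearity of the
  cluster endpoint with dose (two independent tracks essentially never
  cooperate within 25 bp, so the yield counts tracks and tracks count
  dose).

For qualitative comparison only, the module also embeds the two
regulatory weighting curves plotted against such models: the ICRP
Publication 103 continuous neutron radiation weighting factor w_R and
the U.S. NRC (10 CFR Part 20) neutron quality-factor table.  Both are
transcriptions from the regulations; radiation weighting factors are
defined for radiation-protection purposes, not individual risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "ReferenceField",
    "RBECurve",
    "rbe_ystar",
    "rbe_cluster",
    "icrp103_wr",
    "nrc_quality_factor",
]


@dataclass(frozen=True)
class ReferenceField:
    """Reference photon field scalars entering the RBE denominators.

    ``y_star_ref`` maps saturation parameter y0 (keV/μm) to the
    reference field's y* (keV/μm); ``cluster_yield_ref`` is its DSB
    cluster yield per Gy per cell.  The default label describes a
    filtered 220 kV X-ray field of the kind conventionally used as
    low-LET reference.
    """

    y_star_ref: dict[float, float]
    cluster_yield_ref: float
    label: str = "X-ray 220 kV, 2 mm Cu"

    def __post_init__(self) -> None:
        if self.cluster_yield_ref <= 0:
            raise ConfigurationError("reference cluster yield must be positive")
        if any(v <= 0 for v in self.y_star_ref.values()):
            raise ConfigurationError("reference y* values must be positive")


@dataclass(frozen=True)
class RBECurve:
    """RBE values with uncertainties on a neutron-energy grid."""

    model: str  # "ystar" | "dsb_cluster"
    region: str
    energies: np.ndarray
    rbe: np.ndarray
    rbe_err: np.ndarray
    y0: float | None = None  # saturation parameter for the ystar model

    def __post_init__(self) -> None:
        if self.model not in ("ystar", "dsb_cluster"):
            raise ConfigurationError(f"unknown RBE model {self.model!r}")
        e = np.asarray(self.energies, dtype=float)
        r = np.asarray(self.rbe, dtype=float)
        s = np.asarray(self.rbe_err, dtype=float)
        if not (e.shape == r.shape == s.shape):
            raise ConfigurationError("energies, rbe and rbe_err must share a shape")
        if np.any(r < 0):
            raise ConfigurationError("RBE values must be non-negative")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "rbe", r)
        object.__setattr__(self, "rbe_err", s)


def rbe_ystar(
    y_star_n: float,
    ref: ReferenceField,
    y0: float,
    *,
    y_star_n_err: float = 0.0,
    y_star_ref_err: float = 0.0,
) -> tuple[float, float]:
    """Phenomenological RBE: neutron y* over reference-photon y*.

    Both y* values must be computed with the same saturation parameter
    ``y0``; relative errors add in quadrature.
    """
    if y0 not in ref.y_star_ref:
        raise ConfigurationError(
            f"reference field has no y* for y0={y0:g} keV/μm "
            f"(available: {sorted(ref.y_star_ref)})"
        )
    denom = ref.y_star_ref[y0]
    value = y_star_n / denom
    rel = math.hypot(
        y_star_n_err / y_star_n if y_star_n > 0 else 0.0,
        y_star_ref_err / denom,
    )
    return value, value * rel


def rbe_cluster(
    cluster_yield_n: float,
    ref: ReferenceField,
    *,
    yield_n_err: float = 0.0,
    yield_ref_err: float = 0.0,
) -> tuple[float, float]:
    """Mechanistic RBE: neutron DSB-cluster yield over the photon yield."""
    value = cluster_yield_n / ref.cluster_yield_ref
    rel = math.hypot(
        yield_n_err / cluster_yield_n if cluster_yield_n > 0 else 0.0,
        yield_ref_err / ref.cluster_yield_ref,
    )
    return value, value * rel


# ---------------------------------------------------------------------
# Regulatory reference curves (qualitative comparison only)
# ---------------------------------------------------------------------

def icrp103_wr(E_n):
    """ICRP Publication 103 continuous neutron radiation weighting factor.

    Three log-Gaussian branches in neutron energy E (MeV)::

        E < 1 MeV:        2.5 + 18.2 exp(−[ln E]²/6)
        1 ≤ E ≤ 50 MeV:   5.0 + 17.0 exp(−[ln 2E]²/6)
        E > 50 MeV:       2.5 + 3.25 exp(−[ln 0.04E]²/6)

    The curve peaks at w_R ≈ 20.7 near 1 MeV.  As printed in the
    regulation the branches agree only to ≈ 0.01 at the boundaries;
    the formula is transcribed as published.  Accepts scalars or
    arrays; defined for radiation-protection purposes only.
    """
    E = np.asarray(E_n, dtype=float)
    if np.any(E <= 0) or not np.all(np.isfinite(E)):
        raise InvalidParameterError("neutron energy must be positive and finite")
    low = 2.5 + 18.2 * np.exp(-np.log(E) ** 2 / 6.0)
    mid = 5.0 + 17.0 * np.exp(-np.log(2.0 * E) ** 2 / 6.0)
    high = 2.5 + 3.25 * np.exp(-np.log(0.04 * E) ** 2 / 6.0)
    out = np.where(E < 1.0, low, np.where(E <= 50.0, mid, high))
    return float(out) if np.isscalar(E_n) else out


#: U.S. NRC 10 CFR 20.1004(b) table 2: mean quality factor versus neutron
#: energy (MeV), transcribed from the regulation.
_NRC_TABLE_E = np.array([
    2.5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 5e-1,
    1.0, 2.5, 5.0, 7.0, 10.0, 14.0, 20.0, 40.0, 60.0,
    1e2, 2e2, 3e2, 4e2,
])
_NRC_TABLE_Q = np.array([
    2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.5, 7.5, 11.0,
    11.0, 9.0, 8.0, 7.0, 6.5, 7.5, 8.0, 7.0, 5.5,
    4.0, 3.5, 3.5, 3.5,
])


def nrc_quality_factor(E_n):
    """U.S. NRC neutron mean quality factor, log-linear in energy.

    Interpolates the 10 CFR 20 table in log10(E); outside the table the
    nearest tabulated value is used.  Note the secondary rise around
    20 MeV that the ICRP continuous curve does not show.
    """
    E = np.asarray(E_n, dtype=float)
    if np.any(E <= 0) or not np.all(np.isfinite(E)):
        raise InvalidParameterError("neutron energy must be positive and finite")
    out = np.interp(np.log10(E), np.log10(_NRC_TABLE_E), _NRC_TABLE_Q)
    return float(out) if np.isscalar(E_n) else out
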