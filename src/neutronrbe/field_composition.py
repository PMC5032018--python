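"""The two-number-per-species condensation of a neutron-induced mixed field.

A neutron beam traversing tissue accelerates a mixed field of secondary
charged particles (electrons from capture photons, recoil protons,
deuterons, α particles and C/N/O recoils).  For coupling transport
output to DNA-damage models, the full field at one neutron energy and
scoring depth is condensed to two numbers per species: its relative
contribution to the total neutron dose, and its dose-mean lineal energy
ȳ_D (the clustering indicator).  This module holds that data model, its
validation and interpolation across neutron energy, and the small set
of nuclear-physics helpers the analysis needs:

* elastic-kinematics maximal energy transfer,
* Q-values of the two dominant capture reactions from an embedded
  atomic-mass table,
* conversions between dose, fluence and LET, and the track-average LET
  estimator used for particles stopping inside the nucleus.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CompositionError,
    InvalidInputError,
    InvalidParameterError,
    RangeError,
    UnknownReactionError,
)

__all__ = [
    "SPECIES",
    "SpeciesDoseRecord",
    "FieldComposition",
    "PhantomGeometry",
    "validate_composition",
    "interpolate_composition",
    "max_energy_transfer",
    "reaction_q_value",
    "let_from_dose_fluence",
    "dose_from_let_fluence",
    "track_average_let",
    "read_composition_csv",
    "write_composition_csv",
    "read_composition_json",
    "write_composition_json",
]

logger = logging.getLogger(__name__)

#: Closed enumeration of secondary charged species tracked in the analysis.
#: Tissue recoils with Z > 8 are excluded; their dose share is at most a few
#: per cent at the highest neutron energies and is carried as a residual.
SPECIES = ("electron", "proton", "deuteron", "alpha", "C", "N", "O")

REGIONS = ("inner", "intermediate", "outer")

#: Neutron mass in atomic mass units (CODATA).
NEUTRON_MASS_U = 1.008665

#: Atomic mass excesses are avoided; we embed atomic masses directly (u),
#: AME2020 values rounded to 1e-8 u (≈ 10 eV precision, far below the keV
#: level quoted for reaction energetics).
ATOMIC_MASS_U = {
    "n": 1.00866492,
    "H1": 1.00782503,
    "H2": 2.01410178,
    "C12": 12.0,
    "C14": 14.00324199,
    "N14": 14.00307400,
    "O16": 15.99491462,
}

#: Atomic-mass-unit energy equivalent, MeV (CODATA).
U_TO_MEV = 931.49410242

#: Reactions with embedded energetics: initial and final atomic species.
#: H(n,γ)d — radiative neutron capture on hydrogen; the binding-energy gain
#: is carried off by a 2.2 MeV photon whose electrons dominate the low-energy
#: neutron dose.  N14(n,p)C14 — thermal capture on nitrogen; the 626 keV
#: energy release is shared by the proton and the ¹⁴C recoil.
_REACTIONS = {
    "H(n,g)d": (("H1", "n"), ("H2",)),
    "N14(n,p)C14": (("N14", "n"), ("C14", "H1")),
}
_REACTION_ALIASES = {
    "h(n,g)d": "H(n,g)d",
    "p(n,g)d": "H(n,g)d",
    "h(n,gamma)d": "H(n,g)d",
    "n14(n,p)c14": "N14(n,p)C14",
}

#: Gy per (keV/μm × μm⁻² / (g/cm³)): 1 keV/μm · 1 μm⁻² deposits
#: 1.602e-16 J per kg·(1e-15 m³·1e3 kg/m³) … = 0.1602 Gy in unit-density matter.
_DOSE_UNIT_FACTOR = 0.1602


# ---------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesDoseRecord:
    """Dose fraction and dose-mean lineal energy of one secondary species."""

    species: str
    dose_fraction: float
    y_D: float
    dose_fraction_err: float = 0.0
    y_D_err: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidInputError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        if not 0.0 <= self.dose_fraction <= 1.0:
            raise InvalidInputError(
                f"dose_fraction must lie in [0, 1], got {self.dose_fraction}"
            )
        if self.y_D <= 0 or not math.isfinite(self.y_D):
            raise InvalidInputError(f"y_D must be positive, got {self.y_D}")
        if self.dose_fraction_err < 0 or self.y_D_err < 0:
            raise InvalidInputError("uncertainties must be non-negative")


@dataclass(frozen=True)
class FieldComposition:
    """Per-species condensation of the mixed field at one energy and region."""

    neutron_energy: float  # MeV
    region: str
    records: tuple[SpeciesDoseRecord, ...]
    residual_fraction: float = 0.0  # dose share of excluded Z > 8 species

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InvalidInputError(f"unknown region {self.region!r}; expected {REGIONS}")
        if self.neutron_energy <= 0:
            raise InvalidInputError("neutron_energy must be positive")
        object.__setattr__(self, "records", tuple(self.records))
        seen = [r.species for r in self.records]
        if len(set(seen)) != len(seen):
            raise InvalidInputError(f"duplicate species in composition: {seen}")

    @property
    def fraction_sum(self) -> float:
        return float(sum(r.dose_fraction for r in self.records))

    def fraction(self, species: str) -> float:
        for r in self.records:
            if r.species == species:
                return r.dose_fraction
        return 0.0

    def record(self, species: str) -> SpeciesDoseRecord | None:
        for r in self.records:
            if r.species == species:
                return r
        return None


@dataclass(frozen=True)
class PhantomGeometry:
    """Spherical tissue phantom with spherical scoring regions.

    Defaults describe a trunk-sized soft-tissue sphere (radius 15 cm)
    with three scoring spheres of radius 1.5 cm centred on a common
    diameter at offsets 0 (inner), 7.5 (intermediate) and 13.5 cm
    (outer, touching the surface).
    """

    phantom_radius: float = 15.0
    scoring_radius: float = 1.5
    scoring_offsets: tuple[float, ...] = (0.0, 7.5, 13.5)

    def __post_init__(self) -> None:
        if self.phantom_radius <= 0 or self.scoring_radius <= 0:
            raise InvalidParameterError("radii must be positive")
        for d in self.scoring_offsets:
            if d < 0 or d + self.scoring_radius > self.phantom_radius:
                raise InvalidParameterError(
                    f"scoring sphere at offset {d} cm does not fit inside the phantom"
                )

    @property
    def region_offsets(self) -> dict[str, float]:
        return dict(zip(REGIONS, self.scoring_offsets))


# ---------------------------------------------------------------------
# Validation and interpolation
# ---------------------------------------------------------------------

def validate_composition(comp: FieldComposition) -> FieldComposition:
    """Enforce the dose-fraction sum rule, renormalising small deviations.

    Fractions whose sum lies in [0.95, 1.05] are renormalised to 1
    (with a logged warning when the deviation exceeds 1e-3, the
    tolerance attributed to the excluded Z > 8 residual); sums outside
    that window raise `CompositionError`.
    """
    total = comp.fraction_sum
    if not 0.95 <= total <= 1.05:
        raise CompositionError(
            f"dose fractions at E_n={comp.neutron_energy:g} MeV ({comp.region}) "
            f"sum to {total:.4g}, outside [0.95, 1.05]"
        )
    if abs(total - 1.0) <= 1e-3:
        return comp
    residual = 1.0 - total
    if residual > 0.05:
        raise CompositionError(
            f"residual dose fraction {residual:.3g} exceeds the 0.05 budget "
            f"for excluded species at E_n={comp.neutron_energy:g} MeV"
        )
    logger.warning(
        "renormalising dose fractions (sum %.4f) at E_n=%g MeV (%s); "
        "residual %.4f attributed to excluded species",
        total, comp.neutron_energy, comp.region, residual,
    )
    records = tuple(
        replace(r, dose_fraction=r.dose_fraction / total,
                dose_fraction_err=r.dose_fraction_err / total)
        for r in comp.records
    )
    return replace(comp, records=records, residual_fraction=residual)


def interpolate_composition(
    table: Sequence[FieldComposition], E_n: float
) -> FieldComposition:
    """Interpolate a composition table to neutron energy ``E_n`` (MeV).

    Dose fractions are interpolated linearly in log10(E) and
    renormalised; ȳ_D is interpolated log-log between nodes where the
    species is present (nearest present node otherwise).  A species
    absent at the lower bracketing node (its production channel below
    threshold there) keeps fraction 0 at that node, so the interpolant
    vanishes at and below the last absent node and no channel is
    extrapolated across its threshold.
    """
    if len(table) < 1:
        raise InvalidInputError("empty composition table")
    regions = {c.region for c in table}
    if len(regions) != 1:
        raise InvalidInputError(f"mixed regions in composition table: {sorted(regions)}")
    nodes = sorted(table, key=lambda c: c.neutron_energy)
    energies = np.array([c.neutron_energy for c in nodes])
    if not (energies[0] <= E_n <= energies[-1]):
        raise RangeError(
            f"E_n={E_n:g} MeV outside tabulated range "
            f"[{energies[0]:g}, {energies[-1]:g}] MeV"
        )
    exact = int(np.argmin(np.abs(energies - E_n)))
    if math.isclose(energies[exact], E_n, rel_tol=1e-12):
        return nodes[exact]
    hi = int(np.searchsorted(energies, E_n))
    lo = hi - 1
    c_lo, c_hi = nodes[lo], nodes[hi]
    t = (math.log10(E_n) - math.log10(energies[lo])) / (
        math.log10(energies[hi]) - math.log10(energies[lo])
    )
    records = []
    for sp in SPECIES:
        r_lo, r_hi = c_lo.record(sp), c_hi.record(sp)
        w_lo = r_lo.dose_fraction if r_lo else 0.0
        w_hi = r_hi.dose_fraction if r_hi else 0.0
        w = (1 - t) * w_lo + t * w_hi
        if w <= 0:
            continue
        if r_lo and r_hi:
            y = math.exp((1 - t) * math.log(r_lo.y_D) + t * math.log(r_hi.y_D))
            y_err = (1 - t) * r_lo.y_D_err + t * r_hi.y_D_err
        else:
            present = r_lo or r_hi
            y, y_err = present.y_D, present.y_D_err
        w_err = (1 - t) * (r_lo.dose_fraction_err if r_lo else 0.0) + t * (
            r_hi.dose_fraction_err if r_hi else 0.0
        )
        records.append(
            SpeciesDoseRecord(sp, dose_fraction=w, y_D=y,
                              dose_fraction_err=w_err, y_D_err=y_err)
        )
    comp = FieldComposition(E_n, c_lo.region, tuple(records))
    total = comp.fraction_sum
    records = tuple(
        replace(r, dose_fraction=r.dose_fraction / total,
                dose_fraction_err=r.dose_fraction_err / total)
        for r in comp.records
    )
    return validate_composition(replace(comp, records=records))


# ---------------------------------------------------------------------
# Kinematics and reaction energetics
# ---------------------------------------------------------------------

def max_energy_transfer(E_n: float, m_t: float) -> float:
    """Maximal energy a neutron of energy ``E_n`` transfers to a target.

    Head-on elastic scattering gives
    ``E_max = 4 m_n m_t / (m_n + m_t)² · E_n`` with ``m_t`` the target
    mass in u.  The kinematic fraction is 1 only for ``m_t = m_n``
    (hydrogen), which is why recoil protons dominate the dose in the
    elastic regime.
    """
    if E_n < 0:
        raise InvalidParameterError(f"E_n must be non-negative, got {E_n}")
    if m_t <= 0:
        raise InvalidParameterError(f"target mass must be positive, got {m_t}")
    m_n = NEUTRON_MASS_U
    return 4.0 * m_n * m_t / (m_n + m_t) ** 2 * E_n


def reaction_q_value(reaction_id: str) -> float:
    """Q-value (MeV) of an embedded capture reaction.

    Supported: ``"H(n,g)d"`` (→ 2.2246 MeV, the capture-photon energy)
    and ``"N14(n,p)C14"`` (→ 0.626 MeV shared by proton and ¹⁴C).
    Atomic masses are used throughout, so electron counts balance.
    A reaction id prefixed with ``"-"`` denotes the reverse reaction
    (Q changes sign exactly).
    """
    rid = reaction_id.strip()
    sign = 1.0
    if rid.startswith("-"):
        sign, rid = -1.0, rid[1:].strip()
    key = _REACTION_ALIASES.get(rid.lower())
    if key is None:
        raise UnknownReactionError(
            f"unknown reaction {reaction_id!r}; supported: {sorted(_REACTIONS)}"
        )
    initial, final = _REACTIONS[key]
    dm = sum(ATOMIC_MASS_U[s] for s in initial) - sum(ATOMIC_MASS_U[s] for s in final)
    return sign * dm * U_TO_MEV


# ---------------------------------------------------------------------
# LET estimators
# ---------------------------------------------------------------------

def dose_from_let_fluence(let: float, fluence: float, density: float = 1.0) -> float:
    """Absorbed dose (Gy) from LET (keV/μm) and fluence (μm⁻²).

    D = 0.1602 · L · Φ / ρ, with ρ in g/cm³.
    """
    if fluence < 0 or let < 0 or density <= 0:
        raise InvalidParameterError("let and fluence must be ≥ 0, density > 0")
    return _DOSE_UNIT_FACTOR * let * fluence / density


def let_from_dose_fluence(dose: float, fluence: float, density: float = 1.0) -> float:
    """LET (keV/μm) over a microscopic volume from dose and fluence.

    Inverts D = 0.1602 · L · Φ / ρ; used when energetic particles cross
    the whole nucleus at a known fluence.
    """
    if fluence <= 0:
        raise InvalidParameterError(f"fluence must be positive, got {fluence}")
    if density <= 0:
        raise InvalidParameterError(f"density must be positive, got {density}")
    if dose < 0:
        raise InvalidParameterError(f"dose must be non-negative, got {dose}")
    return dose * density / (_DOSE_UNIT_FACTOR * fluence)


def track_average_let(E0: float, range_fn: Callable[[float], float]) -> float:
    """Track-average LET (keV/μm) of a particle stopping in the target.

    For particles too slow to traverse the nucleus, the fluence-based
    estimator breaks down and LET is better estimated as the initial
    energy ``E0`` (MeV) divided by the track length ``range_fn(E0)``
    (μm).
    """
    if E0 < 0:
        raise InvalidParameterError(f"E0 must be non-negative, got {E0}")
    r = float(range_fn(E0))
    if r <= 0 or not math.isfinite(r):
        raise InvalidParameterError(f"range must be positive and finite, got {r}")
    return 1e3 * E0 / r  # MeV → keV


# ---------------------------------------------------------------------
# I/O — composition CSV/JSON
# columns: E_n_MeV, region, species, dose_fraction, dose_fraction_err,
#          yD_keV_um, yD_err
# ---------------------------------------------------------------------

_CSV_COLUMNS = [
    "E_n_MeV", "region", "species", "dose_fraction", "dose_fraction_err",
    "yD_keV_um", "yD_err",
]


def compositions_to_frame(table: Sequence[FieldComposition]) -> pd.DataFrame:
    rows = [
        {
            "E_n_MeV": c.neutron_energy,
            "region": c.region,
            "species": r.species,
            "dose_fraction": r.dose_fraction,
            "dose_fraction_err": r.dose_fraction_err,
            "yD_keV_um": r.y_D,
            "yD_err": r.y_D_err,
        }
        for c in table
        for r in c.records
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_compositions(df: pd.DataFrame) -> list[FieldComposition]:
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"composition table missing columns: {sorted(missing)}")
    out = []
    for (e, region), grp in df.groupby(["E_n_MeV", "region"], sort=True):
        records = tuple(
            SpeciesDoseRecord(
                species=row.species,
                dose_fraction=float(row.dose_fraction),
                dose_fraction_err=float(row.dose_fraction_err),
                y_D=float(row.yD_keV_um),
                y_D_err=float(row.yD_err),
            )
            for row in grp.itertuples()
        )
        out.append(FieldComposition(float(e), str(region), records))
    return out


def write_composition_csv(table: Sequence[FieldComposition], path) -> None:
    compositions_to_frame(table).to_csv(path, index=False)


def read_composition_csv(path) -> list[FieldComposition]:
    return frame_to_compositions(pd.read_csv(path, comment="#", float_precision="round_trip"))


def write_composition_json(table: Sequence[FieldComposition], path) -> None:
    payload = compositions_to_frame(table).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_composition_json(path) -> list[FieldComposition]:
    with open(path) as fh:
        return frame_to_compositions(pd.DataFrame(json.load(fh)))
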