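"""Coupling of mixed-field composition to DNA-damage curves.

The coupling scheme converts a per-species condensation of the
neutron-induced field (dose fractions w_s and dose-mean lineal energies
ȳ_D,s) plus per-species analytic damage curves Y_s(L) into neutron
damage per Gy per cell:

    Y_n(E) = Σ_s  w_s(E) · Y_s(ȳ_D,s(E))

The identification of ȳ_D with LET is exact: although the two
quantities differ in definition, dose averaging over the site evens out
the difference, so the species curve is simply evaluated at L = ȳ_D,s.
Two species lack their own curves: deuterons induce the same damage per
LET as protons, and electrons — whose lineal energy is low and nearly
constant — are evaluated on the proton curve at their ȳ_D, which falls
at (or below, and is then clamped to) the proton curve's low-LET end,
i.e. its highest-energy protons.

Uncertainties propagate to first order from the dose-fraction errors
only (σ²_Y = Σ_s Y_s² σ²_{w_s}); propagation of ȳ_D errors through the
curve slope can be enabled with ``propagate_yd_errors=True``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .damage_models import DamageCurve, eval_damage
from .errors import ConfigurationError, DataError, InvalidInputError
from .field_composition import FieldComposition, validate_composition

__all__ = [
    "NeutronDamagePoint",
    "couple",
    "neutron_damage_curve",
    "interior_maxima",
    "damage_curve_frame",
    "write_damage_curve_csv",
]

logger = logging.getLogger(__name__)

#: Species that have their own damage curves; the remaining two are
#: surrogated onto the proton curve.
CURVE_SPECIES = ("proton", "alpha", "C", "N", "O")
_SURROGATE = {"deuteron": "proton", "electron": "proton"}


@dataclass(frozen=True)
class NeutronDamagePoint:
    """Neutron-induced damage at one energy: total and per-species parts."""

    neutron_energy: float
    region: str
    endpoint: str
    yield_per_gy_per_cell: float
    yield_err: float
    per_species: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.per_species.values())
        if any(v < 0 for v in self.per_species.values()):
            raise InvalidInputError("per-species contributions must be non-negative")
        if abs(total - self.yield_per_gy_per_cell) > 1e-9 * max(1.0, abs(total)):
            raise InvalidInputError(
                "total yield does not decompose into per-species contributions"
            )


def _curve_for(
    curves: Mapping[str, DamageCurve], species: str, endpoint: str
) -> DamageCurve:
    lookup = _SURROGATE.get(species, species)
    curve = curves.get(lookup)
    if curve is None:
        raise ConfigurationError(
            f"no {endpoint} damage curve for species {lookup!r} "
            f"(needed for {species!r})"
        )
    if curve.endpoint != endpoint:
        raise ConfigurationError(
            f"curve for {lookup!r} scores {curve.endpoint!r}, expected {endpoint!r}"
        )
    return curve


def couple(
    comp: FieldComposition,
    curves: Mapping[str, DamageCurve],
    endpoint: str,
    *,
    propagate_yd_errors: bool = False,
) -> NeutronDamagePoint:
    """Neutron damage per Gy per cell at one energy and region.

    Each species' curve is evaluated at L = ȳ_D,s and weighted by the
    species' relative dose contribution; the weighted yields sum to the
    neutron yield.  Evaluations outside a curve's fitted LET span are
    clamped to the span endpoint (logged at debug level — routine for
    electrons, whose lineal energy sits below the proton data).
    """
    comp = validate_composition(comp)
    total = 0.0
    var = 0.0
    per_species: dict[str, float] = {}
    for rec in comp.records:
        if rec.dose_fraction == 0.0:
            continue
        curve = _curve_for(curves, rec.species, endpoint)
        if rec.y_D is None or rec.y_D <= 0:
            raise DataError(
                f"species {rec.species!r} has dose fraction {rec.dose_fraction:g} "
                "but no valid dose-mean lineal energy"
            )
        y_s, clamped = eval_damage(curve, rec.y_D, return_clamped=True)
        if clamped:
            logger.debug(
                "ȳ_D=%.3g keV/μm for %s clamped to %s curve range %s",
                rec.y_D, rec.species, curve.species, curve.let_range,
            )
        contribution = rec.dose_fraction * y_s
        per_species[rec.species] = contribution
        total += contribution
        var += (y_s * rec.dose_fraction_err) ** 2
        if propagate_yd_errors and rec.y_D_err > 0:
            h = 1e-4 * rec.y_D
            slope = (eval_damage(curve, rec.y_D + h) - eval_damage(curve, rec.y_D - h)) / (2 * h)
            var += (rec.dose_fraction * slope * rec.y_D_err) ** 2
    return NeutronDamagePoint(
        neutron_energy=comp.neutron_energy,
        region=comp.region,
        endpoint=endpoint,
        yield_per_gy_per_cell=total,
        yield_err=math.sqrt(var),
        per_species=per_species,
    )


def interior_maxima(energies: Sequence[float], values: Sequence[float]) -> list[float]:
    """Energies of strict interior maxima by three-point comparison."""
    e = np.asarray(energies, dtype=float)
    v = np.asarray(values, dtype=float)
    out = []
    for i in range(1, len(v) - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            out.append(float(e[i]))
    return out


def neutron_damage_curve(
    table: Sequence[FieldComposition],
    curves: Mapping[str, DamageCurve],
    endpoint: str,
    **kwargs,
) -> tuple[list[NeutronDamagePoint], list[float]]:
    """Couple a whole composition table over its neutron-energy grid.

    Returns the damage points ordered by energy together with the
    energies of interior local maxima of the yield curve (three-point
    comparison), the feature used to locate the regions of maximal
    effectiveness.
    """
    if len(table) < 2:
        raise InvalidInputError("need compositions at ≥ 2 energies")
    regions = {c.region for c in table}
    if len(regions) != 1:
        raise InvalidInputError(f"mixed regions in composition table: {sorted(regions)}")
    ordered = sorted(table, key=lambda c: c.neutron_energy)
    points = [couple(c, curves, endpoint, **kwargs) for c in ordered]
    maxima = interior_maxima(
        [p.neutron_energy for p in points],
        [p.yield_per_gy_per_cell for p in points],
    )
    return points, maxima


# ---------------------------------------------------------------------
# I/O — wide CSV plus per-species long-format companion
# ---------------------------------------------------------------------

def damage_curve_frame(points: Sequence[NeutronDamagePoint]) -> tuple[pd.DataFrame, pd.DataFrame]:
    wide = pd.DataFrame(
        {
            "E_n_MeV": [p.neutron_energy for p in points],
            "region": [p.region for p in points],
            "endpoint": [p.endpoint for p in points],
            "yield": [p.yield_per_gy_per_cell for p in points],
            "yield_err": [p.yield_err for p in points],
        }
    )
    long = pd.DataFrame(
        [
            {
                "E_n_MeV": p.neutron_energy,
                "region": p.region,
                "endpoint": p.endpoint,
                "species": sp,
                "weighted_yield": contrib,
            }
            for p in points
            for sp, contrib in sorted(p.per_species.items())
        ]
    )
    return wide, long


def write_damage_curve_csv(points: Sequence[NeutronDamagePoint], path, species_path=None) -> None:
    wide, long = damage_curve_frame(points)
    wide.to_csv(path, index=False)
    if species_path is not None:
        long.to_csv(species_path, index=False)
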