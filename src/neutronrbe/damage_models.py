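"""Analytic DNA-damage-vs-LET models and genomic damage-endpoint scoring.

Track-structure simulations of single-cell irradiation deliver damage
yields per Gy per cell as a function of particle LET, for two endpoint
definitions that probe damage complexity:

* ``short_fragments`` — DNA fragments shorter than 30 bp, produced when
  two double-strand breaks (DSBs) fall very close together;
* ``dsb_clusters`` — lesions containing at least two DSBs within a
  genomic distance shorter than 25 bp.

Light species (protons, α) follow a simple power law in LET,
``Y = a_p L^{n_p}``.  For heavier ions (C, N, O) the cluster yield
rises and then falls before the stopping-power maximum, which one extra
clustering parameter captures: ``Y = A_p L^{N_p} exp(−B_p L)``.  The
clustered form nests the power law at ``B_p = 0`` and has a single
interior maximum at ``L = N_p/B_p``.

Fitting is weighted least squares in log-yield space, where both forms
are linear in their parameters (log A, N, −B), so noiseless synthetic
data is recovered to machine precision and the optimiser has no
convergence pathology.

The endpoint scorers operate on genomic break patterns (chromosome,
0-based bp position).  Breaks are treated as points between base pairs,
fragment length is the coordinate difference, and both thresholds are
strict (`< 30 bp`, `< 25 bp`).  Cluster membership uses transitive
chain linkage by default (consecutive breaks closer than 25 bp belong
to one cluster); a pairwise variant, in which every pair in a cluster
must be closer than 25 bp, is available behind the same predicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FitError,
    InvalidInputError,
    InvalidParameterError,
    PatternValidationError,
)

__all__ = [
    "SHORT_FRAGMENT_BP",
    "CLUSTER_DISTANCE_BP",
    "DamageCurve",
    "DamagePoint",
    "eval_damage",
    "fit_damage_curve",
    "BreakPattern",
    "DamageScore",
    "score_breaks",
    "read_damage_points_csv",
    "write_damage_points_csv",
    "read_break_pattern_bed",
    "write_break_pattern_bed",
]

#: Endpoint thresholds (strict inequalities: "shorter than").
SHORT_FRAGMENT_BP = 30
CLUSTER_DISTANCE_BP = 25

ENDPOINTS = ("short_fragments", "dsb_clusters")
FORMS = ("power_law", "power_law_clustered")


# ---------------------------------------------------------------------
# Analytic damage curves
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class DamageCurve:
    """Damage yield per Gy per cell as an analytic function of LET.

    ``params`` is ``(a_p, n_p)`` for ``power_law`` and
    ``(A_p, N_p, B_p)`` for ``power_law_clustered``.  ``let_range`` is
    the LET span (keV/μm) of the fitted data; evaluation outside it is
    clamped to the nearer endpoint and flagged.
    """

    species: str
    endpoint: str
    form: str
    params: tuple[float, ...]
    let_range: tuple[float, float]
    covariance: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise InvalidInputError(f"unknown endpoint {self.endpoint!r}")
        if self.form not in FORMS:
            raise InvalidInputError(f"unknown curve form {self.form!r}")
        n_expected = 2 if self.form == "power_law" else 3
        if len(self.params) != n_expected:
            raise InvalidInputError(
                f"{self.form} needs {n_expected} parameters, got {len(self.params)}"
            )
        if self.params[0] <= 0:
            raise InvalidInputError("amplitude parameter must be positive")
        lo, hi = self.let_range
        if not (0 < lo < hi):
            raise InvalidInputError(f"invalid let_range {self.let_range}")

    @property
    def interior_maximum(self) -> float | None:
        """LET of the interior maximum N_p/B_p (clustered form, B_p > 0)."""
        if self.form == "power_law_clustered":
            A, N, B = self.params
            if N > 0 and B > 0:
                return N / B
        return None

    def __call__(self, let: float) -> float:
        return eval_damage(self, let)


def eval_damage(curve: DamageCurve, let: float, *, return_clamped: bool = False):
    """Evaluate a damage curve at LET ``let`` (keV/μm).

    Outside the fitted LET span the curve is evaluated at the nearer
    span endpoint (extrapolating a fitted power law beyond its data is
    not meaningful); with ``return_clamped=True`` a ``(yield, clamped)``
    pair is returned.
    """
    if let <= 0 or not math.isfinite(let):
        raise InvalidParameterError(f"LET must be positive, got {let}")
    lo, hi = curve.let_range
    L = min(max(let, lo), hi)
    clamped = L != let
    if curve.form == "power_law":
        a, n = curve.params
        y = a * L**n
    else:
        A, N, B = curve.params
        y = A * L**N * math.exp(-B * L)
    return (y, clamped) if return_clamped else y


@dataclass(frozen=True)
class DamagePoint:
    """One simulated damage datum: LET, yield per Gy per cell, uncertainty."""

    let: float
    yield_: float
    yield_err: float = 0.0


def _as_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pts = list(points)
    L = np.array([p.let for p in pts], dtype=float)
    Y = np.array([p.yield_ for p in pts], dtype=float)
    E = np.array([p.yield_err for p in pts], dtype=float)
    return L, Y, E


def fit_damage_curve(
    points: Iterable[DamagePoint],
    form: str,
    species: str,
    endpoint: str,
) -> DamageCurve:
    """Weighted least-squares fit of a damage curve in log-yield space.

    Both analytic forms are linear in (log amplitude, LET exponent,
    clustering slope) once the yield is logged, so the fit is a single
    weighted linear solve; weights are ``(Y/σ_Y)²`` (the first-order
    variance of log Y), or uniform when no uncertainties are given.
    Returns the curve with its parameter covariance and the data's LET
    span as ``let_range``.
    """
    if form not in FORMS:
        raise FitError(f"unknown curve form {form!r}")
    L, Y, E = _as_points(points)
    n_par = 2 if form == "power_law" else 3
    min_pts = n_par + 1
    if L.size < min_pts:
        raise FitError(f"{form} fit needs at least {min_pts} points, got {L.size}")
    if np.any(L <= 0) or np.any(Y <= 0):
        raise FitError("all LET and yield values must be positive")

    logL, logY = np.log(L), np.log(Y)
    with np.errstate(divide="ignore"):
        sigma = np.where(E > 0, E / Y, np.nan)
    if np.all(np.isnan(sigma)):
        sigma = np.ones_like(logY)
    elif np.any(np.isnan(sigma)):
        raise FitError("yield uncertainties must be all zero or all positive")

    X = np.column_stack([np.ones_like(logL), logL] + ([-L] if n_par == 3 else []))
    W = 1.0 / sigma
    coef, *_ = np.linalg.lstsq(X * W[:, None], logY * W, rcond=None)
    resid = logY - X @ coef
    xtx = (X * W[:, None]).T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
        raise FitError(f"singular design matrix in {form} fit: {exc}") from exc
    dof = max(L.size - n_par, 1)
    if not np.all(E > 0):
        cov = cov * float(resid @ (W**2 * resid)) / dof

    if form == "power_law":
        params = (math.exp(coef[0]), float(coef[1]))
    else:
        params = (math.exp(coef[0]), float(coef[1]), float(coef[2]))
    if not all(map(math.isfinite, params)):
        raise FitError(f"{form} fit did not converge: parameters {params}")
    return DamageCurve(
        species=species,
        endpoint=endpoint,
        form=form,
        params=params,
        let_range=(float(L.min()), float(L.max())),
        covariance=cov,
    )


# ---------------------------------------------------------------------
# Genomic break patterns and endpoint scoring
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class BreakPattern:
    """DSB positions (0-based bp) against a chromosome-sizes table.

    ``chrom_sizes`` maps chromosome name to length in bp;
    ``dsb_positions`` maps chromosome name to a sorted integer array of
    break coordinates.  Breaks are points between base pairs, so the
    fragment between consecutive breaks has length equal to their
    coordinate difference.
    """

    chrom_sizes: dict[str, int]
    dsb_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        positions = {}
        for chrom, pos in self.dsb_positions.items():
            if chrom not in self.chrom_sizes:
                raise PatternValidationError(f"chromosome {chrom!r} not in sizes table")
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise PatternValidationError("positions must be 1-D")
            if arr.size and (arr.min() < 0 or arr.max() >= self.chrom_sizes[chrom]):
                raise PatternValidationError(
                    f"positions on {chrom} outside [0, {self.chrom_sizes[chrom]})"
                )
            if np.any(np.diff(arr) < 0):
                raise PatternValidationError(f"positions on {chrom} are not sorted")
            positions[chrom] = arr
        object.__setattr__(self, "dsb_positions", positions)

    @property
    def n_dsb(self) -> int:
        return int(sum(p.size for p in self.dsb_positions.values()))


@dataclass(frozen=True)
class DamageScore:
    """Endpoint counts for one break pattern.

    ``multiplicities`` holds the DSB count of each cluster (each ≥ 2);
    the total DSB count decomposes exactly into clustered plus isolated
    breaks.
    """

    n_short_fragments: int
    n_clusters: int
    multiplicities: tuple[int, ...]
    n_isolated_dsb: int

    def __post_init__(self) -> None:
        if any(m < 2 for m in self.multiplicities):
            raise InvalidInputError("cluster multiplicities must be ≥ 2")
        if len(self.multiplicities) != self.n_clusters:
            raise InvalidInputError("n_clusters inconsistent with multiplicities")

    @property
    def n_dsb(self) -> int:
        return sum(self.multiplicities) + self.n_isolated_dsb


def _chain_clusters(gaps: np.ndarray, max_gap: int) -> list[int]:
    """Multiplicities of maximal runs of consecutive gaps < max_gap."""
    sizes, run = [], 1
    for g in gaps:
        if g < max_gap:
            run += 1
        else:
            if run >= 2:
                sizes.append(run)
            run = 1
    if run >= 2:
        sizes.append(run)
    return sizes


def _pairwise_clusters(pos: np.ndarray, max_span: int) -> list[int]:
    """Greedy left-to-right grouping requiring every pair within max_span."""
    sizes = []
    i, n = 0, pos.size
    while i < n:
        j = i
        while j + 1 < n and pos[j + 1] - pos[i] < max_span:
            j += 1
        if j > i:
            sizes.append(j - i + 1)
        i = j + 1
    return sizes


def score_breaks(
    pattern: BreakPattern,
    *,
    cluster_distance_bp: int = CLUSTER_DISTANCE_BP,
    short_fragment_bp: int = SHORT_FRAGMENT_BP,
    linkage: Literal["chain", "pairwise"] = "chain",
) -> DamageScore:
    """Score the two damage endpoints on a genomic break pattern.

    Per chromosome, consecutive DSBs separated by strictly less than
    ``cluster_distance_bp`` are linked; maximal linked runs with ≥ 2
    members are clusters (``linkage="chain"``, the default transitive
    rule) or, with ``linkage="pairwise"``, groups additionally require
    every member pair within the distance.  Short fragments are
    inter-DSB intervals strictly shorter than ``short_fragment_bp``,
    counted genome-wide.
    """
    if linkage not in ("chain", "pairwise"):
        raise InvalidInputError(f"unknown linkage {linkage!r}")
    n_short = 0
    multiplicities: list[int] = []
    for chrom in sorted(pattern.dsb_positions):
        pos = pattern.dsb_positions[chrom]
        if pos.size < 2:
            continue
        gaps = np.diff(pos)
        n_short += int(np.count_nonzero(gaps < short_fragment_bp))
        if linkage == "chain":
            multiplicities.extend(_chain_clusters(gaps, cluster_distance_bp))
        else:
            multiplicities.extend(_pairwise_clusters(pos, cluster_distance_bp))
    n_clustered = sum(multiplicities)
    return DamageScore(
        n_short_fragments=n_short,
        n_clusters=len(multiplicities),
        multiplicities=tuple(multiplicities),
        n_isolated_dsb=pattern.n_dsb - n_clustered,
    )


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def read_damage_points_csv(path) -> list[DamagePoint]:
    """CSV columns: LET_keV_um, yield_per_Gy_per_cell, yield_err."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"LET_keV_um", "yield_per_Gy_per_cell", "yield_err"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"damage CSV missing columns: {sorted(missing)}")
    return [
        DamagePoint(float(r.LET_keV_um), float(r.yield_per_Gy_per_cell), float(r.yield_err))
        for r in df.itertuples()
    ]


def write_damage_points_csv(points: Sequence[DamagePoint], path) -> None:
    pd.DataFrame(
        {
            "LET_keV_um": [p.let for p in points],
            "yield_per_Gy_per_cell": [p.yield_ for p in points],
            "yield_err": [p.yield_err for p in points],
        }
    ).to_csv(path, index=False)


def write_break_pattern_bed(pattern: BreakPattern, bed_path, sizes_path) -> None:
    """BED3 (end = start + 1) plus a two-column chrom.sizes file."""
    with open(bed_path, "w") as fh:
        for chrom in sorted(pattern.dsb_positions):
            for p in pattern.dsb_positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")
    with open(sizes_path, "w") as fh:
        for chrom, size in sorted(pattern.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")


def read_break_pattern_bed(bed_path, sizes_path) -> BreakPattern:
    sizes: dict[str, int] = {}
    with open(sizes_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    positions: dict[str, list[int]] = {c: [] for c in sizes}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            if int(end) != int(start) + 1:
                raise PatternValidationError(
                    f"break records must have end = start + 1, got {line.strip()!r}"
                )
            if chrom not in positions:
                raise PatternValidationError(f"chromosome {chrom!r} not in sizes table")
            positions[chrom].append(int(start))
    return BreakPattern(
        chrom_sizes=sizes,
        dsb_positions={c: np.sort(np.array(p, dtype=np.int64)) for c, p in positions.items()},
    )
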