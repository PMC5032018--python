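# Methods

This note records the models implemented in `neutronrbe`, the
assumptions behind them, the calibration constants of the synthetic
generators, and what the test suite does and does not establish.

## Microdosimetric quantities

A radiation field at the micrometre scale is described by the frequency
density f(y) of the lineal energy y (keV/μm, energy imparted per mean
chord length of a site; site diameter 1 μm by default, carried as
metadata only — no chord-length resampling is performed). The dose
density is d(y) = y f(y)/ȳ_F with ȳ_F = ∫ y f dy. Moments:

* dose-mean lineal energy ȳ_D = ∫ y² f dy / ∫ y f dy (first moment of
  d(y)), the field's clustering indicator;
* saturation-corrected dose-mean lineal energy
  y\*(y₀) = y₀² ∫ (1 − exp(−y²/y₀²)) f dy / ∫ y f dy.

The exponential saturation kernel is the standard (ICRU Report 36 /
Kellerer) form; y₀ is conventionally 100–200 keV/μm and the package
treats {100, 150, 200} as the canonical configuration set. y\* is
provably non-decreasing in y₀, bounded by ȳ_D, and converges to ȳ_D as
y₀ → ∞ — these are enforced as property tests.

Spectra are stored either on log grids (trapezoidal quadrature; 256
points over 10⁻²–10³ keV/μm by default) or as discrete line spectra
with exact sums. Constructors renormalise densities whose integral is
within 1% of unity and reject larger deviations (almost always a unit
mistake); `from_unnormalized` is the explicit entry point for raw
tallies. Mixing acts in d-space — d_mix = Σ w_s d_s — so the identity
ȳ_D,mix = Σ w_s ȳ_D,s holds exactly (to float round-off) on a shared
grid; spectra on different grids are first resampled to a common log
grid (1024 points).

## The mixed-field condensation

The whole transport output at one neutron energy and scoring depth is
condensed to two numbers per secondary species s: its relative dose
contribution w_s and its ȳ_D,s. Species form a closed set
{electron, proton, deuteron, α, C, N, O}; tissue recoils with Z > 8 are
excluded and may appear only as a logged residual ≤ 0.05 of the dose.
Validation renormalises fraction sums within [0.95, 1.05] and rejects
anything worse. Interpolation across neutron energy is linear in
log₁₀E for dose fractions (then renormalised) and log-log for ȳ_D;
a species absent at the lower bracketing node keeps fraction 0 at and
below that node, so no reaction channel is extrapolated across its
threshold.

Physics helpers:

* maximal elastic energy transfer E_max = 4 m_n m_t/(m_n+m_t)² · E_n
  (m_n = 1.008665 u) — equal to E_n only for hydrogen, which is why
  recoil protons dominate the elastic regime;
* Q-values of H(n,γ)d (2.2246 MeV → the 2.2 MeV capture photon) and
  ¹⁴N(n,p)¹⁴C (0.626 MeV) from embedded AME-style atomic masses
  (rounded to 10⁻⁸ u, ≈10 eV, far below the keV level quoted);
* the dose–fluence–LET relation D[Gy] = 0.1602·L[keV/μm]·Φ[μm⁻²]/ρ,
  inverted for crossing particles, and the track-average estimator
  L = E₀/range for particles stopping inside the nucleus.

## Damage models and endpoint scoring

Damage yields per Gy per cell versus LET follow a power law
Y = a_p L^(n_p) for light species. For heavy ions the DSB-cluster
yield turns over before the stopping maximum; the implemented form
Y = A_p L^(N_p) e^(−B_p L) was chosen because it nests the power law at
B_p = 0, adds exactly one clustering parameter, and has a single
interior maximum at L = N_p/B_p, reproducing the observed rise and
fall. Fits run as weighted least squares in log-yield space, where
both forms are linear in (log A, N, −B): a single linear solve, exact
on noiseless data, with covariance from the normal equations (scaled by
the residual variance when no point uncertainties are given). Fitted
curves carry the data's LET span; evaluation outside the span clamps to
the nearer endpoint and flags the event — extrapolating a fitted power
law beyond its data is deliberately not supported.

Genomic endpoints operate on break patterns (chromosome, 0-based bp
position; breaks are points between base pairs, fragment length =
coordinate difference). Both thresholds are strict: fragments shorter
than 30 bp, cluster linkage distance shorter than 25 bp. Cluster
membership uses transitive chain linkage by default (consecutive
breaks < 25 bp apart join one cluster); whether the original scoring is
pairwise or transitive is not specified in the sources, so a pairwise
variant (every pair within the window, greedy left-to-right) sits
behind the same predicate. Scoring is validated against an O(n²)
union-find oracle on hundreds of random patterns and is invariant under
chromosome relabeling and uniform translation.

## Coupling and RBE

Coupling identifies ȳ_D,s with the LET argument of the damage curve —
exactly, with no smearing: the two quantities differ in definition but
dose-averaging over the site evens out the difference. Then
Y_n(E) = Σ_s w_s·Y_s(ȳ_D,s). Deuterons use the proton curve at their
own lineal energy; electrons use the proton curve at their low,
near-constant ȳ_D, which falls at (or below, then clamped to) the
curve's low-LET end — the highest-energy-proton end. Uncertainty
propagates to first order from dose-fraction errors only
(σ² = Σ Y_s² σ_w²); propagation of ȳ_D errors through the curve slope
is available behind a flag but off by default. The coupled curve over
an energy grid reports interior maxima by three-point comparison.

RBE models: (i) y\*-ratio at matched y₀; (ii) DSB-cluster yield ratio,
valid under linearity of the endpoint with dose (two tracks essentially
never cooperate within 25 bp, so cluster counts scale with track number
and hence dose). Reference-field scalars are configuration inputs; the
default fixture is a synthetic low-LET electron-like field (lognormal,
ȳ_D = 2.2 keV/μm) whose cluster yield comes from the proton curve's
low-LET end. Absolute RBE levels therefore track this uncalibrated
reference; only shapes, orderings and peak positions are asserted.
ICRP 103's continuous w_R (three log-Gaussian branches; the printed
coefficients agree only to ≈0.01 at the 1 and 50 MeV boundaries, and
the transcription preserves that) and the U.S. NRC 10 CFR 20 quality
factor table (log-linear interpolation) are embedded strictly for
qualitative comparison.

## Synthetic generators

The generators emulate the statistical and mechanistic structure of
transport and track-structure outputs; they are not transport codes,
and every calibrated constant lives in `FieldGeneratorConfig`.

**Stopping powers.** An embedded coarse proton electronic-stopping
table for unit-density tissue (32 nodes, 10⁻³–10³ MeV/u, maximum
≈81 keV/μm near 0.08 MeV/u) is interpolated log-log and scaled to other
ions by the squared Barkas effective-charge ratio at equal velocity,
z_eff = z(1 − e^(−125β/z^(2/3))). The table is an approximate
parameterisation of the canonical shape — only the *placement* of
dose-mean lineal energies depends on it, not any dosimetry — and it
carries ranges, slowing-down mean LET (∫S dE′/E) and the dose-weighted
recoil-spectrum average used below.

**Field generator.** At each node of the default 49-point log grid
(10⁻⁵–10³ MeV; six nodes per decade, so 1 MeV is a node) unnormalised
channel strengths are computed and normalised into dose fractions:

* capture regime: electron-dominated plateau (w_e ≈ 0.91) with a
  constant proton share from ¹⁴N(n,p)¹⁴C and a small capture-deuteron
  share; compositions are frozen below 10⁻⁴ MeV, encoding the 1/v
  constancy of the no-threshold capture cross sections toward thermal
  energies;
* a logistic handover (width 0.55 decades) to proton-recoil dominance
  at a per-region crossover energy (outer 0.05, intermediate 0.15,
  inner 0.18 MeV — deeper regions see partially moderated flux and
  cross over later);
* threshold-gated channels, exactly zero at and below threshold
  (N 1 MeV, O 5 MeV, C 10 MeV; α at the lowest threshold), ramping in
  over per-channel widths (α/N 1.0, O 0.64, C 0.35 decades) and diluted
  at very high energy by a 1/(1+E/120 MeV) softening that stands for
  the growing share of excluded products.

Species lineal energies: electrons constant at 2.2 keV/μm; protons
follow the dose-weighted uniform-recoil average of the stopping table,
held flat below a per-region knee (outer 1.0, intermediate 1.5, inner
2.0 MeV — slow recoils near the stopping maximum dominate up to higher
nominal energy at depth) and declining above it; α particles are
emitted at E_α = 1.2 + 0.25(E_n − 1) MeV and so appear just past their
stopping maximum with ȳ_D declining from threshold; C/N/O use the
elastic recoil-spectrum average, rising steeply above threshold toward
600–1000 keV/μm.

The crossover energies, channel amplitudes, ramp widths, knees and the
softening scale are calibration constants, chosen once so that the
default pipeline exhibits the qualitative regime structure the physics
dictates — a single low-energy effectiveness maximum exactly at the
1 MeV grid node (outer region), a second maximum at the 21.54 MeV node
(the grid node nearest 20 MeV), reduced prominence of the second peak
for the cluster endpoint relative to raw fragments, and low-energy
peaks shifted to higher energy with depth. They are calibration, not
derivation.

**Damage datasets** draw yields log-normally (mean-preserving, CV
`noise_cv`, default 0.10) around analytic ground-truth curves and
return the truth alongside the points for recovery tests. Default
truths: protons (0.015, 1.40) and α (0.010, 1.35) power laws for
clusters; heavy-ion cluster curves with turnover at 3/4 of each
species' LET span and peak yield 24 /Gy/cell; steeper pure power laws
for the fragment endpoint. LET spans correspond to initial energies of
0.0625–64 MeV/u per species.

**Break patterns** place Poisson-multiplicity tracks on a synthetic
three-chromosome genome (240 Mbp total — not a real assembly): a track
is clustered with probability `cluster_fraction` (its breaks land in
one burst of width `cluster_span_bp`, emulating a densely ionising
track core) and scattered uniformly (length-weighted) otherwise.
Accidental clusters among isolated breaks follow the analytic
birthday-collision rate, which the suite checks over 200 replicates.

All generators are pure functions of (parameters, seed); the default
fixture seed is 34033.

## Numerical choices

* Trapezoidal quadrature everywhere on log grids; lognormal species
  spectra are evaluated over ±7 log-sd with 512 points, giving
  moment-matching to ≈10⁻⁴ relative.
* `expm1` is used in the saturation kernel to avoid cancellation at
  y ≪ y₀.
* CSV exchange uses shortest-round-trip float formatting and
  `float_precision="round_trip"` parsing, so composition tables survive
  a write/read cycle bit-exactly.
* Degenerate inputs fail loudly: zero-frequency spectra, non-positive
  LET, unsorted or out-of-bounds break positions, fraction sums outside
  [0.95, 1.05], unknown reactions or regions.
* Interior maxima use strict three-point comparison; plateaus do not
  count as peaks.

## What the tests show — and do not

The suite establishes the identities and oracle equivalences above and
that the default synthetic pipeline reproduces the expected emergent
structure robustly across noise seeds. Because the field generator is
a calibrated emulator, passing tests demonstrate the correctness of the
analysis pipeline (moments, fits, scoring, coupling, ratios) — not
agreement of absolute dose fractions, damage yields or RBE levels with
transport/track-structure calculations or with experiment. Real
transport outputs can be substituted at any stage through the CSV/BED
interfaces. Known limitations: no chord-length or site-size
conversions; no transport or radiation chemistry; the Bragg-edge
ambiguity (two energies, one LET) is knowingly ignored by the analytic
damage curves; heavy-fragment yields above Z=8 and π/EM cascades at the
highest energies are out of scope.
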