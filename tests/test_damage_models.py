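"""Damage-vs-LET curves, fitting, and genomic endpoint scoring."""

import math

import numpy as np
import pytest

import neutronrbe as nr
from neutronrbe.damage_models import (
    CLUSTER_DISTANCE_BP,
    SHORT_FRAGMENT_BP,
    DamagePoint,
    _pairwise_clusters,
)
from neutronrbe.errors import FitError, InvalidParameterError, PatternValidationError


def curve(form, params, species="proton", endpoint="dsb_clusters",
          let_range=(0.5, 1000.0)):
    return nr.DamageCurve(species=species, endpoint=endpoint, form=form,
                          params=params, let_range=let_range)


class TestEvaluation:
    def test_identity_power_law(self):
        assert curve("power_law", (1.0, 1.0))(10.0) == pytest.approx(10.0)

    def test_clustered_reduces_to_power_law_at_b_zero(self):
        pl = curve("power_law", (0.7, 1.3))
        cl = curve("power_law_clustered", (0.7, 1.3, 0.0))
        for L in (1.0, 10.0, 300.0):
            assert cl(L) == pytest.approx(pl(L), rel=1e-12)

    def test_clustered_closed_form(self):
        c = curve("power_law_clustered", (2.0, 1.5, 0.01))
        assert c(100.0) == pytest.approx(2.0 * 1000.0 * math.exp(-1.0), rel=1e-12)

    def test_interior_maximum_at_n_over_b(self):
        c = curve("power_law_clustered", (1.0, 1.5, 0.005))
        L_max = c.interior_maximum
        assert L_max == pytest.approx(300.0)
        eps = 1e-3
        assert c(L_max) > c(L_max * (1 + eps)) and c(L_max) > c(L_max * (1 - eps))

    def test_clamping_outside_fitted_range(self):
        c = curve("power_law", (1.0, 1.0), let_range=(10.0, 100.0))
        y, clamped = nr.eval_damage(c, 5.0, return_clamped=True)
        assert clamped and y == pytest.approx(c(10.0))
        y, clamped = nr.eval_damage(c, 500.0, return_clamped=True)
        assert clamped and y == pytest.approx(c(100.0))

    def test_nonpositive_let_rejected(self):
        with pytest.raises(InvalidParameterError):
            curve("power_law", (1.0, 1.0))(0.0)


class TestFitting:
    def test_noiseless_power_law_recovery(self):
        truth = (0.5, 1.2)
        L = np.geomspace(1, 100, 8)
        pts = [DamagePoint(l, truth[0] * l ** truth[1]) for l in L]
        fit = nr.fit_damage_curve(pts, "power_law", "proton", "dsb_clusters")
        assert fit.params[0] == pytest.approx(truth[0], rel=1e-6)
        assert fit.params[1] == pytest.approx(truth[1], rel=1e-6)
        assert fit.let_range == (1.0, 100.0)

    def test_noiseless_clustered_recovery(self):
        A, N, B = 1.0, 1.3, 0.008
        L = np.geomspace(20, 900, 9)
        pts = [DamagePoint(l, A * l**N * math.exp(-B * l)) for l in L]
        fit = nr.fit_damage_curve(pts, "power_law_clustered", "C", "dsb_clusters")
        assert fit.params[0] == pytest.approx(A, rel=1e-4)
        assert fit.params[1] == pytest.approx(N, rel=1e-4)
        assert fit.params[2] == pytest.approx(B, rel=1e-4)

    def test_noiseless_residuals_at_machine_precision(self):
        ds = nr.generate_damage_dataset("C", "dsb_clusters", noise_cv=0.0)
        fit = nr.fit_damage_curve(ds.points, "power_law_clustered", "C", "dsb_clusters")
        for p in ds.points:
            assert fit(p.let) == pytest.approx(p.yield_, rel=1e-8)

    def test_noisy_recovery_within_3_se(self):
        # 200 seeded replicates, 12 points, 10% multiplicative noise:
        # the exponent must fall within 3 estimated standard errors of
        # truth in at least 95% of replicates.
        truth = (0.05, 1.45)
        L = np.geomspace(2, 150, 12)
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            sigma = math.sqrt(math.log1p(0.1**2))
            Y = truth[0] * L ** truth[1] * np.exp(
                rng.normal(-0.5 * sigma**2, sigma, L.size)
            )
            pts = [DamagePoint(l, y, 0.1 * y) for l, y in zip(L, Y)]
            fit = nr.fit_damage_curve(pts, "power_law", "proton", "dsb_clusters")
            se = math.sqrt(fit.covariance[1, 1])
            if abs(fit.params[1] - truth[1]) <= 3 * se:
                hits += 1
        assert hits >= 190

    def test_insufficient_points(self):
        pts = [DamagePoint(1.0, 1.0), DamagePoint(2.0, 2.0)]
        with pytest.raises(FitError):
            nr.fit_damage_curve(pts, "power_law", "proton", "dsb_clusters")

    def test_default_heavy_curves_peak_inside_span(self, cluster_curves):
        for sp in ("C", "N", "O"):
            c = cluster_curves[sp]
            lo, hi = c.let_range
            assert lo < c.interior_maximum < hi


def brute_force_score(pattern):
    """O(n²) oracle: union-find over all pairs closer than 25 bp."""
    n_short = 0
    mult = []
    for chrom, pos in pattern.dsb_positions.items():
        pos = list(map(int, pos))
        n = len(pos)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if abs(pos[i] - pos[j]) < CLUSTER_DISTANCE_BP:
                    parent[find(i)] = find(j)
        sizes = {}
        for i in range(n):
            sizes[find(i)] = sizes.get(find(i), 0) + 1
        mult.extend(s for s in sizes.values() if s >= 2)
        sorted_pos = sorted(pos)
        n_short += sum(
            1 for a, b in zip(sorted_pos, sorted_pos[1:]) if b - a < SHORT_FRAGMENT_BP
        )
    return n_short, sorted(mult)


class TestScoring:
    def test_worked_example(self):
        p = nr.BreakPattern({"chr1": 10_000}, {"chr1": np.array([1000, 1010, 5000])})
        score = nr.score_breaks(p)
        assert score.n_clusters == 1
        assert score.multiplicities == (2,)
        assert score.n_isolated_dsb == 1
        assert score.n_short_fragments == 1  # the 10 bp gap
        assert score.n_dsb == 3

    def test_empty_pattern(self):
        p = nr.BreakPattern({"chr1": 1000}, {})
        s = nr.score_breaks(p)
        assert (s.n_clusters, s.n_short_fragments, s.n_isolated_dsb) == (0, 0, 0)

    def test_strict_thresholds(self):
        # gaps: 24 (cluster + fragment), 76 (neither), 29 (fragment only),
        # and a gap of exactly 25 must NOT cluster ("shorter than" is strict)
        p = nr.BreakPattern(
            {"chr1": 10_000}, {"chr1": np.array([100, 124, 200, 229])}
        )
        s = nr.score_breaks(p)
        assert s.n_clusters == 1 and s.multiplicities == (2,)
        assert s.n_short_fragments == 2
        assert s.n_isolated_dsb == 2
        boundary = nr.BreakPattern({"chr1": 1000}, {"chr1": np.array([0, 25])})
        assert nr.score_breaks(boundary).n_clusters == 0
        assert nr.score_breaks(boundary).n_short_fragments == 1

    def test_500_random_patterns_match_brute_force(self, rng):
        for _ in range(500):
            n = int(rng.integers(0, 40))
            pos = np.sort(rng.integers(0, 2000, size=n))
            p = nr.BreakPattern({"c": 2000}, {"c": pos})
            s = nr.score_breaks(p)
            n_short, mult = brute_force_score(p)
            assert s.n_short_fragments == n_short
            assert sorted(s.multiplicities) == mult
            assert s.n_dsb == n

    def test_relabeling_and_translation_invariance(self, rng):
        pos = np.sort(rng.integers(100, 5000, size=25))
        a = nr.score_breaks(nr.BreakPattern({"chrA": 10_000}, {"chrA": pos}))
        b = nr.score_breaks(nr.BreakPattern({"zzz": 10_000}, {"zzz": pos}))
        c = nr.score_breaks(nr.BreakPattern({"chrA": 10_000}, {"chrA": pos + 500}))
        assert a == b == c

    def test_pairwise_linkage_tighter_than_chain(self):
        # 0,20,40: chain links all three; pairwise splits (0-40 = 40 ≥ 25)
        pos = np.array([0, 20, 40])
        p = nr.BreakPattern({"c": 1000}, {"c": pos})
        chain = nr.score_breaks(p, linkage="chain")
        pair = nr.score_breaks(p, linkage="pairwise")
        assert chain.multiplicities == (3,)
        assert pair.multiplicities == (2,)
        assert _pairwise_clusters(pos, 25) == [2]

    def test_validation_errors(self):
        with pytest.raises(PatternValidationError):
            nr.BreakPattern({"c": 100}, {"c": np.array([150])})
        with pytest.raises(PatternValidationError):
            nr.BreakPattern({"c": 100}, {"c": np.array([50, 10])})
        with pytest.raises(PatternValidationError):
            nr.BreakPattern({"c": 100}, {"other": np.array([5])})

    def test_bed_round_trip(self, tmp_path):
        p = nr.generate_break_pattern(n_tracks=40, seed=3)
        bed, sizes = tmp_path / "b.bed", tmp_path / "c.sizes"
        nr.write_break_pattern_bed(p, bed, sizes)
        back = nr.read_break_pattern_bed(bed, sizes)
        assert back.chrom_sizes == p.chrom_sizes
        for chrom in p.dsb_positions:
            assert np.array_equal(back.dsb_positions[chrom], p.dsb_positions[chrom])
        assert nr.score_breaks(back) == nr.score_breaks(p)
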