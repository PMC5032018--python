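"""Synthetic field, spectrum, damage and break-pattern generators."""

import math

import numpy as np
import pytest

import neutronrbe as nr
from neutronrbe.errors import ConfigurationError, InvalidParameterError
from neutronrbe.synthetic_data import DEFAULT_LET_POINTS


class TestStoppingPowers:
    @pytest.mark.parametrize("species", ["proton", "alpha", "C", "N", "O"])
    def test_positive_with_single_bragg_maximum(self, species):
        tbl = nr.StoppingPowerTable.for_species(species)
        s = tbl.stopping
        assert np.all(s > 0)
        # single interior maximum: the sign of the derivative changes once
        sign_changes = np.count_nonzero(np.diff(np.sign(np.diff(s))) != 0)
        assert sign_changes == 1

    def test_range_monotone_in_energy(self):
        tbl = nr.StoppingPowerTable.for_species("proton")
        E = np.array([0.1, 1.0, 10.0, 100.0])
        R = tbl.range_um(E)
        assert np.all(np.diff(R) > 0)
        # ~1 MeV proton range in tissue is a few tens of μm
        assert 10 < tbl.range_um(1.0) < 60

    def test_heavier_ions_stop_harder(self):
        eps = 1.0  # MeV/u
        lets = [
            float(nr.StoppingPowerTable.for_species(sp).stopping_at(eps * a))
            for sp, a in (("proton", 1), ("alpha", 4), ("C", 12), ("O", 16))
        ]
        assert lets == sorted(lets)

    def test_recoil_average_below_track_maximum(self):
        tbl = nr.StoppingPowerTable.for_species("proton")
        assert tbl.recoil_dose_mean_let(1.0) < tbl.stopping.max()
        assert tbl.recoil_dose_mean_let(1.0) > tbl.mean_let(1e3)


class TestFieldGenerator:
    def test_thermal_limit_constancy(self):
        cfg = nr.FieldGeneratorConfig()
        table = nr.generate_composition_table(cfg)
        lo = next(c for c in table if c.neutron_energy == pytest.approx(1e-5))
        hi = next(c for c in table if c.neutron_energy == pytest.approx(1e-4))
        for sp in ("electron", "proton", "deuteron"):
            assert lo.fraction(sp) == pytest.approx(hi.fraction(sp), rel=1e-3)
            assert lo.record(sp).y_D == pytest.approx(hi.record(sp).y_D, rel=1e-6)

    def test_capture_regime_is_electron_dominated(self, outer_table):
        c = outer_table[0]
        assert c.fraction("electron") > 0.8
        assert c.fraction("alpha") == 0.0

    def test_elastic_regime_proton_dominates(self, outer_table):
        c = next(x for x in outer_table if 0.4 < x.neutron_energy < 0.6)
        assert c.fraction("proton") > c.fraction("electron")

    def test_alpha_gated_at_minimum_threshold(self, outer_table):
        thr = 1.0
        for c in outer_table:
            if c.neutron_energy <= thr:
                assert c.fraction("alpha") == 0.0
            if c.neutron_energy > 2 * thr:
                assert c.fraction("alpha") > 0.0

    def test_every_node_validates(self, outer_table):
        for c in outer_table:
            v = nr.validate_composition(c)
            assert v.fraction_sum == pytest.approx(1.0, abs=1e-9)

    def test_proton_yd_flat_then_decreasing(self, outer_table):
        E = np.array([c.neutron_energy for c in outer_table])
        yd = np.array([c.record("proton").y_D for c in outer_table])
        low = yd[E <= 1.0]
        assert np.ptp(low) / low.mean() < 1e-6  # flat below the knee
        above = yd[(E >= 1.0) & (E <= 100.0)]
        assert np.all(np.diff(above) < 0)

    def test_electron_yd_constant_and_low(self, outer_table):
        yd = {c.record("electron").y_D for c in outer_table}
        assert len(yd) == 1 and yd.pop() < 10.0

    def test_alpha_yd_decreasing_from_threshold(self, outer_table):
        vals = [
            c.record("alpha").y_D
            for c in outer_table
            if c.fraction("alpha") > 0 and c.neutron_energy < 500
        ]
        assert np.all(np.diff(vals) < 0)

    def test_determinism(self):
        a = nr.generate_composition_table(nr.FieldGeneratorConfig())
        b = nr.generate_composition_table(nr.FieldGeneratorConfig())
        for ca, cb in zip(a, b):
            assert ca == cb

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            nr.FieldGeneratorConfig(energy_grid=np.array([1.0, 0.5]))
        with pytest.raises(ConfigurationError):
            nr.FieldGeneratorConfig(region="surface")


class TestSpeciesSpectrum:
    def test_moment_matched_dose_mean(self):
        s = nr.generate_species_spectrum("proton", 100.0, gsd=1.5)
        assert nr.dose_mean(s) == pytest.approx(100.0, abs=0.1)

    def test_narrow_limit_approaches_line(self):
        s = nr.generate_species_spectrum("proton", 40.0, gsd=1.01)
        assert nr.dose_mean(s) == pytest.approx(40.0, rel=1e-3)
        assert nr.frequency_mean(s) == pytest.approx(40.0, rel=2e-3)

    def test_deterministic_regardless_of_seed(self):
        a = nr.generate_species_spectrum("C", 300.0, seed=1)
        b = nr.generate_species_spectrum("C", 300.0, seed=999)
        assert np.array_equal(a.f_density, b.f_density)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            nr.generate_species_spectrum("proton", -5.0)
        with pytest.raises(InvalidParameterError):
            nr.generate_species_spectrum("proton", 10.0, gsd=0.9)


class TestDamageDatasets:
    def test_zero_noise_points_on_curve(self):
        ds = nr.generate_damage_dataset("proton", "dsb_clusters", noise_cv=0.0)
        for p in ds.points:
            assert p.yield_ == pytest.approx(ds.true_curve(p.let), rel=1e-12)

    def test_fit_on_noiseless_data_recovers_truth(self):
        ds = nr.generate_damage_dataset("O", "dsb_clusters", noise_cv=0.0)
        fit = nr.fit_damage_curve(ds.points, ds.true_curve.form, "O", "dsb_clusters")
        for got, want in zip(fit.params, ds.true_curve.params):
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_same_seed_same_dataset(self):
        a = nr.generate_damage_dataset("proton", "dsb_clusters", seed=11)
        b = nr.generate_damage_dataset("proton", "dsb_clusters", seed=11)
        assert a.points == b.points

    def test_let_points_positive_required(self):
        with pytest.raises(InvalidParameterError):
            nr.generate_damage_dataset(
                "proton", "dsb_clusters", let_points=[-1.0, 2.0, 3.0, 4.0]
            )

    def test_default_spans_match_curve_ranges(self, cluster_curves):
        for sp, c in cluster_curves.items():
            L = DEFAULT_LET_POINTS[sp]
            assert c.let_range == (float(L.min()), float(L.max()))


class TestBreakGenerator:
    def test_no_tracks_empty_pattern(self):
        p = nr.generate_break_pattern(n_tracks=0)
        assert p.n_dsb == 0

    def test_pure_bursts_give_one_cluster_each(self):
        p = nr.generate_break_pattern(
            chrom_sizes={"c": 10_000_000},
            n_tracks=50, dsb_per_track_mean=2.0, cluster_fraction=1.0,
            cluster_span_bp=10, seed=5, fixed_multiplicity=True,
        )
        s = nr.score_breaks(p)
        # every 2-break burst within 10 bp is a cluster; overlaps between
        # bursts on a 10 Mbp chromosome are vanishingly rare
        assert s.n_clusters == 50
        assert all(m == 2 for m in s.multiplicities)

    def test_isolated_break_collision_rate_matches_birthday_oracle(self):
        # cluster_fraction = 0: clusters arise only from accidental
        # proximity of independent uniform breaks.  For n uniform breaks
        # on G bp, a pair is linked when |Δ| ≤ 24, so
        # E[pairs] ≈ C(n,2)·(2·24+1)/G, and at this sparsity essentially
        # every linked pair is its own 2-cluster.
        G, n = 1_000_000, 200
        lam = n * (n - 1) / 2 * 49 / G
        total, reps = 0, 200
        for seed in range(reps):
            p = nr.generate_break_pattern(
                chrom_sizes={"c": G}, n_tracks=n, dsb_per_track_mean=1.0,
                cluster_fraction=0.0, cluster_span_bp=10, seed=seed,
                fixed_multiplicity=True,
            )
            total += nr.score_breaks(p).n_clusters
        expected = reps * lam
        assert abs(total - expected) < 3 * math.sqrt(expected)

    def test_span_must_fit_chromosome(self):
        with pytest.raises(InvalidParameterError):
            nr.generate_break_pattern(chrom_sizes={"c": 100}, cluster_span_bp=200)

    def test_same_seed_same_pattern(self):
        a = nr.generate_break_pattern(seed=7)
        b = nr.generate_break_pattern(seed=7)
        for chrom in a.dsb_positions:
            assert np.array_equal(a.dsb_positions[chrom], b.dsb_positions[chrom])


class TestEmergentStructure:
    def test_outer_ystar_low_energy_peak_at_1_mev(self, outer_table):
        from neutronrbe.coupling import interior_maxima

        E = np.array([c.neutron_energy for c in outer_table])
        ystar = np.array(
            [nr.composition_to_spectrum(c, y0=150.0)[1].y_star for c in outer_table]
        )
        low = E < 10.0
        peaks = interior_maxima(E[low], ystar[low])
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(1.0)

    def test_second_peak_less_prominent_for_clusters(
        self, outer_table, cluster_curves, fragment_curves
    ):
        def prominence(curves, endpoint):
            pts, maxima = nr.neutron_damage_curve(outer_table, curves, endpoint)
            E = np.array([p.neutron_energy for p in pts])
            Y = np.array([p.yield_per_gy_per_cell for p in pts])
            i1 = int(np.argmin(np.abs(E - maxima[0])))
            i2 = int(np.argmin(np.abs(E - maxima[-1])))
            return Y[i2] / Y[i1:i2 + 1].min()

        p_frag = prominence(fragment_curves, "short_fragments")
        p_clus = prominence(cluster_curves, "dsb_clusters")
        assert p_clus < p_frag

    def test_deeper_regions_peak_at_higher_energy(self):
        curves = nr.default_damage_curves("dsb_clusters", noise_cv=0.0)
        peaks = {}
        for region in ("outer", "intermediate", "inner"):
            cfg = nr.FieldGeneratorConfig(region=region)
            table = nr.generate_composition_table(cfg)
            _, maxima = nr.neutron_damage_curve(table, curves, "dsb_clusters")
            low = [m for m in maxima if m < 10.0]
            assert len(low) == 1
            peaks[region] = low[0]
        assert peaks["outer"] < peaks["intermediate"] < peaks["inner"]
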