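"""Generator determinism and forward-model self-consistency."""

import numpy as np
import pytest

from boxbind.errors import ConfigError
from boxbind.fret_stats import compare_groups
from boxbind.native_ms_occupancy import identical_sites_fractions, occupancy
from boxbind.sequence_motifs import BUILTIN_MOTIFS, scan_proteome
from boxbind.synthetic_data import (
    dilution_series,
    gen_fret_rois,
    gen_melting_titration,
    gen_species_titration,
    gen_toy_proteome,
    statistical_factor_kds,
    _identical_probs,
    _stepwise_probs,
)
from boxbind.thermal_shift import ThermoModel, detect_tm, predict_tm


class TestDeterminism:
    def test_same_seed_same_output(self):
        a = gen_toy_proteome(seed=7)
        b = gen_toy_proteome(seed=7)
        assert a.sequences == b.sequences
        assert all(
            np.array_equal(a.tracks[k].scores, b.tracks[k].scores) for k in a.tracks
        )
        fa = gen_fret_rois([("WT", 8.0, 30, 3.0)], seed=5)
        fb = gen_fret_rois([("WT", 8.0, 30, 3.0)], seed=5)
        assert fa.table.equals(fb.table)
        sa = gen_species_titration(("identical", 3, 50.0), seed=9)
        sb = gen_species_titration(("identical", 3, 50.0), seed=9)
        assert all(
            np.array_equal(x.intensities, y.intensities)
            for x, y in zip(sa.distributions, sb.distributions)
        )

    def test_different_seed_different_background(self):
        assert gen_toy_proteome(seed=1).sequences != gen_toy_proteome(seed=2).sequences


class TestToyProteome:
    def test_scan_recovers_disordered_plants_only(self):
        toy = gen_toy_proteome(seed=11)
        result = scan_proteome(
            toy.sequences, BUILTIN_MOTIFS["CBM"], toy.tracks, cutoff=0.5
        )
        expected = {
            (p["protein_id"], p["position"])
            for p in toy.manifest["plants"]
            if p["disordered"]
        }
        found = {
            (r.protein_id, r.start) for r in result.table.itertuples(index=False)
        }
        assert expected <= found
        # nothing outside the manifest's exhaustive self-scan
        for r in result.table.itertuples(index=False):
            assert r.start in toy.manifest["self_scan_starts"][r.protein_id]

    def test_unfiltered_scan_equals_manifest_self_scan(self):
        toy = gen_toy_proteome(seed=23)
        result = scan_proteome(toy.sequences, BUILTIN_MOTIFS["CBM"])
        expected = sum(len(v) for v in toy.manifest["self_scan_starts"].values())
        assert result.n_hits == expected

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ConfigError):
            gen_toy_proteome(plants=[(0, 40, True), (0, 42, True)], seed=0)


class TestMeltingTitration:
    def test_noiseless_detection_matches_midpoint_prediction(self):
        model = ThermoModel(318.15, 260.0)
        sim = gen_melting_titration(
            model, kd_uM=34.0, n_points=4, top_lt_uM=1000.0,
            baselines=((1.0, 0.0), (0.4, 0.0)), noise_sd=0.0,
        )
        for curve in sim.curves:
            tm_det = detect_tm(curve).tm_K
            tm_pred = predict_tm(model, 34.0, curve.ligand_total_uM, 8.0)
            assert tm_det == pytest.approx(tm_pred, abs=0.15)

    def test_tm_ladder_monotone_in_ligand(self):
        model = ThermoModel(318.15, 260.0)
        sim = gen_melting_titration(model, kd_uM=34.0, noise_sd=0.0)
        tms = [detect_tm(c).tm_K for c in sim.curves]  # curves sorted by Lt
        assert all(b >= a - 1e-9 for a, b in zip(tms, tms[1:]))

    def test_dilution_ladder_geometry(self):
        lts = dilution_series(3750.0)
        assert lts.size == 12 and lts[0] == 0.0
        assert lts[1] == pytest.approx(3750.0 / 2**10)  # ~3.66 uM bottom point
        assert lts[-1] == 3750.0


class TestSpeciesTitration:
    def test_large_counts_approach_analytic_fractions(self):
        sim = gen_species_titration(
            ("identical", 3, 50.0), lt_grid_uM=(20.0,), counts_n=2_000_000, seed=1
        )
        occ = occupancy(sim.distributions[0])
        expected = identical_sites_fractions(3, 50.0, 1.75, 20.0)
        assert np.allclose(occ.fractions, expected, atol=0.01)

    def test_statistical_factor_stepwise_equals_binomial(self):
        # Kd_i = Kd * i/(n-i+1) makes sequential binding exactly identical-sites
        kds = statistical_factor_kds(50.0, 3)
        for lt in (2.0, 10.0, 80.0):
            step = _stepwise_probs(kds, 1.75, lt)
            iid = _identical_probs(3, 50.0, 1.75, lt)
            assert np.allclose(step, iid, atol=1e-12)

    def test_zero_ligand_all_apo(self):
        sim = gen_species_titration(
            ("identical", 3, 50.0), lt_grid_uM=(0.0,), counts_n=1000, seed=0
        )
        counts = sim.distributions[0].intensities
        assert counts[0] == 1000 and counts[1:].sum() == 0


class TestFretRois:
    def test_zero_efficiency_group_centers_at_zero(self):
        ds = gen_fret_rois([("null", 0.0, 200, 3.0)], seed=2)
        comp = compare_groups(ds.table, "null")
        tm = comp.table["trimmed_mean_pct"].iloc[0]
        assert tm == pytest.approx(0.0, abs=3.0 / np.sqrt(200) * 3)

    def test_known_difference_recovered(self):
        ds = gen_fret_rois([("WT", 8.0, 100, 3.0), ("Cla", 5.0, 100, 3.0)], seed=4)
        comp = compare_groups(ds.table, "WT")
        t = comp.table.set_index("group")["trimmed_mean_pct"]
        assert t["WT"] - t["Cla"] == pytest.approx(3.0, abs=1.2)

    def test_underbleached_population_mostly_dropped(self):
        ds = gen_fret_rois(
            [("WT", 8.0, 200, 3.0)], bleach_mean=0.80, bleach_sd=0.02, seed=6
        )
        from boxbind.fret_stats import FretRoi, bleach_qc

        kept = sum(
            bleach_qc(FretRoi(str(r.roi_id), str(r.group), r.donor_pre,
                              r.donor_post, r.acceptor_pre, r.acceptor_post))
            for r in ds.table.itertuples(index=False)
        )
        assert kept < 50  # majority fails the 85% bleach threshold
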