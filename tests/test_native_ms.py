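"""Occupancy statistics, identical-sites null model, and competition."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

from boxbind.errors import FitError, ModelError
from boxbind.native_ms_occupancy import (
    CompetitionSystem,
    SpeciesDistribution,
    competition_curve,
    fit_identical_sites,
    identical_sites_fractions,
    occupancy,
    one_site_bound_fraction,
    solve_competition,
)


class TestOccupancy:
    def test_arithmetic_example(self):
        occ = occupancy(SpeciesDistribution(10.0, 2.0, [1.0, 2.0, 1.0]))
        assert np.allclose(occ.fractions, [0.25, 0.5, 0.25])
        assert occ.nu == pytest.approx(1.0)
        assert occ.lfree_uM == pytest.approx(8.0)
        assert occ.scatchard_y == pytest.approx(1.0 / 8.0)

    def test_apo_only(self):
        occ = occupancy(SpeciesDistribution(10.0, 2.0, [5.0, 0, 0, 0, 0]))
        assert occ.nu == 0.0 and occ.scatchard_y == 0.0

    def test_upper_bound_attained(self):
        occ = occupancy(SpeciesDistribution(50.0, 2.0, [0.0, 0, 0, 1.0]))
        assert occ.nu == pytest.approx(3.0)

    def test_overdepleted_ligand_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            occ = occupancy(SpeciesDistribution(1.0, 2.0, [0.0, 0, 1.0]))
        assert occ.lfree_uM == 0.0 and occ.scatchard_y is None


class TestIdenticalSites:
    def test_zero_ligand_all_apo(self):
        f = identical_sites_fractions(3, 10.0, 2.0, 0.0)
        assert f[0] == 1.0 and f.sum() == pytest.approx(1.0)

    def test_saturation_limit(self):
        f = identical_sites_fractions(3, 10.0, 2.0, 1e7)
        assert f[-1] == pytest.approx(1.0, abs=1e-5)

    def test_per_site_occupancy_fixed_point_oracle(self):
        n, kd, pt, lt = 3, 10.0, 2.0, 10.0
        p = 0.5
        for _ in range(500):
            p = (lt - n * pt * p) / (kd + lt - n * pt * p)
        f = identical_sites_fractions(n, kd, pt, lt)
        expected = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
        assert np.allclose(f, expected, atol=1e-9)
        assert p == pytest.approx(0.4266, abs=2e-4)

    def test_fractions_sum_to_one(self):
        for lt in (0.0, 1.0, 7.3, 100.0):
            f = identical_sites_fractions(4, 25.0, 1.75, lt)
            assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scatchard_linearity_exact(self):
        # nu / Lfree = (n - nu) / Kd is an algebraic identity of the model
        n, kd, pt = 3, 50.0, 1.75
        for lt in (0.5, 2.0, 5.0, 20.0, 100.0, 1000.0):
            occ = occupancy(
                SpeciesDistribution(lt, pt, identical_sites_fractions(n, kd, pt, lt))
            )
            assert occ.scatchard_y == pytest.approx((n - occ.nu) / kd, abs=1e-9)

    def test_exact_binomial_point_has_zero_deviation(self):
        kd = 50.0
        dists = [
            SpeciesDistribution(lt, 1.75, identical_sites_fractions(3, kd, 1.75, lt))
            for lt in (5.0, 20.0, 80.0)
        ]
        fit = fit_identical_sites(dists, 3)
        assert fit.deviation == pytest.approx(0.0, abs=1e-12)
        assert fit.kd_uM == pytest.approx(kd, rel=1e-3)

    def test_all_apo_titration_is_degenerate(self):
        dists = [
            SpeciesDistribution(lt, 1.75, [1.0, 0, 0, 0]) for lt in (0.0, 1.0, 2.0)
        ]
        with pytest.raises(FitError):
            fit_identical_sites(dists, 3)


class TestCompetition:
    def test_single_ligand_reduces_to_quadratic(self):
        pt, at, kda = 1.75, 20.0, 138.0
        res = solve_competition(CompetitionSystem(pt, at, 0.0, kda, 177.0))
        assert res.fraction_pa == pytest.approx(
            one_site_bound_fraction(pt, at, kda), abs=1e-9
        )
        assert res.fraction_pb == 0.0

    def test_symmetric_ligands_split_equally(self):
        res = solve_competition(CompetitionSystem(1.75, 20.0, 20.0, 150.0, 150.0))
        assert res.fraction_pa == pytest.approx(res.fraction_pb, abs=1e-10)

    def test_mass_conservation(self):
        sys = CompetitionSystem(1.75, 20.0, 35.0, 138.0, 177.0)
        res = solve_competition(sys)
        pa = res.fraction_pa * sys.pt_uM
        pb = res.fraction_pb * sys.pt_uM
        assert res.afree_uM + pa == pytest.approx(sys.at_uM, abs=1e-9)
        assert res.bfree_uM + pb == pytest.approx(sys.bt_uM, abs=1e-9)
        assert res.pfree_uM + pa + pb == pytest.approx(sys.pt_uM, abs=1e-9)

    def test_against_fsolve_oracle(self):
        sys = CompetitionSystem(1.75, 20.0, 20.0, 138.0, 177.0)
        res = solve_competition(sys)

        def equations(v):
            p, a, b = v
            return [
                p + p * a / sys.kda_uM + p * b / sys.kdb_uM - sys.pt_uM,
                a + p * a / sys.kda_uM - sys.at_uM,
                b + p * b / sys.kdb_uM - sys.bt_uM,
            ]

        p, a, b = fsolve(equations, [sys.pt_uM, sys.at_uM, sys.bt_uM], xtol=1e-13)
        assert res.pfree_uM == pytest.approx(p, rel=1e-8)
        assert res.fraction_pa == pytest.approx(p * a / sys.kda_uM / sys.pt_uM, rel=1e-8)
        # the tighter binder occupies more of the shared site
        assert res.fraction_pa > res.fraction_pb

    def test_rejects_invalid_constants(self):
        with pytest.raises(ModelError):
            CompetitionSystem(1.75, 20.0, 20.0, -1.0, 177.0)


COMPETITION_GRID = [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 50.0]


class TestCompetitionCurve:
    def test_titration_design_table(self):
        table = competition_curve(
            1.75, ("Ent2", 20.0, 177.0), ("Ent1", COMPETITION_GRID, 138.0)
        )
        assert len(table) == 8
        fixed = table["frac_bound_Ent2"].to_numpy()
        assert np.all(np.diff(fixed) <= 1e-12)  # monotone non-increasing

    def test_inert_titrant_leaves_fixed_ligand_untouched(self):
        table = competition_curve(
            1.75, ("B", 20.0, 177.0), ("A", COMPETITION_GRID, 1e12)
        )
        fixed = table["frac_bound_B"].to_numpy()
        assert np.ptp(fixed) < 1e-9

    def test_stronger_titrant_displaces_more(self):
        strong = competition_curve(1.75, ("B", 20.0, 177.0), ("A", COMPETITION_GRID, 50.0))
        weak = competition_curve(1.75, ("B", 20.0, 177.0), ("A", COMPETITION_GRID, 500.0))
        s = strong["frac_bound_B"].to_numpy()[1:]
        w = weak["frac_bound_B"].to_numpy()[1:]
        assert np.all(s < w)

    def test_displacement_asymmetry_matches_affinity_order(self):
        # the tighter ligand (KdA < KdB) displaces the weaker one by a larger
        # fraction of its starting occupancy than the mirror experiment does
        kda, kdb, pt = 138.0, 177.0, 1.75
        a_into_b = competition_curve(pt, ("B", 20.0, kdb), ("A", COMPETITION_GRID, kda))
        b_into_a = competition_curve(pt, ("A", 20.0, kda), ("B", COMPETITION_GRID, kdb))
        rel_b = 1.0 - (a_into_b["frac_bound_B"] / a_into_b["frac_bound_B"].iloc[0])
        rel_a = 1.0 - (b_into_a["frac_bound_A"] / b_into_a["frac_bound_A"].iloc[0])
        assert np.all(rel_b.to_numpy()[1:] > rel_a.to_numpy()[1:])
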