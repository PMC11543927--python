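"""End-to-end simulation studies validating the analysis chain.

Each study simulates data under the conditions of the underlying
experiments with the forward generators, runs the corresponding analysis,
and reports recovery/error-rate summaries.  They are used both by the
validation test suite and by the reproduction script, so the numbers those
two report are computed by the same code path.

All studies are deterministic given a base seed; internal seeds are
derived from it and stay below 2**31.
"""

from __future__ import annotations

import numpy as np

from .fret_stats import compare_groups
from .native_ms_occupancy import (
    fit_identical_sites,
    identical_sites_fractions,
    null_deviation_quantile,
    occupancy,
)
from .synthetic_data import (
    DEFAULT_NTD_MODEL_PARAMS,
    dilution_series,
    gen_fret_rois,
    gen_species_titration,
)
from .thermal_shift import ThermoModel, fit_kd_tmshift, predict_tm

FRET_GROUPS = ("WT", "Cla", "Arr", "W", "Cla+Arr", "Cla+W", "Arr+W", "Cla+Arr+W")


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def kd_recovery_study(
    kds_uM=(34.0, 138.0, 598.0),
    n_seeds: int = 20,
    noise_sd_K: float = 0.3,
    pt_uM: float = 8.0,
    top_lt_uM: float = 3750.0,
    seed: int = 0,
    model: ThermoModel | None = None,
) -> dict:
    """Tm-shift KD recovery under the eleven-point 1:1 dilution design.

    For each truth Kd, Tm values are forward-predicted on the titration
    ladder (plus apo), perturbed with iid Gaussian noise of ``noise_sd_K``
    Kelvin, and refitted.  Returns per-Kd and pooled relative-error
    summaries plus the noiseless round-trip error.
    """
    model = model or ThermoModel(**DEFAULT_NTD_MODEL_PARAMS)
    lts = dilution_series(top_lt_uM)
    per_kd = {}
    all_errs = []
    for kd in kds_uM:
        errs = []
        for s in range(n_seeds):
            rng = np.random.default_rng(_sub_seed(seed, int(kd) * 1000 + s))
            obs = [
                (lt, predict_tm(model, kd, lt, pt_uM) + rng.normal(0.0, noise_sd_K))
                for lt in lts
            ]
            fit = fit_kd_tmshift(obs, pt_uM, model_init=model, profile_ci=False)
            errs.append(abs(fit.kd_app_uM / kd - 1.0))
        per_kd[kd] = {"median_rel_err": float(np.median(errs)), "errs": errs}
        all_errs.extend(errs)

    # noiseless round trip at the middle truth value
    kd_mid = kds_uM[len(kds_uM) // 2]
    obs0 = [(lt, predict_tm(model, kd_mid, lt, pt_uM)) for lt in lts]
    fit0 = fit_kd_tmshift(obs0, pt_uM, model_init=model, profile_ci=False)
    return {
        "pooled_median_rel_err": float(np.median(all_errs)),
        "per_kd": per_kd,
        "noiseless_rel_err": abs(fit0.kd_app_uM / kd_mid - 1.0),
        "n_fits": len(all_errs),
    }


def identical_sites_study(
    kd_uM: float = 50.0,
    n_sites: int = 3,
    pt_uM: float = 1.75,
    lt_grid_uM=(0.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    counts_n: int = 5000,
    cooperative_kds_uM=(200.0, 50.0, 12.5),
    n_null_datasets: int = 10,
    n_coop_seeds: int = 20,
    n_null_sims: int = 200,
    seed: int = 0,
) -> dict:
    """Identical-sites null recovery and cooperativity detection.

    Null side: multinomial titrations from the binomial model are fitted;
    reports the Kd relative error on the first dataset and, across
    ``n_null_datasets`` datasets, the fraction whose deviation statistic
    stays below its simulated 95th-percentile null threshold (expected
    0.95).  Alternative side: titrations from the stepwise cooperative
    model (positive cooperativity: successively tighter site constants)
    are fitted the same way; reports the fraction of seeds whose deviation
    exceeds the threshold.
    """
    below = 0
    kd_err = None
    for k in range(n_null_datasets):
        sim = gen_species_titration(
            ("identical", n_sites, kd_uM), pt_uM, lt_grid_uM, counts_n,
            seed=_sub_seed(seed, 10 + k),
        )
        fit = fit_identical_sites(sim.distributions, n_sites)
        if kd_err is None:
            kd_err = abs(fit.kd_uM / kd_uM - 1.0)
        thr = null_deviation_quantile(
            n_sites, fit.kd_uM, pt_uM, lt_grid_uM, counts_n,
            n_sims=n_null_sims, seed=_sub_seed(seed, 500 + k),
        )
        below += fit.deviation < thr

    detected = 0
    for k in range(n_coop_seeds):
        sim = gen_species_titration(
            ("stepwise", list(cooperative_kds_uM)), pt_uM, lt_grid_uM, counts_n,
            seed=_sub_seed(seed, 1000 + k),
        )
        fit = fit_identical_sites(sim.distributions, n_sites)
        thr = null_deviation_quantile(
            n_sites, fit.kd_uM, pt_uM, lt_grid_uM, counts_n,
            n_sims=n_null_sims, seed=_sub_seed(seed, 2000 + k),
        )
        detected += fit.deviation > thr

    return {
        "kd_rel_err": float(kd_err),
        "null_below_threshold_rate": below / n_null_datasets,
        "cooperative_detection_rate": detected / n_coop_seeds,
    }


def scatchard_linearity_error(
    kd_uM: float = 50.0,
    n_sites: int = 3,
    pt_uM: float = 1.75,
    lt_grid_uM=(1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 500.0),
) -> float:
    """Max deviation of nu/Lfree from (n - nu)/Kd on the exact model.

    For independent identical sites the Scatchard plot is the straight
    line nu/Lfree = (n - nu)/Kd; this returns the largest absolute
    discrepancy across the grid (an algebraic identity, so it is at
    numerical round-off).
    """
    from .native_ms_occupancy import SpeciesDistribution

    worst = 0.0
    for lt in lt_grid_uM:
        frac = identical_sites_fractions(n_sites, kd_uM, pt_uM, lt)
        occ = occupancy(SpeciesDistribution(lt, pt_uM, frac))
        if occ.scatchard_y is None:
            continue
        worst = max(worst, abs(occ.scatchard_y - (n_sites - occ.nu) / kd_uM))
    return worst


def fret_null_fwer_study(
    n_replicates: int = 1000,
    n_per_group: int = 100,
    true_e_pct: float = 8.0,
    sd_pct: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise type-I error of the Yuen/Holm pipeline under the null.

    Every replicate draws all eight groups of the FRET mutant design from
    the reference distribution and counts replicates with any Holm-adjusted
    p-value below ``alpha``.
    """
    false_positives = 0
    for rep in range(n_replicates):
        ds = gen_fret_rois(
            [(g, true_e_pct, n_per_group, sd_pct) for g in FRET_GROUPS],
            seed=_sub_seed(seed, rep),
        )
        comp = compare_groups(ds.table, "WT")
        p_adj = comp.table["p_adj_vs_reference"].dropna()
        false_positives += bool((p_adj < alpha).any())
    return {
        "fwer": false_positives / n_replicates,
        "n_replicates": n_replicates,
    }


def fret_power_study(
    wt_e_pct: float = 8.0,
    mut_e_pct: float = 5.0,
    n_per_group: int = 100,
    sd_pct: float = 3.0,
    n_seeds: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection rate of a WT-vs-mutant efficiency difference.

    Simulates the full eight-group design with one group (Cla) at the
    mutant efficiency and the rest at the reference value; reports how
    often the mutant is flagged significant after Holm adjustment.
    """
    hits = 0
    for rep in range(n_seeds):
        groups = [
            (g, mut_e_pct if g == "Cla" else wt_e_pct, n_per_group, sd_pct)
            for g in FRET_GROUPS
        ]
        ds = gen_fret_rois(groups, seed=_sub_seed(seed, 7000 + rep))
        comp = compare_groups(ds.table, "WT")
        row = comp.table[comp.table["group"] == "Cla"]
        hits += bool((row["p_adj_vs_reference"] < alpha).all())
    return {"power": hits / n_seeds, "n_seeds": n_seeds}
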