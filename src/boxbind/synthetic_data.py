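"""Seeded synthetic inputs with the statistical structure the analyses assume.

Each generator emulates one experimental data stream of the binding study
and returns, alongside the data, a machine-readable truth manifest the
test suite uses as its oracle:

* toy proteomes with clathrin-binding motifs planted inside disordered
  (score 0.9) or ordered (score 0.1) spans of random background sequence;
* nanoDSF melting titrations from the two-state, ligand-coupled model:
  eleven 1:1 dilution points from a top peptide concentration (plus an
  apo curve), linear folded/unfolded baselines and Gaussian noise;
* native-MS species titrations: equilibrium species probabilities (exact
  binomial for independent identical sites, sequential partition function
  for stepwise constants) sampled as multinomial counts;
* acceptor-photobleaching FRET ROI tables with known per-group true
  efficiency and bleach-fraction distribution.

The forward models here are implemented independently of the fitting code
in the analysis modules (full per-temperature equilibrium instead of the
midpoint condition, mass-balance root finding instead of the occupancy
quadratic), so parameter-recovery tests exercise a genuine round trip.
All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .sequence_motifs import AA_ALPHABET, DisorderTrack, MotifSpec, get_motif
from .thermal_shift import CELSIUS_OFFSET, MeltingCurve, ThermoModel

_AA = sorted(AA_ALPHABET)

#: Scenario presets: apparent KD scales (µM) of the studied adaptor peptides.
PEPTIDE_KD_UM = {
    "ent5_1": 34.0,
    "ent1": 138.0,
    "ent2": 177.0,
    "apl2_1": 245.0,
    "yap1802": 311.0,
    "yap1801": 598.0,
}

#: Default unfolding thermodynamics of the scanned domain.  dHu is set so
#: that a saturating peptide titration (top 3.75 mM, Kd ~ 34 µM) shifts the
#: midpoint by more than 15 K, the stabilization scale reported for
#: CBM-bound clathrin NTD; Tm0 = 45 C is a typical apo midpoint for a
#: small globular domain ramped from 20 to 95 C.
DEFAULT_NTD_MODEL_PARAMS = {"tm0_K": 318.15, "dhu_kJmol": 260.0, "dcp_kJmolK": 0.0}

#: Peptide sequences carrying one CBM each.
PEPTIDE_SEQUENCES = {
    "Ent1": "GYTLIDL",
    "Ent2": "GVSLIDL",
    "Ent5.1": "IPDLIDLDD",
    "Yap1801": "NLNLIDM",
    "Yap1802": "NPNLIDI",
    "Apl2.1": "SQDLLDLF",
}


# ---------------------------------------------------------------------------
# Toy proteome
# ---------------------------------------------------------------------------


@dataclass
class ToyProteome:
    sequences: dict
    tracks: dict
    manifest: dict


def _brute_force_hits(seq: str, motif: MotifSpec):
    """Window-by-window exhaustive check, independent of the scanner."""
    out = []
    m = len(motif)
    for i in range(len(seq) - m + 1):
        ok = True
        for k in range(m):
            cls = motif.classes[k]
            if len(cls) == len(AA_ALPHABET):
                continue
            if seq[i + k] not in cls:
                ok = False
                break
        if ok:
            out.append(i + 1)
    return out


def gen_toy_proteome(
    n_proteins: int = 10,
    length: int = 300,
    plants: "list[tuple[int, int, bool]] | None" = None,
    motif: "MotifSpec | str" = "CBM",
    disorder_span: int = 7,
    seed: int = 0,
) -> ToyProteome:
    """Random proteome with planted motif instances and disorder tracks.

    ``plants`` is a list of ``(protein_index, position, disordered)``
    tuples (position 1-based).  Background is uniform over the 20
    residues; the disorder track is 0.1 everywhere except a window of
    ``disorder_span`` residues around each disordered plant, set to 0.9.
    The manifest records every plant plus an exhaustive self-scan of the
    finished sequences (so accidental background matches are accounted
    for).
    """
    motif = get_motif(motif) if isinstance(motif, str) else motif
    rng = np.random.default_rng(seed)
    if plants is None:
        plants = [(0, 40, True), (1, 80, True), (2, 120, True),
                  (3, 160, True), (4, 200, False), (5, 240, False)]
    m = len(motif)
    spans = {}
    for idx, pos, _ in plants:
        if not (0 <= idx < n_proteins):
            raise ConfigError(f"plant protein index {idx} out of range")
        if not (1 <= pos <= length - m + 1):
            raise ConfigError(f"plant position {pos} out of sequence bounds")
        for other_pos, _ in spans.get(idx, []):
            if abs(other_pos - pos) < m:
                raise ConfigError(
                    f"overlapping plants at protein {idx}, positions "
                    f"{other_pos} and {pos}"
                )
        spans.setdefault(idx, []).append((pos, None))

    seqs = {}
    tracks = {}
    plant_records = []
    for i in range(n_proteins):
        letters = rng.choice(_AA, size=length)
        scores = np.full(length, 0.1)
        seqs[f"prot{i:03d}"] = letters
        tracks[f"prot{i:03d}"] = scores
    for idx, pos, disordered in plants:
        pid = f"prot{idx:03d}"
        instance = "".join(
            rng.choice(sorted(cls)) for cls in motif.classes
        )
        seqs[pid][pos - 1 : pos - 1 + m] = list(instance)
        if disordered:
            lo = max(0, pos - 1 - (disorder_span - m) // 2)
            tracks[pid][lo : lo + max(disorder_span, m)] = 0.9
        plant_records.append(
            {"protein_id": pid, "position": pos, "instance": instance,
             "disordered": bool(disordered)}
        )

    sequences = {pid: "".join(arr) for pid, arr in seqs.items()}
    track_objs = {
        pid: DisorderTrack(pid, scores, "disorder_probability")
        for pid, scores in tracks.items()
    }
    self_scan = {
        pid: _brute_force_hits(s, motif) for pid, s in sequences.items()
    }
    manifest = {
        "seed": seed,
        "motif": motif.name,
        "plants": plant_records,
        "self_scan_starts": self_scan,
        "n_expected_disordered_hits": sum(1 for p in plant_records if p["disordered"]),
    }
    return ToyProteome(sequences=sequences, tracks=track_objs, manifest=manifest)


# ---------------------------------------------------------------------------
# nanoDSF melting titration
# ---------------------------------------------------------------------------


@dataclass
class MeltingTitration:
    curves: list
    manifest: dict


def _fu_coupled(T_K: float, model: ThermoModel, kd_uM: float,
                lt_uM: float, pt_uM: float) -> float:
    """Unfolded fraction with 1:1 binding to the folded state.

    Species: U (unfolded), F (free folded), FL (bound folded) with
    Ku = U/F and Kd = F*L/FL.  Free ligand L solves the mass balance
    Lt = L + Pt * (L/Kd) / (1 + Ku + L/Kd); fu = Ku / (1 + Ku + L/Kd).
    """
    ku = float(model.ku(T_K))
    if lt_uM == 0:
        return ku / (1.0 + ku)

    def balance(L):
        return lt_uM - L - pt_uM * (L / kd_uM) / (1.0 + ku + L / kd_uM)

    L = brentq(balance, 0.0, lt_uM, xtol=1e-12, rtol=1e-14)
    return ku / (1.0 + ku + L / kd_uM)


def dilution_series(top_uM: float, n_points: int = 11, dilution: float = 2.0,
                    include_apo: bool = True) -> np.ndarray:
    """Descending 1:`dilution` series from ``top_uM``, optionally plus 0."""
    lts = top_uM / dilution ** np.arange(n_points)
    if include_apo:
        lts = np.append(lts, 0.0)
    return np.sort(lts)


def gen_melting_titration(
    model: ThermoModel,
    kd_uM: float,
    pt_uM: float = 8.0,
    top_lt_uM: float = 3750.0,
    n_points: int = 11,
    dilution: float = 2.0,
    include_apo: bool = True,
    temp_range_C: tuple = (20.0, 95.0),
    step_C: float = 0.5,
    baselines: tuple = ((1.0, -0.0015), (0.45, -0.0005)),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltingTitration:
    """Forward-simulated nanoDSF titration under the ligand-coupled model.

    Ligand concentrations are an ``n_points``-step 1:``dilution`` series
    from ``top_lt_uM`` (the study design: eleven 1:1 dilutions), plus an
    apo curve by default.  The signal is

        native(T) + (unfolded(T) - native(T)) * fu_app(T)

    with linear baselines ``(intercept, slope)`` relative to 20 C and
    optional Gaussian noise scaled to ``noise_sd`` times the baseline
    separation.  fu_app comes from the full three-species equilibrium at
    each temperature, not from the midpoint shortcut used by the fitter.
    """
    rng = np.random.default_rng(seed)
    lts = dilution_series(top_lt_uM, n_points, dilution, include_apo)
    T_C = np.arange(temp_range_C[0], temp_range_C[1] + step_C / 2, step_C)
    T_K = T_C + CELSIUS_OFFSET
    (an, bn), (au, bu) = baselines
    amplitude = abs(au - an)
    curves = []
    for lt in lts:
        fu = np.array([_fu_coupled(t, model, kd_uM, lt, pt_uM) for t in T_K])
        native = an + bn * (T_C - temp_range_C[0])
        unfolded = au + bu * (T_C - temp_range_C[0])
        signal = native + (unfolded - native) * fu
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd * amplitude, signal.size)
        curves.append(
            MeltingCurve(
                temperature_C=T_C.copy(),
                signal=signal,
                ligand_total_uM=float(lt),
                protein_total_uM=pt_uM,
            )
        )
    manifest = {
        "seed": seed,
        "kd_uM": kd_uM,
        "pt_uM": pt_uM,
        "tm0_K": model.tm0_K,
        "dhu_kJmol": model.dhu_kJmol,
        "dcp_kJmolK": model.dcp_kJmolK,
        "lt_uM": [float(x) for x in lts],
        "noise_sd": noise_sd,
    }
    return MeltingTitration(curves=curves, manifest=manifest)


# ---------------------------------------------------------------------------
# Native-MS species titration
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTitration:
    distributions: list
    manifest: dict


def _identical_probs(n: int, kd: float, pt: float, lt: float) -> np.ndarray:
    """Binomial species probabilities via mass-balance root finding."""
    if lt == 0:
        probs = np.zeros(n + 1)
        probs[0] = 1.0
        return probs

    def balance(L):
        return lt - L - pt * n * L / (kd + L)

    L = brentq(balance, 0.0, lt, xtol=1e-14, rtol=1e-15)
    p = L / (kd + L)
    from math import comb

    i = np.arange(n + 1)
    return np.array([comb(n, k) for k in i]) * p**i * (1 - p) ** (n - i)


def _stepwise_probs(kds: "list[float]", pt: float, lt: float) -> np.ndarray:
    """Species probabilities for stepwise macroscopic constants Kd_1..Kd_n.

    [PL_i] proportional to L^i / prod_{j<=i} Kd_j; free L solves
    Lt = L + Pt * nu(L).
    """
    kds = np.asarray(kds, dtype=float)
    n = kds.size

    def weights(L):
        w = np.ones(n + 1)
        for i in range(1, n + 1):
            w[i] = w[i - 1] * L / kds[i - 1]
        return w

    if lt == 0:
        probs = np.zeros(n + 1)
        probs[0] = 1.0
        return probs

    def balance(L):
        w = weights(L)
        nu = (np.arange(n + 1) @ w) / w.sum()
        return lt - L - pt * nu

    L = brentq(balance, 0.0, lt, xtol=1e-14, rtol=1e-15)
    w = weights(L)
    return w / w.sum()


def statistical_factor_kds(kd_uM: float, n: int) -> list:
    """Stepwise constants Kd_i = Kd * i / (n - i + 1) of identical sites."""
    return [kd_uM * i / (n - i + 1) for i in range(1, n + 1)]


def gen_species_titration(
    binding: tuple,
    pt_uM: float = 1.75,
    lt_grid_uM=(0.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    counts_n: int = 5000,
    seed: int = 0,
) -> SpeciesTitration:
    """Multinomial species counts along a ligand titration.

    ``binding`` is ``("identical", n_sites, kd_uM)`` or
    ``("stepwise", [kd_1, ..., kd_n])``.  Each titration point draws
    ``counts_n`` protein molecules from the equilibrium species
    probabilities.
    """
    from .native_ms_occupancy import SpeciesDistribution

    rng = np.random.default_rng(seed)
    kind = binding[0]
    if kind == "identical":
        _, n, kd = binding
        prob_fn = lambda lt: _identical_probs(n, kd, pt_uM, lt)
        truth = {"model": "identical", "n_sites": n, "kd_uM": kd}
    elif kind == "stepwise":
        _, kds = binding
        prob_fn = lambda lt: _stepwise_probs(kds, pt_uM, lt)
        truth = {"model": "stepwise", "kds_uM": list(map(float, kds))}
    else:
        raise ConfigError(f"unknown binding model '{kind}'")

    dists = []
    probs_list = []
    for lt in lt_grid_uM:
        probs = prob_fn(float(lt))
        counts = rng.multinomial(counts_n, probs / probs.sum()).astype(float)
        if not counts.any():
            counts[0] = 1.0
        dists.append(SpeciesDistribution(float(lt), pt_uM, counts))
        probs_list.append([float(p) for p in probs])
    manifest = {
        "seed": seed,
        "pt_uM": pt_uM,
        "lt_grid_uM": [float(x) for x in lt_grid_uM],
        "counts_n": counts_n,
        "true_probabilities": probs_list,
        **truth,
    }
    return SpeciesTitration(distributions=dists, manifest=manifest)


# ---------------------------------------------------------------------------
# FRET ROI tables
# ---------------------------------------------------------------------------


@dataclass
class FretDataset:
    table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def gen_fret_rois(
    groups: "list[tuple[str, float, int, float]]",
    bleach_mean: float = 0.92,
    bleach_sd: float = 0.03,
    donor_scale: float = 1000.0,
    seed: int = 0,
) -> FretDataset:
    """ROI intensity table with known group efficiencies.

    ``groups`` is a list of ``(label, true_E_percent, n_rois, sd_percent)``.
    donor_post is lognormal around ``donor_scale``; donor_pre is
    donor_post * (1 - E/100) with E drawn per ROI; the acceptor bleach
    fraction is normal(``bleach_mean``, ``bleach_sd``) clipped to [0, 1).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, true_e, n, sd in groups:
        if n < 1:
            raise ConfigError(f"group '{label}' needs n >= 1")
        donor_post = donor_scale * rng.lognormal(0.0, 0.3, n)
        e = rng.normal(true_e, sd, n)
        donor_pre = donor_post * (1.0 - e / 100.0)
        acceptor_pre = donor_scale * rng.lognormal(0.0, 0.3, n)
        bleach = np.clip(rng.normal(bleach_mean, bleach_sd, n), 0.0, 0.999)
        acceptor_post = acceptor_pre * (1.0 - bleach)
        for k in range(n):
            rows.append(
                (f"{label}_{k:04d}", label, donor_pre[k], donor_post[k],
                 acceptor_pre[k], acceptor_post[k])
            )
    table = pd.DataFrame(
        rows,
        columns=["roi_id", "group", "donor_pre", "donor_post",
                 "acceptor_pre", "acceptor_post"],
    )
    manifest = {
        "seed": seed,
        "groups": [
            {"label": g, "true_E_pct": e, "n": n, "sd_pct": sd}
            for g, e, n, sd in groups
        ],
        "bleach_mean": bleach_mean,
        "bleach_sd": bleach_sd,
    }
    return FretDataset(table=table, manifest=manifest)


# ---------------------------------------------------------------------------
# Synthetic structures (for superposition tests and the simulate CLI)
# ---------------------------------------------------------------------------


def gen_helix_calpha(n_residues: int = 10, start_num: int = 1) -> np.ndarray:
    """Idealized alpha-helical C-alpha trace (rise 1.5 A, 100 deg turn)."""
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    r = 2.3
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), 1.5 * i])


def write_calpha_pdb(path, coords: np.ndarray, chain: str = "A",
                     start_num: int = 1) -> None:
    """Write a minimal C-alpha-only PDB file (synthetic fixture)."""
    lines = []
    for k, (x, y, z) in enumerate(coords):
        num = start_num + k
        lines.append(
            f"ATOM  {k + 1:5d}  CA  ALA {chain}{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
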