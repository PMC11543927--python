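"""Shared plain-text readers/writers (FASTA, TSV/CSV, JSON results).

All outputs are diff-stable: fixed column order and floats printed with 6
significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError, InputNotFoundError
from .fret_stats import FretRoi
from .native_ms_occupancy import SpeciesDistribution
from .sequence_motifs import DisorderTrack
from .thermal_shift import MeltingCurve


def fmt6(x) -> str:
    """Fixed 6-significant-digit float formatting for diff-stable output."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{float(x):.6g}"


def _check_exists(path) -> Path:
    path = Path(path)
    if not path.exists():
        raise InputNotFoundError(f"input file not found: {path}")
    return path


def read_fasta(path) -> dict:
    """FASTA records as an id -> sequence dict; duplicate ids are an error."""
    path = _check_exists(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DataError(f"duplicate FASTA id '{rec.id}' in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(path, sequences: dict) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_disorder_tracks(path, kind: str = "disorder_probability") -> dict:
    """TSV with header protein_id, position (1-based), score -> tracks."""
    path = _check_exists(path)
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "score"}
    if not required.issubset(df.columns):
        raise DataError(
            f"disorder TSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    tracks = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, positions.size + 1)):
            raise DataError(f"track '{pid}': positions must be 1..L without gaps")
        tracks[str(pid)] = DisorderTrack(str(pid), sub["score"].to_numpy(), kind)
    return tracks


def write_disorder_tracks(path, tracks: dict) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tscore\n")
        for pid, track in tracks.items():
            for i, s in enumerate(track.scores, start=1):
                fh.write(f"{pid}\t{i}\t{fmt6(s)}\n")


def write_hit_table(path, table: pd.DataFrame) -> None:
    out = table.copy()
    out["disorder_mean"] = out["disorder_mean"].map(fmt6)
    out.to_csv(path, sep="\t", index=False)


def read_melting_curves(path, protein_uM: float) -> list:
    """Melting curves from CSV, long or wide format.

    Long: columns temperature_C, signal, ligand_uM (one block per ligand
    concentration).  Wide: a temperature_C column plus one signal column
    per concentration, headers parseable as µM values.
    """
    path = _check_exists(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    curves = []
    if {"temperature_C", "signal", "ligand_uM"}.issubset(cols):
        for lt, sub in df.groupby("ligand_uM", sort=True):
            sub = sub.sort_values("temperature_C")
            curves.append(
                MeltingCurve(
                    temperature_C=sub["temperature_C"].to_numpy(),
                    signal=sub["signal"].to_numpy(),
                    ligand_total_uM=float(lt),
                    protein_total_uM=protein_uM,
                )
            )
    elif "temperature_C" in cols:
        for col in df.columns:
            if col == "temperature_C":
                continue
            try:
                lt = float(col)
            except ValueError as exc:
                raise DataError(
                    f"wide-format column '{col}' is not a µM concentration"
                ) from exc
            curves.append(
                MeltingCurve(
                    temperature_C=df["temperature_C"].to_numpy(),
                    signal=df[col].to_numpy(),
                    ligand_total_uM=lt,
                    protein_total_uM=protein_uM,
                )
            )
    else:
        raise DataError(
            "melting CSV needs either (temperature_C, signal, ligand_uM) or a "
            "temperature_C column plus one column per concentration"
        )
    if not curves:
        raise DataError(f"no melting curves in {path}")
    return sorted(curves, key=lambda c: c.ligand_total_uM)


def write_melting_curves(path, curves: list) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "temperature_C": c.temperature_C,
                    "signal": c.signal,
                    "ligand_uM": c.ligand_total_uM,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_species_csv(path) -> list:
    """Species CSV (Lt_uM, Pt_uM, n_bound, intensity) -> distributions."""
    path = _check_exists(path)
    df = pd.read_csv(path)
    required = {"Lt_uM", "Pt_uM", "n_bound", "intensity"}
    if not required.issubset(df.columns):
        raise DataError(f"species CSV needs columns {sorted(required)}")
    dists = []
    for (lt, pt), sub in df.groupby(["Lt_uM", "Pt_uM"], sort=True):
        sub = sub.sort_values("n_bound")
        n_max = int(sub["n_bound"].max())
        intensities = np.zeros(n_max + 1)
        intensities[sub["n_bound"].to_numpy(dtype=int)] = sub["intensity"].to_numpy()
        dists.append(SpeciesDistribution(float(lt), float(pt), intensities))
    return dists


def write_species_csv(path, dists: list) -> None:
    rows = []
    for d in dists:
        for i, val in enumerate(d.intensities):
            rows.append((d.lt_uM, d.pt_uM, i, val))
    pd.DataFrame(rows, columns=["Lt_uM", "Pt_uM", "n_bound", "intensity"]).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_fret_rois(path) -> list:
    """ROI CSV -> FretRoi list; optional `background` column is subtracted."""
    path = _check_exists(path)
    df = pd.read_csv(path)
    required = {"roi_id", "group", "donor_pre", "donor_post",
                "acceptor_pre", "acceptor_post"}
    if not required.issubset(df.columns):
        raise DataError(f"ROI CSV needs columns {sorted(required)}")
    bg = df["background"] if "background" in df.columns else 0.0
    rois = []
    for idx, r in df.iterrows():
        b = float(bg.iloc[idx]) if hasattr(bg, "iloc") else 0.0
        rois.append(
            FretRoi(
                roi_id=str(r["roi_id"]),
                group=str(r["group"]),
                donor_pre=float(r["donor_pre"]) - b,
                donor_post=float(r["donor_post"]) - b,
                acceptor_pre=float(r["acceptor_pre"]) - b,
                acceptor_post=float(r["acceptor_post"]) - b,
            )
        )
    return rois


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
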