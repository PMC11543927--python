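"""C-alpha extraction and Kabsch least-squares superposition.

Crystal structures of the clathrin heavy-chain N-terminal domain in
complex with different adaptor peptides are compared over a common
residue range (the beta-propeller core) by optimal rigid-body
superposition of C-alpha atoms.  Structures are read from PDB or mmCIF
with gemmi; pairing between reference and mobile is by author residue
number over the intersection of the two selections (the compared models
are the same protein, so no sequence alignment is needed).

The Kabsch algorithm computes the proper rotation minimizing the RMSD in
closed form from the SVD of the coordinate covariance, with the
reflection case corrected so det(R) = +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import DataError, GeometryError, InputNotFoundError


@dataclass
class StructureModel:
    """Ordered C-alpha trace of one chain (author residue numbering)."""

    entry_id: str
    chain_id: str
    residues: list  # [(residue_number, np.ndarray shape (3,)), ...]

    def __post_init__(self):
        nums = [n for n, _ in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise DataError("residue numbers must be strictly increasing")
        for _, xyz in self.residues:
            if not np.all(np.isfinite(xyz)):
                raise DataError("non-finite coordinates")

    @property
    def residue_numbers(self) -> list:
        return [n for n, _ in self.residues]

    @property
    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.residues], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


def load_calpha(
    path: "str | Path",
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
) -> StructureModel:
    """Read the C-alpha trace of one chain from a PDB or mmCIF file.

    Only altloc '' or 'A' atoms are used (first occurrence wins); residues
    without a C-alpha are omitted.  ``residue_range`` is a 1-based
    inclusive (start, end) filter on author residue numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InputNotFoundError(f"structure file not found: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"cannot parse structure '{path}': {exc}") from exc
    structure.setup_entities()
    if not len(structure):
        raise DataError(f"'{path}' contains no models")
    model = structure[0]

    selected = None
    for ch in model:
        if chain is not None:
            if ch.name == chain:
                selected = ch
                break
        else:
            # first chain with any C-alpha = first protein chain
            if any(res.find_atom("CA", "*") for res in ch):
                selected = ch
                break
    if selected is None:
        raise DataError(
            f"chain {chain!r} not found in '{path}'" if chain
            else f"no protein chain with C-alpha atoms in '{path}'"
        )

    residues = []
    seen = set()
    for res in selected:
        num = res.seqid.num
        if residue_range is not None and not (residue_range[0] <= num <= residue_range[1]):
            continue
        if num in seen:
            continue
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                ca = atom
                break
        if ca is None:
            continue
        seen.add(num)
        residues.append((num, np.array([ca.pos.x, ca.pos.y, ca.pos.z])))
    if not residues:
        raise DataError(f"empty C-alpha selection in '{path}'")
    residues.sort(key=lambda t: t[0])
    return StructureModel(
        entry_id=structure.name or path.stem,
        chain_id=selected.name,
        residues=residues,
    )


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition: x_mobile -> rotation @ x + translation."""

    rotation: np.ndarray  # 3x3, proper orthogonal
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd_A: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    reference: StructureModel, mobile: StructureModel
) -> SuperpositionResult:
    """Least-squares superposition of mobile onto reference C-alphas.

    Atoms are paired by author residue number over the intersection of the
    two selections; at least 3 non-collinear common residues are required.
    """
    common = sorted(set(reference.residue_numbers) & set(mobile.residue_numbers))
    if len(common) < 3:
        raise GeometryError(f"only {len(common)} common residues; need >= 3")
    ref_map = dict(reference.residues)
    mob_map = dict(mobile.residues)
    P = np.array([mob_map[n] for n in common])  # mobile
    Q = np.array([ref_map[n] for n in common])  # reference

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) coordinate set")

    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    Rmat = Vt.T @ D @ U.T
    t = qc - Rmat @ pc
    diff = P0 @ Rmat.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(common)))
    return SuperpositionResult(
        rotation=Rmat, translation=t, rmsd_A=rmsd, n_atoms=len(common)
    )
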