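"""Positional character-class motif scanning in disordered regions.

Clathrin-binding motifs (CBMs) are short linear motifs (SLiMs) that sit in
intrinsically disordered regions of adaptor proteins and dock into the
binding boxes of the clathrin heavy-chain N-terminal domain.  This module
defines such motifs as ordered lists of allowed-residue classes (bracket
notation, e.g. ``[DSNTV]L[IL]D[ILMFW]``), scans protein sequences for all
(possibly overlapping) occurrences, and filters hits by a per-residue
disorder track -- either a disorder probability in [0, 1] (keep spans with
mean score at or above the cutoff, default 0.5) or an AlphaFold pLDDT in
[0, 100] (keep spans with mean strictly below the cutoff, default 50,
since low pLDDT marks predicted disorder).

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, MotifParseError

#: The 20 standard amino acids, upper case.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_WILDCARD = frozenset(AA_ALPHABET)  # a full-alphabet class behaves as a wildcard


@dataclass(frozen=True)
class MotifSpec:
    """A positional character-class motif.

    ``classes[i]`` is the set of residues allowed at motif position ``i``;
    a class equal to the full 20-letter alphabet is a wildcard and also
    matches non-standard letters (X, B, Z, U ...), whereas finite classes
    never do.
    """

    name: str
    classes: tuple[frozenset, ...]

    def __post_init__(self):
        if len(self.classes) < 3:
            raise MotifParseError(
                f"motif '{self.name}' has {len(self.classes)} positions; need >= 3"
            )
        for i, cls in enumerate(self.classes):
            if not cls:
                raise MotifParseError(f"motif '{self.name}' position {i + 1} is empty")
            bad = set(cls) - AA_ALPHABET
            if bad:
                raise MotifParseError(
                    f"motif '{self.name}' position {i + 1} has non-amino-acid "
                    f"letters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.classes)

    def matches_at(self, seq: str, i: int) -> bool:
        """True if the window ``seq[i : i + len(self)]`` (0-based) matches."""
        if i < 0 or i + len(self) > len(seq):
            return False
        for cls, letter in zip(self.classes, seq[i : i + len(self)]):
            if cls is _WILDCARD or cls == AA_ALPHABET:
                continue  # wildcard: any letter, including ambiguity codes
            if letter not in cls:
                return False
        return True


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder scores for one protein.

    ``kind`` is ``"disorder_probability"`` (scores in [0, 1], high =
    disordered) or ``"plddt"`` (scores in [0, 100], low = disordered).
    """

    protein_id: str
    scores: np.ndarray
    kind: str = "disorder_probability"

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if self.kind not in ("disorder_probability", "plddt"):
            raise DataError(f"unknown disorder track kind '{self.kind}'")
        hi = 1.0 if self.kind == "disorder_probability" else 100.0
        if scores.size and (scores.min() < 0 or scores.max() > hi):
            raise DataError(
                f"track '{self.protein_id}': scores outside [0, {hi:g}] "
                f"for kind '{self.kind}'"
            )

    @property
    def default_cutoff(self) -> float:
        return 0.5 if self.kind == "disorder_probability" else 50.0

    def span_mean(self, start: int, end: int) -> float:
        """Mean score over 1-based inclusive residue range [start, end]."""
        if start < 1 or end > self.scores.size:
            raise DataError(
                f"track '{self.protein_id}' (length {self.scores.size}) does not "
                f"cover span {start}-{end}"
            )
        return float(self.scores[start - 1 : end].mean())


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start`` is 1-based, span is inclusive."""

    protein_id: str
    start: int
    matched: str
    motif_name: str
    disorder_summary: float | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


def compile_motif(pattern: str, name: str | None = None) -> MotifSpec:
    """Parse a bracket-notation motif pattern into a :class:`MotifSpec`.

    Single upper-case letters are one-residue classes, ``[...]`` groups are
    multi-residue classes, and ``x``/``X`` are wildcards expanding to the
    full 20-letter alphabet.

    >>> m = compile_motif("[DSNTV]L[IL]D[ILMFW]")
    >>> [len(c) for c in m.classes]
    [5, 1, 2, 1, 5]
    """
    classes: list[frozenset] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i + 1)
            if j < 0:
                raise MotifParseError(
                    f"unbalanced bracket at position {i + 1}: '{pattern[i:]}'"
                )
            group = pattern[i + 1 : j]
            if not group:
                raise MotifParseError(f"empty class '[]' at position {i + 1}")
            bad = set(group.upper()) - AA_ALPHABET
            if bad:
                raise MotifParseError(
                    f"non-amino-acid letters {sorted(bad)} in class '[{group}]'"
                )
            classes.append(frozenset(group.upper()))
            i = j + 1
        elif ch == "]":
            raise MotifParseError(f"unbalanced ']' at position {i + 1}")
        elif ch in "xX":
            classes.append(_WILDCARD)
            i += 1
        elif ch.upper() in AA_ALPHABET:
            classes.append(frozenset(ch.upper()))
            i += 1
        else:
            raise MotifParseError(f"invalid token '{ch}' at position {i + 1}")
    return MotifSpec(name=name or pattern, classes=tuple(classes))


#: Built-in motif library.  Two CBM variants circulate: the initial
#: proteome-search form (first class [TSNV]) and the final refined form
#: (first class [DSNTV], adding the flanking-Asp matches such as Apl2 and
#: Ent5).  The refined [DSNTV] variant is the default CBM.
BUILTIN_MOTIFS: dict[str, MotifSpec] = {
    "CBM": compile_motif("[DSNTV]L[IL]D[ILMFW]", name="CBM"),
    "CBM_TSNV": compile_motif("[TSNV]L[IL]D[ILMFW]", name="CBM_TSNV"),
    "Arrestin": compile_motif("[LI][LI]GXL", name="Arrestin"),
    "W-box": compile_motif("WXXW", name="W-box"),
}


def get_motif(name_or_pattern: str) -> MotifSpec:
    """Look up a built-in motif by name, else compile as a pattern."""
    if name_or_pattern in BUILTIN_MOTIFS:
        return BUILTIN_MOTIFS[name_or_pattern]
    return compile_motif(name_or_pattern)


def scan_sequence(seq: str, motif: MotifSpec, protein_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, ascending start.

    The sequence must be upper case; letters outside the 20-letter alphabet
    are tolerated but only ever match wildcard positions.
    """
    hits = []
    m = len(motif)
    for i in range(len(seq) - m + 1):
        if motif.matches_at(seq, i):
            hits.append(
                MotifHit(
                    protein_id=protein_id,
                    start=i + 1,
                    matched=seq[i : i + m],
                    motif_name=motif.name,
                )
            )
    return hits


def filter_by_disorder(
    hits: Iterable[MotifHit],
    track: DisorderTrack,
    cutoff: float | None = None,
) -> list[MotifHit]:
    """Keep hits whose matched span is disordered on average.

    For probability tracks a hit survives iff the span mean is >= cutoff
    (default 0.5); for pLDDT tracks iff the span mean is strictly < cutoff
    (default 50).  ``disorder_summary`` is populated on every returned hit.
    """
    if cutoff is None:
        cutoff = track.default_cutoff
    kept = []
    for hit in hits:
        mean = track.span_mean(hit.start, hit.end)
        if track.kind == "disorder_probability":
            keep = mean >= cutoff
        else:
            keep = mean < cutoff
        if keep:
            kept.append(replace(hit, disorder_summary=mean))
    return kept


@dataclass
class ProteomeScan:
    """Result of :func:`scan_proteome`: the hit table plus summary counts."""

    table: pd.DataFrame
    n_hits: int
    n_proteins: int
    hits: list[MotifHit] = field(default_factory=list)


_TABLE_COLUMNS = ["protein_id", "motif_name", "start", "end", "matched", "disorder_mean"]


def scan_proteome(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    motifs: Sequence[MotifSpec] | MotifSpec,
    tracks: Mapping[str, DisorderTrack] | None = None,
    cutoff: float | None = None,
) -> ProteomeScan:
    """Scan every sequence with every motif, optionally disorder-filtered.

    ``sequences`` maps unique protein ids to sequences (a list of
    ``(id, seq)`` pairs is also accepted and checked for duplicate ids).
    Sequences without a track are kept unfiltered when ``tracks`` is given
    only for a subset; pass tracks for all proteins for a uniform filter.
    """
    if isinstance(motifs, MotifSpec):
        motifs = [motifs]
    if not isinstance(sequences, Mapping):
        ids = [pid for pid, _ in sequences]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate FASTA ids: {dupes}")
        sequences = dict(sequences)

    all_hits: list[MotifHit] = []
    for pid, seq in sequences.items():
        for motif in motifs:
            hits = scan_sequence(seq.upper(), motif, protein_id=pid)
            if tracks is not None and pid in tracks:
                hits = filter_by_disorder(hits, tracks[pid], cutoff)
            all_hits.extend(hits)

    rows = [
        (h.protein_id, h.motif_name, h.start, h.end, h.matched, h.disorder_summary)
        for h in all_hits
    ]
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return ProteomeScan(
        table=table,
        n_hits=len(all_hits),
        n_proteins=table["protein_id"].nunique() if len(table) else 0,
        hits=all_hits,
    )
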