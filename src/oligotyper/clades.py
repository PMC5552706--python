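"""Reference-based clade assignment of oligotype representatives.

Each representative is matched against a clade-labelled reference alignment
that shares the reads' coordinate system (same alignment template — this is
a preprocessing contract, not something checked beyond sequence length).
An exact match gives distance 0; otherwise the nearest reference(s) by
base-pair difference determine the clade call, and *all* tied clades are
reported jointly (e.g. "CB4, CB5").
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_GAP = ord("-")


@dataclass
class ReferenceDB:
    """Clade-labelled reference alignment."""

    ids: list[str]
    clades: list[str]
    matrix: np.ndarray  # (n_entries, alignment_length) uint8 ASCII

    @property
    def alignment_length(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class CladeAssignment:
    """Clade call for one representative: all best-matching clades at minimal distance."""

    oligotype: str
    best_clades: tuple[str, ...]
    distance: int
    matched_ids: tuple[str, ...]

    @property
    def label(self) -> str:
        """Joint label, Table-style: tied clades comma-joined."""
        return ", ".join(self.best_clades)


def load_reference_db(path: str | Path, clade_key: str = "clade") -> ReferenceDB:
    """Load an aligned reference FASTA whose deflines carry ``|clade=<label>`` tags."""
    pattern = re.compile(rf"(?:^|\|){re.escape(clade_key)}=([^|\s]+)")
    ids: list[str] = []
    clades: list[str] = []
    seqs: list[str] = []
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.search(rec.description)
        if m is None:
            raise ValueError(f"reference record {rec.id!r} has no {clade_key}= tag")
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"reference record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        ids.append(rec.id.split("|")[0])
        clades.append(m.group(1))
        seqs.append(seq)
    if not seqs:
        return ReferenceDB([], [], np.empty((0, 0), dtype=np.uint8))
    mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(len(seqs), length).copy()
    tally = Counter(clades)
    logger.info(
        "load_reference_db: %d entries, %d clades (%s)",
        len(ids), len(tally), ", ".join(f"{c}:{n}" for c, n in sorted(tally.items())),
    )
    return ReferenceDB(ids, clades, mat)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def sequence_distance(a: str, b: str) -> int:
    """Base-pair differences between two aligned sequences.

    Columns where both sequences are gaps are excluded; a gap aligned to a
    base counts as one difference.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    x, y = _encode(a), _encode(b)
    both_gap = (x == _GAP) & (y == _GAP)
    return int(((x != y) & ~both_gap).sum())


def assign_clade(rep: str, db: ReferenceDB, oligotype: str = "") -> CladeAssignment:
    """Find the minimal-distance reference entries and report their clades jointly."""
    if len(db) == 0:
        raise ValueError("reference database is empty")
    x = _encode(rep)
    if x.size != db.alignment_length:
        raise ValueError(
            f"representative length {x.size} != reference alignment length "
            f"{db.alignment_length}"
        )
    both_gap = (db.matrix == _GAP) & (x == _GAP)
    dists = ((db.matrix != x) & ~both_gap).sum(axis=1)
    dmin = int(dists.min())
    hits = np.flatnonzero(dists == dmin)
    best = tuple(sorted({db.clades[i] for i in hits}))
    matched = tuple(db.ids[i] for i in hits)
    return CladeAssignment(oligotype, best, dmin, matched)
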