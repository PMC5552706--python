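"""Aligned-FASTA intake, gap-column trimming and read dereplication.

Reads arrive as a pre-aligned multi-FASTA in which every defline encodes the
sample a read came from (by default, everything before the *last* separator:
``<sample>_<read>``). Internally an alignment is held as a dense uint8 matrix
of ASCII codes over the closed alphabet ``{A, C, G, T, -, N}`` — one row per
read, one column per alignment position — which makes the downstream entropy
and decomposition passes cheap vectorised operations.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Closed residue alphabet: four bases, the alignment gap, and N for anything else.
ALPHABET = "ACGT-N"
GAP = ord("-")
N_CODE = ord("N")
_ALLOWED = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


@dataclass
class AlignedReadSet:
    """Equal-length aligned reads with one sample label per read.

    Attributes
    ----------
    matrix:
        ``(n_reads, n_columns)`` uint8 array of ASCII codes over
        ``{A, C, G, T, -, N}``.
    read_ids:
        Unique per-read identifiers (the full FASTA defline id).
    samples:
        Sample label of each read, parallel to ``read_ids``.
    column_map:
        Maps the current column index to the column index of the original
        (untrimmed) alignment; strictly increasing.
    """

    matrix: np.ndarray
    read_ids: list[str]
    samples: list[str]
    column_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-dimensional")
        if self.column_map is None:
            self.column_map = np.arange(self.matrix.shape[1])
        self.column_map = np.asarray(self.column_map, dtype=int)
        n = self.matrix.shape[0]
        if len(self.read_ids) != n or len(self.samples) != n:
            raise ValueError("read_ids and samples must match the number of rows")
        if self.column_map.shape[0] != self.matrix.shape[1]:
            raise ValueError("column_map length must equal the number of columns")
        if self.column_map.size > 1 and not np.all(np.diff(self.column_map) > 0):
            raise ValueError("column_map must be strictly increasing")
        if len(set(self.read_ids)) != n:
            raise ValueError("read identifiers must be unique")

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    @property
    def alignment_length(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_counts(self) -> Counter:
        """Reads per sample."""
        return Counter(self.samples)

    def sequences(self) -> list[str]:
        """Decode the rows back into strings."""
        return [row.tobytes().decode("ascii") for row in self.matrix]

    def subset(self, indices: np.ndarray | Sequence[int]) -> "AlignedReadSet":
        idx = np.asarray(indices, dtype=int)
        return AlignedReadSet(
            matrix=self.matrix[idx],
            read_ids=[self.read_ids[i] for i in idx],
            samples=[self.samples[i] for i in idx],
            column_map=self.column_map.copy(),
        )


def empty_read_set(alignment_length: int = 0) -> AlignedReadSet:
    return AlignedReadSet(
        matrix=np.empty((0, alignment_length), dtype=np.uint8),
        read_ids=[],
        samples=[],
        column_map=np.arange(alignment_length),
    )


def _sample_from_defline(defline: str, sep: str, regex: str | None) -> str:
    if regex is not None:
        m = re.search(regex, defline)
        if m is None or not m.groups():
            raise ValueError(f"defline {defline!r} does not match sample pattern {regex!r}")
        return m.group(1)
    head, _, tail = defline.rpartition(sep)
    if not head or not tail:
        raise ValueError(
            f"defline {defline!r} has no {sep!r}-separated sample prefix"
        )
    return head


def read_aligned_fasta(
    path: str | Path,
    sample_sep: str = "_",
    sample_regex: str | None = None,
) -> AlignedReadSet:
    """Read a pre-aligned multi-FASTA with sample-labelled deflines.

    All records must share a single alignment length; a record of deviating
    length aborts the read and names the offender (misaligned reads are a
    defect of the upstream aligner, not something to silently drop here).
    Characters outside ``{A,C,G,T,-}`` are mapped to ``N`` and counted in
    the log.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.info("read_aligned_fasta: %s is empty", path)
        return empty_read_set()

    length: int | None = None
    first_id = ""
    seqs: list[str] = []
    ids: list[str] = []
    samples: list[str] = []
    for i, rec in enumerate(records, start=1):
        seq = str(rec.seq).upper()
        if length is None:
            length, first_id = len(seq), rec.id
        elif len(seq) != length:
            raise ValueError(
                f"record {rec.id!r} (entry {i}) has length {len(seq)}, "
                f"expected {length} as in {first_id!r}"
            )
        try:
            sample = _sample_from_defline(rec.id, sample_sep, sample_regex)
        except ValueError as exc:
            raise ValueError(f"record {i}: {exc}") from exc
        seqs.append(seq)
        ids.append(rec.id)
        samples.append(sample)

    mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(len(seqs), length).copy()
    bad = ~np.isin(mat, _ALLOWED)
    if bad.any():
        logger.warning(
            "read_aligned_fasta: %d non-ACGT/gap characters mapped to N", int(bad.sum())
        )
        mat[bad] = N_CODE

    rs = AlignedReadSet(matrix=mat, read_ids=ids, samples=samples)
    tally = rs.sample_counts
    logger.info(
        "read_aligned_fasta: %d reads x %d columns from %d samples (%s)",
        rs.n_reads,
        rs.alignment_length,
        len(tally),
        ", ".join(f"{s}:{c}" for s, c in sorted(tally.items())[:10]),
    )
    return rs


def write_aligned_fasta(rs: AlignedReadSet, path: str | Path) -> None:
    """Write the read set back out; deflines are the stored read ids."""
    records = (
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in zip(rs.read_ids, rs.sequences())
    )
    SeqIO.write(records, str(path), "fasta")


def trim_gap_columns(rs: AlignedReadSet, max_gap_fraction: float = 0.99) -> AlignedReadSet:
    """Drop uninformative gap columns.

    A column is removed when its gap frequency exceeds ``max_gap_fraction``;
    the default 0.99 removes only columns that are gaps in essentially every
    read (alignment-template artifacts). ``column_map`` keeps the original
    coordinates of the surviving columns.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    if rs.n_reads == 0:
        return rs
    gap_frac = (rs.matrix == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise ValueError("no informative columns: every column exceeds the gap threshold")
    if keep.all():
        return rs
    logger.info("trim_gap_columns: removing %d of %d columns", int((~keep).sum()), keep.size)
    return AlignedReadSet(
        matrix=rs.matrix[:, keep],
        read_ids=list(rs.read_ids),
        samples=list(rs.samples),
        column_map=rs.column_map[keep],
    )


@dataclass
class UniqueSequenceTally:
    """Dereplicated sequences with total and per-sample counts.

    Ordered by descending total count, then lexicographically by sequence.
    """

    sequences: list[str]
    counts: np.ndarray
    per_sample: list[Counter]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total(self) -> int:
        return int(self.counts.sum()) if len(self.sequences) else 0

    def items(self) -> Iterable[tuple[str, int]]:
        return zip(self.sequences, (int(c) for c in self.counts))


def dereplicate(rs: AlignedReadSet) -> UniqueSequenceTally:
    """Collapse identical aligned reads into unique sequences with counts."""
    if rs.n_reads == 0:
        return UniqueSequenceTally(sequences=[], counts=np.empty(0, dtype=int), per_sample=[])
    rows = np.ascontiguousarray(rs.matrix).view(
        np.dtype((np.void, rs.alignment_length))
    ).ravel()
    uniq, inverse, counts = np.unique(rows, return_inverse=True, return_counts=True)
    seqs = [u.tobytes().decode("ascii") for u in uniq]
    order = sorted(range(len(seqs)), key=lambda i: (-int(counts[i]), seqs[i]))
    per_sample: list[Counter] = [Counter() for _ in seqs]
    for row_idx, u_idx in enumerate(inverse):
        per_sample[u_idx][rs.samples[row_idx]] += 1
    return UniqueSequenceTally(
        sequences=[seqs[i] for i in order],
        counts=counts[order].astype(int),
        per_sample=[per_sample[i] for i in order],
    )
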