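"""Entropy-based oligotype decomposition.

An oligotype is the group of reads that share identical bases at a selected
set of high-entropy alignment columns. The machinery here covers the four
steps of that decomposition:

1. per-column Shannon entropy of the alignment (``entropy_profile``);
2. greedy iterative selection of component columns until the entropy that
   remains *within* each oligotype falls below a convergence threshold
   (``select_positions``);
3. partitioning of every read by its base string at the selected columns
   (``decompose``);
4. supervised noise filtering with the minimum-substantive-abundance rule:
   an oligotype is retained only if its most abundant unique full-length
   member sequence occurs at least ``M`` times (``apply_min_substantive_abundance``).

Entropy is computed in bits over the alphabet ``{A, C, G, T, -}``; ``N``
characters are excluded from both numerator and denominator. Gaps are kept
in the alphabet because, after uninformative gap columns have been trimmed,
a residual gap is as diagnostic as a substitution.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import AlignedReadSet

#: Characters that enter the entropy computation (N deliberately absent).
ENTROPY_ALPHABET = "ACGT-"
_ENT_CODES = np.frombuffer(ENTROPY_ALPHABET.encode(), dtype=np.uint8)

#: Default convergence threshold (bits) for position selection.
DEFAULT_EPSILON = 0.2
#: Default cap on the number of component positions.
DEFAULT_MAX_POSITIONS = 19
#: Default minimum substantive abundance.
DEFAULT_M = 20


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def _char_counts(matrix: np.ndarray) -> np.ndarray:
    """Per-column counts of A, C, G, T, ``-`` as a ``(5, n_columns)`` array."""
    return np.stack([(matrix == c).sum(axis=0) for c in _ENT_CODES])


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    p = counts / safe
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=0)
    return np.where(totals > 0, np.maximum(h, 0.0), 0.0)


def column_entropy(rs: AlignedReadSet, col: int) -> float:
    """Shannon entropy (bits) of one alignment column.

    A column containing only ``N`` has no counted characters; its entropy is
    defined as 0 and a warning is emitted.
    """
    if not 0 <= col < rs.alignment_length:
        raise IndexError(f"column {col} out of range [0, {rs.alignment_length})")
    counts = _char_counts(rs.matrix[:, col : col + 1])[:, 0]
    if counts.sum() == 0:
        warnings.warn(f"column {col} contains only N; entropy defined as 0")
        return 0.0
    return float(_entropy_from_counts(counts[:, None])[0])


def entropy_profile(rs: AlignedReadSet) -> np.ndarray:
    """Per-column Shannon entropy (bits) over the whole alignment."""
    if rs.n_reads == 0:
        raise ValueError("cannot compute an entropy profile of an empty read set")
    return _entropy_from_counts(_char_counts(rs.matrix))


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass
class Oligotype:
    """One oligotype: a read group keyed by its base string at the component positions."""

    code: str
    read_indices: np.ndarray
    sample_counts: Counter
    #: unique full-length member sequences as (sequence, count), ordered by
    #: descending count then lexicographically.
    members: list[tuple[str, int]]

    @property
    def total_count(self) -> int:
        return int(sum(self.sample_counts.values()))

    @property
    def substantive_abundance(self) -> int:
        """Count of the most abundant unique member sequence (the M-filter operand)."""
        return self.members[0][1] if self.members else 0


def representative_sequence(o: Oligotype) -> str:
    """Most abundant unique full-length member sequence; ties break lexicographically."""
    if not o.members:
        raise ValueError(f"oligotype {o.code!r} has no member sequences")
    return o.members[0][0]


@dataclass
class OligotypePartition:
    """Assignment of every read to exactly one oligotype or the 'other' bucket."""

    oligotypes: list[Oligotype]
    other_bucket: Counter
    sample_totals: Counter
    positions: list[int]
    min_substantive_abundance: int | None = None

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_totals)

    @property
    def total_reads(self) -> int:
        return int(sum(self.sample_totals.values()))

    @property
    def assigned_reads(self) -> int:
        return int(sum(o.total_count for o in self.oligotypes))

    def assigned_fraction(self) -> float:
        """Fraction of all reads that fall in a retained oligotype."""
        return self.assigned_reads / self.total_reads if self.total_reads else 0.0

    def check_conservation(self) -> None:
        """Per-sample and overall: oligotype counts + other bucket == read totals."""
        acc: Counter = Counter(self.other_bucket)
        for o in self.oligotypes:
            acc.update(o.sample_counts)
        if acc != self.sample_totals:
            raise AssertionError("partition does not conserve per-sample read counts")


def _group_labels(matrix: np.ndarray, positions: Sequence[int]) -> tuple[np.ndarray, int]:
    """Label each read by its base string at ``positions``; returns (labels, n_groups)."""
    n = matrix.shape[0]
    if len(positions) == 0:
        return np.zeros(n, dtype=np.intp), 1 if n else 0
    sub = np.ascontiguousarray(matrix[:, list(positions)])
    keys = sub.view(np.dtype((np.void, sub.shape[1]))).ravel()
    _, labels = np.unique(keys, return_inverse=True)
    return labels.astype(np.intp), int(labels.max()) + 1 if n else 0


def _member_tally(matrix: np.ndarray, idx: np.ndarray) -> list[tuple[str, int]]:
    sub = np.ascontiguousarray(matrix[idx])
    rows = sub.view(np.dtype((np.void, matrix.shape[1]))).ravel()
    uniq, counts = np.unique(rows, return_counts=True)
    pairs = [(u.tobytes().decode("ascii"), int(c)) for u, c in zip(uniq, counts)]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return pairs


def decompose(rs: AlignedReadSet, positions: Sequence[int]) -> OligotypePartition:
    """Group reads by their exact base string at the selected columns.

    With no positions every read falls into a single oligotype with the empty
    code; with all columns selected oligotypes coincide with unique sequences.
    Oligotypes are ordered by descending total count, code as tie-break.
    """
    positions = list(positions)
    for p in positions:
        if not 0 <= p < rs.alignment_length:
            raise IndexError(f"position {p} out of range [0, {rs.alignment_length})")
    sample_totals = Counter(rs.samples)
    if rs.n_reads == 0:
        return OligotypePartition([], Counter(), sample_totals, positions)

    labels, n_groups = _group_labels(rs.matrix, positions)
    samples_arr = np.asarray(rs.samples, dtype=object)
    oligos: list[Oligotype] = []
    for g in range(n_groups):
        idx = np.flatnonzero(labels == g)
        code = rs.matrix[idx[0], positions].tobytes().decode("ascii")
        oligos.append(
            Oligotype(
                code=code,
                read_indices=idx,
                sample_counts=Counter(samples_arr[idx].tolist()),
                members=_member_tally(rs.matrix, idx),
            )
        )
    oligos.sort(key=lambda o: (-o.total_count, o.code))
    part = OligotypePartition(oligos, Counter(), sample_totals, positions)
    part.check_conservation()
    return part


def apply_min_substantive_abundance(p: OligotypePartition, M: int) -> OligotypePartition:
    """Dissolve oligotypes whose most common unique sequence occurs fewer than ``M`` times.

    The dissolved reads move to the 'other' bucket, preserving the per-sample
    conservation invariant.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    retained: list[Oligotype] = []
    other = Counter(p.other_bucket)
    for o in p.oligotypes:
        if o.substantive_abundance >= M:
            retained.append(o)
        else:
            other.update(o.sample_counts)
    out = OligotypePartition(retained, other, Counter(p.sample_totals), list(p.positions), M)
    out.check_conservation()
    return out


# ---------------------------------------------------------------------------
# position selection
# ---------------------------------------------------------------------------

@dataclass
class PositionSet:
    """Ordered component columns plus the per-iteration selection trace."""

    positions: list[int] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)
    epsilon: float = DEFAULT_EPSILON
    max_positions: int = DEFAULT_MAX_POSITIONS

    def __len__(self) -> int:
        return len(self.positions)


def select_positions(
    rs: AlignedReadSet,
    epsilon: float = DEFAULT_EPSILON,
    max_positions: int = DEFAULT_MAX_POSITIONS,
    min_group_size: int = DEFAULT_M,
) -> PositionSet:
    """Greedy entropy-convergence selection of component positions.

    Starting from the globally maximal-entropy column, each iteration
    partitions the reads on the current position set, computes the entropy
    profile within every oligotype, and adds the column with the highest
    within-oligotype entropy, provided that entropy is at least ``epsilon``
    and the column actually refines the partition (a column that leaves the
    partition unchanged carries only redundant information and is excluded
    permanently). Selection stops when no column qualifies — the entropy
    within each oligotype has converged — or when ``max_positions`` is
    reached. A fully monomorphic alignment yields an empty set: the whole
    read set is one oligotype.

    Oligotypes smaller than ``min_group_size`` reads do not contribute
    candidate entropy: such groups sit below the substantive-abundance noise
    floor (they are exactly the groups the M filter later dissolves), and a
    couple of error-bearing reads that happen to share a code would otherwise
    exhibit entropy of a full bit at arbitrary error columns and hijack the
    selection. This mirrors the supervised practice of reading entropy
    profiles only for substantive oligotypes.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if max_positions < 1:
        raise ValueError("max_positions must be >= 1")
    if rs.n_reads == 0:
        raise ValueError("cannot select positions from an empty read set")

    matrix = rs.matrix
    n_cols = rs.alignment_length
    selected: list[int] = []
    excluded = np.zeros(n_cols, dtype=bool)
    trace: list[dict] = []

    labels = np.zeros(rs.n_reads, dtype=np.intp)
    n_groups = 1
    while len(selected) < max_positions:
        counts = np.bincount(labels, minlength=n_groups)
        within = np.zeros(n_cols)
        for g in range(n_groups):
            if counts[g] < min_group_size and counts[g] < rs.n_reads:
                continue
            sub = matrix[labels == g]
            within = np.maximum(within, _entropy_from_counts(_char_counts(sub)))
        candidates = within.copy()
        candidates[selected] = -1.0
        candidates[excluded] = -1.0
        max_before = float(candidates.max()) if candidates.size else 0.0

        picked = -1
        # stable descending sort => ties resolve to the lowest column index
        for col in np.argsort(-candidates, kind="stable"):
            if candidates[col] < epsilon:
                break
            new_labels, new_n = _group_labels(matrix, selected + [int(col)])
            if new_n == n_groups:  # redundant: partition unchanged
                excluded[col] = True
                continue
            picked = int(col)
            labels, n_groups = new_labels, new_n
            break
        if picked < 0:
            break
        selected.append(picked)
        trace.append(
            {
                "iteration": len(selected),
                "position": picked,
                "entropy": float(within[picked]),
                "max_within_entropy_before": max_before,
                "n_oligotypes": int(n_groups),
            }
        )

    # converged within-oligotype entropy after the final pick, for the trace
    if trace:
        counts = np.bincount(labels, minlength=n_groups)
        within = np.zeros(n_cols)
        for g in range(n_groups):
            if counts[g] < min_group_size and counts[g] < rs.n_reads:
                continue
            within = np.maximum(
                within, _entropy_from_counts(_char_counts(matrix[labels == g]))
            )
        rest = np.delete(within, selected)
        trace[-1]["max_within_entropy_after"] = float(rest.max()) if rest.size else 0.0

    return PositionSet(selected, trace, epsilon, max_positions)
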