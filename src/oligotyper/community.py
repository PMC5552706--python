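"""Oligotype-by-sample abundance tables, identity matrices and co-occurrence.

Count tables carry the raw partition counts plus the 'other' bucket (reads
not retained in any oligotype). Two normalisation modes exist: fractions of
the total target-genus reads in a sample (counts + other) or of the total
microbial reads, which must be supplied externally. A sample whose
denominator is zero is *missing*, not zero — it is excluded downstream
rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clades import sequence_distance
from .oligotypes import OligotypePartition

_GAP = ord("-")

#: normalisation mode tags
MODE_COUNTS = "counts"
MODE_TOTAL_MICROBIAL = "total_microbial"
MODE_TOTAL_SYNECHOCOCCUS = "total_synechococcus"


@dataclass
class AbundanceTable:
    """Oligotype x sample matrix with an 'other' row kept separately.

    ``data`` holds counts (mode ``counts``) or fractions (either
    normalisation mode); missing samples are NaN columns after
    normalisation.
    """

    data: pd.DataFrame
    other: pd.Series
    total_synechococcus: pd.Series
    total_microbial: pd.Series | None = None
    mode: str = MODE_COUNTS
    codes: dict[str, str] = field(default_factory=dict)

    @property
    def oligotype_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def count_table(
    p: OligotypePartition,
    samples: Sequence[str] | None = None,
    total_microbial: Mapping[str, int] | None = None,
) -> AbundanceTable:
    """Materialise a partition as an oligotype x sample count matrix.

    Oligotypes are labelled ``O1..On`` in abundance-rank order (the partition
    is already sorted); ``codes`` maps each label back to its position code.
    ``samples`` fixes the column order and may add samples with no reads at
    all (all-zero columns); it must cover every sample present in the
    partition.
    """
    present = set(p.sample_totals)
    if samples is None:
        samples = sorted(present)
    else:
        unknown = present - set(samples)
        if unknown:
            raise ValueError(f"partition contains unlisted sample(s): {sorted(unknown)}")
    samples = list(samples)
    ids = [f"O{i + 1}" for i in range(len(p.oligotypes))]
    data = pd.DataFrame(
        [[o.sample_counts.get(s, 0) for s in samples] for o in p.oligotypes],
        index=ids,
        columns=samples,
        dtype=int,
    )
    other = pd.Series([p.other_bucket.get(s, 0) for s in samples], index=samples, dtype=int)
    totals = data.sum(axis=0) + other
    tm = None
    if total_microbial is not None:
        missing = [s for s in samples if s not in total_microbial]
        if missing:
            raise ValueError(f"total microbial counts missing for sample(s): {missing}")
        tm = pd.Series({s: int(total_microbial[s]) for s in samples})
    return AbundanceTable(
        data=data,
        other=other,
        total_synechococcus=totals,
        total_microbial=tm,
        mode=MODE_COUNTS,
        codes=dict(zip(ids, (o.code for o in p.oligotypes))),
    )


def normalize(t: AbundanceTable, mode: str) -> AbundanceTable:
    """Convert a count table to relative abundances.

    ``total_synechococcus`` divides by per-sample counts + other (fractions
    of the target genus); ``total_microbial`` divides by externally supplied
    per-sample totals. Zero-denominator samples become NaN columns.
    """
    if t.mode != MODE_COUNTS:
        raise ValueError("normalize expects a raw count table")
    if mode == MODE_TOTAL_SYNECHOCOCCUS:
        denom = t.total_synechococcus.astype(float)
    elif mode == MODE_TOTAL_MICROBIAL:
        if t.total_microbial is None:
            raise ValueError("total microbial counts are required for this mode")
        denom = t.total_microbial.astype(float)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    denom = denom.replace(0, np.nan)
    return AbundanceTable(
        data=t.data.div(denom, axis=1),
        other=t.other.div(denom),
        total_synechococcus=t.total_synechococcus,
        total_microbial=t.total_microbial,
        mode=mode,
        codes=dict(t.codes),
    )


def pairwise_identity(
    reps: Mapping[str, str] | Sequence[str],
) -> pd.DataFrame:
    """Symmetric percent-identity matrix of aligned representative sequences.

    Identity = 100 x matches / comparable columns, where columns gapped in
    both sequences are excluded and a single gap counts as a mismatch.
    """
    if isinstance(reps, Mapping):
        ids, seqs = list(reps.keys()), list(reps.values())
    else:
        seqs = list(reps)
        ids = [f"O{i + 1}" for i in range(len(seqs))]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"representatives differ in length: {sorted(lengths)}")
    mats = [np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8) for s in seqs]
    n = len(seqs)
    out = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        a, b = mats[i], mats[j]
        comparable = ~((a == _GAP) & (b == _GAP))
        n_comp = int(comparable.sum())
        if n_comp == 0:
            raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
        matches = int(((a == b) & comparable).sum())
        out[i, j] = out[j, i] = 100.0 * matches / n_comp
    return pd.DataFrame(out, index=ids, columns=ids)


def identity_from_distance(a: str, b: str) -> float:
    """Cross-check form: 100 - 100 * distance / comparable columns."""
    x = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    n_comp = int((~((x == _GAP) & (y == _GAP))).sum())
    return 100.0 - 100.0 * sequence_distance(a, b) / n_comp


def cooccurrence_r2(
    t: AbundanceTable | pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Squared Pearson correlation of relative-abundance series across samples.

    Samples missing either series are dropped pairwise; a pair with fewer
    than ``min_samples`` usable samples, or with a zero-variance series, is
    reported as missing (NaN), never as 0.
    """
    data = t.data if isinstance(t, AbundanceTable) else t
    if pairs is None:
        pairs = list(combinations(data.index, 2))
    rows = []
    for a, b in pairs:
        x = data.loc[a].astype(float)
        y = data.loc[b].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        r2 = np.nan
        if n >= min_samples:
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if np.ptp(xv) > 0 and np.ptp(yv) > 0:
                r = np.corrcoef(xv, yv)[0, 1]
                r2 = float(r * r)
        rows.append({"a": a, "b": b, "r2": r2, "n_samples": n})
    return pd.DataFrame(rows)


def write_identity_tsv(identity: pd.DataFrame, path: str) -> None:
    """Write the identity matrix with 2-decimal reporting."""
    identity.round(2).to_csv(path, sep="\t", float_format="%.2f")
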