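"""Shared fixtures: hand-built read sets and session-scoped scenario runs."""

from __future__ import annotations

import numpy as np
import pytest

from oligotyper import oligotypes as olig
from oligotyper.sequence_io import AlignedReadSet
from oligotyper.simulate import ScenarioConfig, simulate_scenario


def make_reads(
    seqs: list[str],
    samples: list[str] | None = None,
    ids: list[str] | None = None,
) -> AlignedReadSet:
    """Build an AlignedReadSet from plain strings."""
    n = len(seqs)
    samples = samples if samples is not None else ["s1"] * n
    ids = ids if ids is not None else [f"{samples[i]}_r{i}" for i in range(n)]
    length = len(seqs[0]) if seqs else 0
    matrix = (
        np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(n, length).copy()
        if seqs
        else np.empty((0, 0), dtype=np.uint8)
    )
    return AlignedReadSet(matrix=matrix, read_ids=ids, samples=samples)


@pytest.fixture(scope="session")
def noisefree_run():
    """Default study-scale scenario without sequencing error, fully processed."""
    cfg = ScenarioConfig(seed=7, error_rate=0.0)
    rs, truth = simulate_scenario(cfg)
    pos = olig.select_positions(rs)
    part = olig.decompose(rs, pos.positions)
    return cfg, rs, truth, pos, part


@pytest.fixture(scope="session")
def noisy_run():
    """Default study-scale scenario at the study error rate, M-filtered."""
    cfg = ScenarioConfig(seed=7)  # error_rate 0.002
    rs, truth = simulate_scenario(cfg)
    pos = olig.select_positions(rs)
    part = olig.apply_min_substantive_abundance(
        olig.decompose(rs, pos.positions), olig.DEFAULT_M
    )
    return cfg, rs, truth, pos, part
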