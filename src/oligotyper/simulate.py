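"""Ground-truthed synthetic estuarine amplicon time series.

The generator emulates the statistical structure the analysis assumes: a
small set of closely related 16S variants (≈12 variants of length ≈482
sharing >94% identity and differing only at ≈19 informative positions)
sampled at 7 stations on 27 dates across two seasons. Variant relative
abundances respond log-linearly to standardised environmental covariates
through a softmax, producing two successional communities — a cool-water /
high-oxygen group and a warm-water group — plus a handful of rare,
salinity-associated variants, one variant private to a single
spatially-isolated warm station, and one variant tied to no covariate.
Reads are drawn multinomially per sample and carry independent per-base
substitution errors (no indels, so reads stay aligned by construction).

All randomness flows from one explicit seed through a single
``numpy.random.Generator``; identical configurations are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .env_models import add_weekly_precip
from .sequence_io import AlignedReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_STATIONS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")


def default_dates() -> tuple[str, ...]:
    """27 sampling dates over two years: weekly in summer, monthly otherwise."""
    summer_2007 = [f"2007-{m:02d}-{d:02d}" for m, d in (
        (6, 4), (6, 11), (6, 18), (6, 25),
        (7, 2), (7, 9), (7, 16), (7, 23), (7, 30),
        (8, 6), (8, 13), (8, 20), (8, 27), (9, 3),
    )]
    winter = ["2007-10-01", "2007-11-05", "2007-12-03",
              "2008-01-07", "2008-02-04", "2008-03-03", "2008-04-07"]
    summer_2008 = ["2008-05-05", "2008-06-02", "2008-06-30",
                   "2008-07-28", "2008-08-25", "2008-09-22"]
    return tuple(summer_2007 + winter + summer_2008)


def default_coefficients(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant covariate coefficients and baseline log-weights.

    Columns follow ``COVARIATES`` order: temperature, salinity, dissolved
    oxygen, weekly precipitation. The default 12-variant matrix encodes an
    early-summer community (V2, V4, V5: cooler water, more oxygen), a
    late-summer community (V1, V3, V7: warmer water), rare salinity-tracking
    variants (V6, V8, V10, V11), one station-private variant (V9, all-zero
    here; privacy is injected separately) and one covariate-neutral variant
    (V12, weak precipitation response). Baselines set the dominant/rare
    abundance hierarchy.
    """
    if k == 12:
        coeffs = np.array([
            [ 1.2, 0.0, 0.0, 0.0],   # V1  late, dominant
            [-1.2, 0.0, 0.8, 0.0],   # V2  early, dominant
            [ 1.1, 0.0, 0.0, 0.0],   # V3  late
            [-1.0, 0.0, 0.7, 0.0],   # V4  early
            [-0.9, 0.0, 0.6, 0.0],   # V5  early
            [ 0.8, 0.8, 0.0, 0.0],   # V6  rare, late + saline
            [ 1.0, 0.0, 0.0, 0.0],   # V7  late
            [ 0.7, 0.9, 0.0, 0.0],   # V8  rare, saline
            [ 0.0, 0.0, 0.0, 0.0],   # V9  private to one station
            [ 0.6, 0.8, 0.0, 0.0],   # V10 rare, saline
            [ 0.7, 0.7, 0.0, 0.0],   # V11 rare, saline
            [ 0.0, 0.0, 0.0, 0.3],   # V12 no seasonal signal
        ])
        baselines = np.array(
            [1.0, 1.2, 0.8, 0.5, 0.1, -0.7, 0.5, -0.9, 1.5, -0.9, -0.8, -0.3]
        )
        return coeffs, baselines
    # generic fallback: alternate warm/cool responders of tapering abundance
    coeffs = np.zeros((k, 4))
    for i in range(k):
        coeffs[i, 0] = 1.0 if i % 2 == 0 else -1.0
    baselines = np.linspace(1.0, -1.0, k)
    return coeffs, baselines


@dataclass
class ScenarioConfig:
    """Study-scale scenario: what the generator produces and at what rates."""

    k_variants: int = 12
    length: int = 482
    n_positions: int = 19
    stations: tuple[str, ...] = DEFAULT_STATIONS
    dates: tuple[str, ...] = field(default_factory=default_dates)
    reads_per_sample: int = 200
    error_rate: float = 0.002
    background_reads: int = 16000
    seed: int = 0
    # environment model
    temp_mean_c: float = 17.0
    temp_amplitude_c: float = 13.0
    temp_noise_sd: float = 0.8
    station_temp_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"S6": 5.0}
    )
    salinity_means_psu: Mapping[str, float] = field(
        default_factory=lambda: {
            "S1": 31.0, "S2": 28.0, "S3": 28.0, "S4": 12.0,
            "S5": 28.0, "S6": 29.0, "S7": 31.0,
        }
    )
    fresh_station: str = "S4"
    salinity_seasonal_psu: float = 6.0
    do_base: float = 9.5
    do_temp_slope: float = -0.18
    station_do_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 1.0, "S7": 1.0, "S4": -1.5}
    )
    precip_wet_prob: float = 0.3
    precip_mean_mm: float = 8.0
    # abundance model
    coefficients: np.ndarray | None = None
    baselines: np.ndarray | None = None
    private_variant: int | None = 8     # 0-based index; V9 by default
    private_station: str | None = "S6"

    def __post_init__(self) -> None:
        if self.k_variants < 1:
            raise ValueError("k_variants must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        if self.n_positions > self.length:
            raise ValueError("n_positions cannot exceed sequence length")

    def resolved_model(self) -> tuple[np.ndarray, np.ndarray]:
        coeffs, baselines = self.coefficients, self.baselines
        if coeffs is None or baselines is None:
            dc, db = default_coefficients(self.k_variants)
            coeffs = dc if coeffs is None else np.asarray(coeffs, dtype=float)
            baselines = db if baselines is None else np.asarray(baselines, dtype=float)
        coeffs = np.asarray(coeffs, dtype=float)
        baselines = np.asarray(baselines, dtype=float)
        if coeffs.shape != (self.k_variants, 4):
            raise ValueError(
                f"coefficient matrix must be (k_variants, 4), got {coeffs.shape}"
            )
        if baselines.shape != (self.k_variants,):
            raise ValueError("baselines must have one entry per variant")
        return coeffs, baselines


@dataclass
class SyntheticTruth:
    """Everything the generator knows, for downstream recovery checks."""

    variants: list[str]
    variant_ids: list[str]
    positions: list[int]
    coefficients: np.ndarray
    baselines: np.ndarray
    env: pd.DataFrame                 # sample-indexed covariate table
    daily_precip: pd.Series
    abundances: pd.DataFrame          # variants x samples, true softmax fractions
    draws: pd.DataFrame               # variants x samples, realised read counts
    total_microbial: pd.Series
    seed: int


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def generate_variants(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[list[str], list[int]]:
    """Build K variants differing only at the informative positions.

    A random root sequence is drawn; for K-1 <= n_positions the variants get
    a hierarchical structure — every non-root variant carries a private
    substitution at its own position, and the second half of the variants
    additionally shares substitutions at the leftover "marker" positions
    (mimicking a clade-like split, and giving the position selector genuinely
    redundant columns to reject). Otherwise each variant receives a distinct
    random base string at the positions. All pairs are checked distinct.
    """
    k, n_pos = cfg.k_variants, cfg.n_positions
    if k > 4 ** max(n_pos, 1) and k > 1:
        raise ValueError(
            f"{k} variants are not distinguishable at {n_pos} positions"
        )
    root = _BASES[rng.integers(0, 4, size=cfg.length)].copy()
    positions = sorted(rng.choice(cfg.length, size=n_pos, replace=False).tolist())

    def substitute(mat_row: np.ndarray, pos: int) -> None:
        alt = _BASES[_BASES != mat_row[pos]]
        mat_row[pos] = rng.choice(alt)

    variants = np.tile(root, (k, 1))
    if k - 1 <= n_pos:
        for i in range(1, k):
            substitute(variants[i], positions[i - 1])
        markers = positions[k - 1:]
        late = range(k // 2, k)  # shared-marker half
        for m in markers:
            alt = _BASES[_BASES != root[m]]
            base = rng.choice(alt)
            for i in late:
                variants[i, m] = base
    else:
        seen = set()
        for i in range(k):
            while True:
                code = _BASES[rng.integers(0, 4, size=n_pos)]
                key = code.tobytes()
                if key not in seen:
                    seen.add(key)
                    break
            variants[i, positions] = code
    seqs = [v.tobytes().decode("ascii") for v in variants]
    if len(set(seqs)) != k:
        raise ValueError("variant construction produced duplicates")
    return seqs, positions


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def generate_env(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Station x date covariate table plus the regional daily-precipitation series.

    Temperature is a seasonal sinusoid (peak in late July) plus a station
    offset; salinity has station-specific means with a strong seasonal swing
    only at the freshwater end-member; dissolved oxygen declines with
    temperature (solubility) with coastal/fresh offsets; daily precipitation
    is intermittent exponential rain shared by all stations.
    """
    dates = pd.to_datetime(list(cfg.dates))
    start = dates.min() - pd.Timedelta(days=6)
    all_days = pd.date_range(start, dates.max(), freq="D")
    wet = rng.random(all_days.size) < cfg.precip_wet_prob
    daily = pd.Series(
        np.where(wet, rng.exponential(cfg.precip_mean_mm, all_days.size), 0.0),
        index=all_days,
        name="precip_mm",
    )

    rows = []
    for station in cfg.stations:
        t_off = cfg.station_temp_offsets.get(station, 0.0)
        s_mean = cfg.salinity_means_psu.get(station, 28.0)
        d_off = cfg.station_do_offsets.get(station, 0.0)
        for date in dates:
            doy = date.dayofyear
            seas = np.sin(2.0 * np.pi * (doy - 110.0) / 365.25)
            temp = (
                cfg.temp_mean_c + cfg.temp_amplitude_c * seas + t_off
                + rng.normal(0.0, cfg.temp_noise_sd)
            )
            sal = s_mean + rng.normal(0.0, 0.5)
            if station == cfg.fresh_station:
                sal += cfg.salinity_seasonal_psu * seas
            do = (
                cfg.do_base + cfg.do_temp_slope * (temp - cfg.temp_mean_c) + d_off
                + rng.normal(0.0, 0.4)
            )
            rows.append(
                {
                    "sample_id": f"{station}_{date:%Y%m%d}",
                    "station": station,
                    "date": date,
                    "temp_c": temp,
                    "salinity_psu": max(sal, 0.0),
                    "dissolved_oxygen": max(do, 0.0),
                }
            )
    env = pd.DataFrame(rows).set_index("sample_id")
    env = add_weekly_precip(env, daily)
    return env, daily


# ---------------------------------------------------------------------------
# abundances and reads
# ---------------------------------------------------------------------------

def generate_abundances(
    env: pd.DataFrame,
    coeffs: np.ndarray,
    baselines: np.ndarray | None = None,
    private_variant: int | None = None,
    private_station: str | None = None,
) -> pd.DataFrame:
    """True relative abundances: softmax of baseline + coeffs @ standardised covariates.

    Returns a variants x samples table whose columns each sum to 1. A sample
    missing any covariate is marked missing (all-NaN column). If a private
    variant is configured, its abundance is zeroed outside its station and
    the column renormalised.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    k = coeffs.shape[0]
    baselines = np.zeros(k) if baselines is None else np.asarray(baselines, dtype=float)
    covs = ["temp_c", "salinity_psu", "dissolved_oxygen", "weekly_precip"]
    X = env.loc[:, covs].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    Z = np.full_like(X, np.nan)
    mu = X[ok].mean(axis=0)
    sd = X[ok].std(axis=0)
    sd[sd == 0] = 1.0
    Z[ok] = (X[ok] - mu) / sd

    scores = baselines[None, :] + Z @ coeffs.T          # samples x variants
    shift = np.zeros(scores.shape[0])
    if ok.any():
        shift[ok] = scores[ok].max(axis=1)
    w = np.exp(scores - shift[:, None])
    if private_variant is not None:
        if private_station is None:
            raise ValueError("private_variant requires private_station")
        away = (env["station"] != private_station).to_numpy()
        w[away, private_variant] = 0.0
    abund = w / w.sum(axis=1, keepdims=True)
    ids = [f"V{i + 1}" for i in range(k)]
    return pd.DataFrame(abund.T, index=ids, columns=env.index)


def simulate_reads(
    variants: Sequence[str],
    abundances: pd.DataFrame,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[AlignedReadSet, pd.DataFrame]:
    """Draw reads multinomially per sample and apply per-base substitution errors.

    Each read copies its source variant, then every base independently
    mutates with probability ``error_rate``, uniformly over the three
    alternative bases. Missing samples (NaN abundance) yield zero reads.
    Returns the read set and the realised per-sample variant draws.
    """
    k = len(variants)
    var_matrix = np.stack(
        [np.frombuffer(v.encode("ascii"), dtype=np.uint8) for v in variants]
    )
    length = var_matrix.shape[1]
    draws = pd.DataFrame(
        0, index=list(abundances.index), columns=list(abundances.columns), dtype=int
    )
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    samples: list[str] = []
    for sample in abundances.columns:
        p = abundances[sample].to_numpy(dtype=float)
        if np.isnan(p).any() or cfg.reads_per_sample == 0:
            continue
        counts = rng.multinomial(cfg.reads_per_sample, p)
        draws[sample] = counts
        assign = np.repeat(np.arange(k), counts)
        block = var_matrix[assign].copy()
        if cfg.error_rate > 0:
            err = rng.random(block.shape) < cfg.error_rate
            if err.any():
                idx = np.searchsorted(np.sort(_BASES), block[err])
                # original bases are ACGT in sorted order already
                shift = rng.integers(1, 4, size=int(err.sum()))
                block[err] = np.sort(_BASES)[(idx + shift) % 4]
        blocks.append(block)
        ids.extend(f"{sample}_{i:04d}" for i in range(cfg.reads_per_sample))
        samples.extend([sample] * cfg.reads_per_sample)
    matrix = (
        np.concatenate(blocks, axis=0)
        if blocks
        else np.empty((0, length), dtype=np.uint8)
    )
    rs = AlignedReadSet(matrix=matrix, read_ids=ids, samples=samples)
    return rs, draws


def simulate_scenario(cfg: ScenarioConfig) -> tuple[AlignedReadSet, SyntheticTruth]:
    """Run the full generator: variants, environment, abundances, reads."""
    rng = np.random.default_rng(cfg.seed)
    coeffs, baselines = cfg.resolved_model()
    variants, positions = generate_variants(cfg, rng)
    env, daily = generate_env(cfg, rng)
    abund = generate_abundances(
        env, coeffs, baselines,
        private_variant=cfg.private_variant,
        private_station=cfg.private_station,
    )
    rs, draws = simulate_reads(variants, abund, cfg, rng)
    totals = pd.Series(
        {s: cfg.reads_per_sample + cfg.background_reads for s in env.index},
        name="total_microbial",
    )
    truth = SyntheticTruth(
        variants=list(variants),
        variant_ids=[f"V{i + 1}" for i in range(cfg.k_variants)],
        positions=positions,
        coefficients=coeffs,
        baselines=baselines,
        env=env,
        daily_precip=daily,
        abundances=abund,
        draws=draws,
        total_microbial=totals,
        seed=cfg.seed,
    )
    return rs, truth


def variant_code(variant: str, positions: Sequence[int]) -> str:
    """Base string of a variant at the given positions (links truth to oligotype codes)."""
    return "".join(variant[p] for p in positions)
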