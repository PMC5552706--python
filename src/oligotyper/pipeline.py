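"""End-to-end run orchestration: prep -> oligotype -> clades -> community -> envstats.

A run is driven by a single validated :class:`RunConfig` (usually loaded
from YAML); every interchange file is written under one output directory
and a ``manifest.json`` records parameters, input checksums and per-stage
record counts, so any output is re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import clades as clade_mod
from . import community as comm
from . import env_models as envm
from . import oligotypes as olig
from . import sequence_io as seqio

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    reads: str = ""
    out_dir: str = "oligotyper_out"
    reference_db: str | None = None
    env_table: str | None = None
    daily_precip: str | None = None
    totals: str | None = None
    groups: str | None = None
    sample_sep: str = "_"
    sample_regex: str | None = None
    max_gap_fraction: float = 0.99
    epsilon: float = olig.DEFAULT_EPSILON
    max_positions: int = olig.DEFAULT_MAX_POSITIONS
    min_substantive_abundance: int = olig.DEFAULT_M
    positions: list[int] | None = None
    normalization: str = comm.MODE_TOTAL_SYNECHOCOCCUS
    n_pcs: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError([f"unknown config key(s): {sorted(unknown)}"])
        return cls(**raw)


def validate_config(cfg: RunConfig) -> RunConfig:
    """Check paths, ranges and cross-field constraints; echo resolved defaults."""
    problems: list[str] = []
    if not cfg.reads:
        problems.append("reads: input FASTA path is required")
    elif not Path(cfg.reads).exists():
        problems.append(f"reads: no such file {cfg.reads!r}")
    for name in ("reference_db", "env_table", "daily_precip", "totals", "groups"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name}: no such file {p!r}")
    if not 0.0 <= cfg.max_gap_fraction <= 1.0:
        problems.append("max_gap_fraction must be in [0, 1]")
    if cfg.epsilon <= 0:
        problems.append("epsilon must be > 0")
    if cfg.max_positions < 1:
        problems.append("max_positions must be >= 1")
    if cfg.min_substantive_abundance < 1:
        problems.append("min_substantive_abundance (M) must be >= 1")
    if cfg.normalization not in (comm.MODE_TOTAL_SYNECHOCOCCUS, comm.MODE_TOTAL_MICROBIAL):
        problems.append(f"unknown normalization mode {cfg.normalization!r}")
    if cfg.normalization == comm.MODE_TOTAL_MICROBIAL and cfg.totals is None:
        problems.append("normalization=total_microbial requires a totals table")
    if cfg.env_table is not None and cfg.daily_precip is None:
        problems.append("env_table requires a daily_precip series for weekly precipitation")
    if cfg.n_pcs < 2:
        problems.append("n_pcs must be >= 2")
    if problems:
        raise ConfigError(problems)
    logger.info(
        "config: M=%d, epsilon=%.3g, max_positions=%d, max_gap_fraction=%.3g, "
        "normalization=%s",
        cfg.min_substantive_abundance, cfg.epsilon, cfg.max_positions,
        cfg.max_gap_fraction, cfg.normalization,
    )
    return cfg


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in order; returns the manifest."""
    validate_config(cfg)
    out = Path(cfg.out_dir)
    manifest: dict = {
        "parameters": asdict(cfg),
        "inputs": {
            name: {"path": p, "md5": _md5(p)}
            for name, p in (
                ("reads", cfg.reads),
                ("reference_db", cfg.reference_db),
                ("env_table", cfg.env_table),
                ("daily_precip", cfg.daily_precip),
                ("totals", cfg.totals),
                ("groups", cfg.groups),
            )
            if p is not None
        },
        "stages": {},
        "outputs": {},
    }

    def _stage(name):
        (out / name).mkdir(parents=True, exist_ok=True)
        return out / name

    # ---- prep -------------------------------------------------------------
    try:
        d = _stage("prep")
        rs = seqio.read_aligned_fasta(cfg.reads, cfg.sample_sep, cfg.sample_regex)
        rs = seqio.trim_gap_columns(rs, cfg.max_gap_fraction)
        seqio.write_aligned_fasta(rs, d / "trimmed.fna")
        manifest["stages"]["prep"] = {
            "n_reads": rs.n_reads,
            "n_samples": len(rs.sample_counts),
            "n_columns": rs.alignment_length,
        }
        manifest["outputs"]["trimmed_fasta"] = str(d / "trimmed.fna")
    except Exception as exc:  # noqa: BLE001
        raise StageError("prep", exc) from exc

    # ---- oligotype --------------------------------------------------------
    try:
        d = _stage("oligotypes")
        profile = olig.entropy_profile(rs)
        pd.DataFrame(
            {"column": rs.column_map + 1, "entropy_bits": profile}
        ).to_csv(d / "entropy_profile.tsv", sep="\t", index=False)
        if cfg.positions is not None:
            positions = list(cfg.positions)
            trace: list[dict] = []
        else:
            pos_set = olig.select_positions(rs, cfg.epsilon, cfg.max_positions)
            positions, trace = pos_set.positions, pos_set.trace
        with open(d / "selection_trace.json", "w") as fh:
            json.dump(
                {
                    "positions_1based_original": [
                        int(rs.column_map[p]) + 1 for p in positions
                    ],
                    "trace": trace,
                },
                fh,
                indent=2,
            )
        raw = olig.decompose(rs, positions)
        part = olig.apply_min_substantive_abundance(raw, cfg.min_substantive_abundance)
        part.check_conservation()
        reps = {
            f"O{i + 1}": olig.representative_sequence(o)
            for i, o in enumerate(part.oligotypes)
        }
        with open(d / "representatives.fna", "w") as fh:
            for i, o in enumerate(part.oligotypes):
                fh.write(f">O{i + 1}|code={o.code}\n{reps[f'O{i + 1}']}\n")
        manifest["stages"]["oligotype"] = {
            "positions": positions,
            "n_oligotypes_prefilter": len(raw.oligotypes),
            "n_oligotypes": len(part.oligotypes),
            "assigned_read_fraction": part.assigned_fraction(),
            "conservation_ok": True,
        }
        manifest["outputs"]["representatives"] = str(d / "representatives.fna")
    except Exception as exc:  # noqa: BLE001
        raise StageError("oligotype", exc) from exc

    # ---- community --------------------------------------------------------
    try:
        d = _stage("community")
        total_microbial = None
        if cfg.totals is not None:
            tm = pd.read_csv(cfg.totals, sep="\t", index_col=0).iloc[:, 0]
            total_microbial = tm.to_dict()
        table = comm.count_table(part, total_microbial=total_microbial)
        table.data.to_csv(d / "counts.tsv", sep="\t")
        rel = comm.normalize(table, comm.MODE_TOTAL_SYNECHOCOCCUS)
        rel.data.to_csv(d / "relabund_synechococcus.tsv", sep="\t")
        if total_microbial is not None:
            comm.normalize(table, comm.MODE_TOTAL_MICROBIAL).data.to_csv(
                d / "relabund_microbial.tsv", sep="\t"
            )
        if len(reps) >= 2:
            identity = comm.pairwise_identity(reps)
            comm.write_identity_tsv(identity, str(d / "identity.tsv"))
            comm.cooccurrence_r2(rel).to_csv(d / "cooccurrence_r2.tsv", sep="\t", index=False)
        manifest["stages"]["community"] = {
            "n_samples": len(table.sample_ids),
            "normalization_modes": ["total_synechococcus"]
            + (["total_microbial"] if total_microbial else []),
        }
        manifest["outputs"]["counts"] = str(d / "counts.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("community", exc) from exc

    # ---- clades -----------------------------------------------------------
    if cfg.reference_db is not None:
        try:
            d = _stage("clades")
            db = clade_mod.load_reference_db(cfg.reference_db)
            rows = []
            for oid, rep in reps.items():
                a = clade_mod.assign_clade(rep, db, oligotype=oid)
                rows.append(
                    {
                        "oligotype": oid,
                        "clades": a.label,
                        "distance_bp": a.distance,
                        "matched": ",".join(a.matched_ids),
                    }
                )
            pd.DataFrame(rows).to_csv(d / "clades.tsv", sep="\t", index=False)
            manifest["stages"]["clades"] = {"n_assigned": len(rows)}
            manifest["outputs"]["clades"] = str(d / "clades.tsv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("clades", exc) from exc

    # ---- envstats ---------------------------------------------------------
    if cfg.env_table is not None:
        try:
            d = _stage("envstats")
            env = pd.read_csv(cfg.env_table, index_col=0, parse_dates=["date"])
            daily = pd.read_csv(
                cfg.daily_precip, index_col=0, parse_dates=True
            ).iloc[:, 0]
            if "weekly_precip" not in env.columns:
                env = envm.add_weekly_precip(env, daily)
            r = envm.pca(rel.data.T)
            r.scores.to_csv(d / "pca_scores.tsv", sep="\t")
            r.loadings.to_csv(d / "pca_loadings.tsv", sep="\t")
            pd.Series(
                r.explained_variance_ratio,
                index=r.scores.columns,
                name="variance_fraction",
            ).to_csv(d / "pca_variance.tsv", sep="\t")
            coords = envm.project_oligotypes(r)
            coords.to_csv(d / "oligotype_projection.tsv", sep="\t")
            env_stats: dict = {
                "n_pca_samples": int(r.scores.shape[0]),
                "variance_fractions": [float(v) for v in r.explained_variance_ratio[: cfg.n_pcs]],
            }
            selections = envm.best_subsets_for_pcs(r, env, n_pcs=cfg.n_pcs)
            for pc, sel in selections.items():
                tab = sel.table.copy()
                tab["subset"] = tab["subset"].apply(lambda s: "+".join(s) or "(intercept)")
                tab.drop(columns="coefficients").to_csv(
                    d / f"bic_{pc}.tsv", sep="\t", index=False
                )
            env_stats["selected_subsets"] = {
                pc: list(sel.selected) for pc, sel in selections.items()
            }
            if cfg.groups is not None:
                groups = (
                    pd.read_csv(cfg.groups, sep="\t", index_col=0).iloc[:, 0].to_dict()
                )
                dist = envm.group_centroid_distance(coords, groups)
                dist.to_csv(d / "centroid_distances.tsv", sep="\t")
                env_stats["group_labels"] = sorted(set(groups.values()))
            manifest["stages"]["envstats"] = env_stats
            manifest["outputs"]["pca_scores"] = str(d / "pca_scores.tsv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("envstats", exc) from exc

    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
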