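"""End-to-end analysis: sessions + gaze -> bias events -> cohort reports.

Thin orchestration over the other modules; the CLI wraps this.  Every output
bundle carries a run-metadata record (config hash, seed, software versions,
record counts per stage) so results are auditable and re-runs idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import ConfigurationError, DataError
from .gaze import Fixation, read_gaze_csv
from .growth import GrowthStandard, load_standard
from .session import BiasEvent, ScanSession, detect_bias_events, episode_fixations, read_sessions
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    adjusted_models,
    before_after_tests,
    build_deviation_records,
    efw_impact,
    incidence_table,
    repeat_comparison,
)

log = logging.getLogger("scanbias")


@dataclass
class RunConfig:
    """One config drives the whole pipeline (input paths or a simulate block)."""

    event_log: str | None = None
    metadata: str | None = None
    gaze_dir: str | None = None
    simulate: SimulationConfig | None = None
    standard: str = "hadlock"
    min_fixation_ms: float = 100.0
    merge_gap_ms: float = 400.0
    unchanged_tol_days: float = 0.25
    discordance_denominator: str = "max"
    out_dir: str = "scanbias_out"
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        has_paths = self.event_log is not None and self.metadata is not None
        if not has_paths and self.simulate is None:
            raise ConfigurationError("RunConfig needs input paths or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=SimulationConfig(**sim) if sim else None, **raw)
        return cfg

    def to_jsonable(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _versions() -> dict:
    import numpy, pandas, scipy, statsmodels  # noqa: E401

    return {
        "scanbias": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }


def compute_bias_events(
    sessions: Sequence[ScanSession],
    gaze_streams: Mapping[str, pd.DataFrame],
    std: GrowthStandard,
    min_fixation_ms: float = 100.0,
    merge_gap_ms: float = 400.0,
) -> list[BiasEvent]:
    """Fixation detection per episode AOI, then bias-event extraction."""
    events: list[BiasEvent] = []
    for s in sessions:
        stream = gaze_streams.get(s.scan_id)
        if stream is None:
            raise DataError(f"no gaze stream for scan {s.scan_id}")
        per_episode = [
            episode_fixations(
                ep, stream, min_fixation_ms=min_fixation_ms, merge_gap_ms=merge_gap_ms
            )
            for ep in s.episodes
        ]
        events.extend(detect_bias_events(s, per_episode, std))
    return events


def compute_bias_events_scripted(
    sessions: Sequence[ScanSession],
    scripted: Mapping[str, Sequence[Sequence[Fixation]]],
    std: GrowthStandard,
) -> list[BiasEvent]:
    """Bias events from pre-computed per-episode fixations (no raw gaze pass)."""
    events: list[BiasEvent] = []
    for s in sessions:
        events.extend(detect_bias_events(s, list(scripted[s.scan_id]), std))
    return events


@dataclass
class AnalysisResult:
    records: pd.DataFrame
    cohort_table: pd.DataFrame
    tests: dict
    scan_summaries: pd.DataFrame
    efw_cohort: dict
    metadata: dict


def analyze_sessions(
    sessions: Sequence[ScanSession],
    bias_events: Sequence[BiasEvent],
    std: GrowthStandard,
    unchanged_tol_days: float = 0.25,
    discordance_denominator: str = "max",
    run_meta: dict | None = None,
) -> AnalysisResult:
    records = build_deviation_records(
        sessions, bias_events, std, unchanged_tol_days=unchanged_tol_days
    )
    log.info("stage=records in=%d sessions out=%d records", len(sessions), len(records))
    table = incidence_table(records, n_scans=len(sessions))
    tests = {
        "before_after": before_after_tests(records),
        "repeat_comparison": repeat_comparison(records),
        "multiple_testing_correction": "none (per-comparison reporting)",
    }
    try:
        tests["adjusted_models"] = adjusted_models(records)
    except DataError as exc:
        tests["adjusted_models"] = {"error": str(exc)}
    summaries, efw_cohort = efw_impact(
        sessions, bias_events, std, discordance_denominator=discordance_denominator
    )
    log.info(
        "stage=efw_impact in=%d sessions out=%d summaries excluded=%d",
        len(sessions), len(summaries), efw_cohort["n_scans_excluded"],
    )
    meta = dict(run_meta or {})
    meta.setdefault("versions", _versions())
    meta["n_sessions"] = len(sessions)
    meta["n_bias_events"] = len(bias_events)
    meta["n_records"] = len(records)
    return AnalysisResult(
        records=records,
        cohort_table=table,
        tests=tests,
        scan_summaries=summaries,
        efw_cohort=efw_cohort,
        metadata=meta,
    )


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_bundle(result: AnalysisResult, out_dir: str | Path) -> None:
    """Write cohort_summary.csv, scan_summaries.csv, tests.json, run_meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cohort_table.to_csv(out / "cohort_summary.csv")
    result.scan_summaries.to_csv(out / "scan_summaries.csv", index=False)
    result.records.to_csv(out / "deviation_records.csv", index=False)
    tests = dict(result.tests)
    tests["efw_impact"] = result.efw_cohort
    with open(out / "tests.json", "w") as fh:
        json.dump(_round_floats(tests), fh, indent=2, default=str)
    with open(out / "run_meta.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, default=str)


def make_figures(result: AnalysisResult, out_dir: str | Path) -> list[Path]:
    """Distribution plots: deviations before/after bias, repeated vs not."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .growth import PLANES

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    rec = result.records

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5), sharey=True)
    for ax, plane in zip(axes, PLANES):
        sub = rec[(rec["plane"] == plane) & rec["biased"]]
        if len(sub):
            ax.boxplot(
                [sub["d_before"].dropna(), sub["d_after"].dropna()],
                tick_labels=["first look", "saved"],
            )
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_title(plane)
    axes[0].set_ylabel("observed - expected GA (days)")
    fig.suptitle("Deviation from expected GA before and after bias")
    fig.tight_layout()
    p = out / "deviation_before_after.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5), sharey=True)
    for ax, plane in zip(axes, PLANES):
        sub = rec[rec["plane"] == plane]
        groups = [
            sub.loc[sub["is_repeat"], "abs_d_after"],
            sub.loc[~sub["is_repeat"], "abs_d_after"],
        ]
        ax.boxplot(groups, tick_labels=["repeated", "not repeated"])
        ax.set_title(plane)
    axes[0].set_ylabel("|observed - expected GA| (days)")
    fig.suptitle("Deviation for repeated vs non-repeated measurements")
    fig.tight_layout()
    p = out / "deviation_repeats.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written


def run_pipeline(cfg: RunConfig) -> AnalysisResult:
    """Execute the configured pipeline and write the output bundle."""
    std = load_standard(cfg.standard)
    run_meta = {
        "config": cfg.to_jsonable(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": _versions(),
    }
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        cohort = simulate_cohort(sim_cfg, std)
        sessions = cohort.sessions
        events = compute_bias_events(
            sessions, cohort.gaze_streams, std,
            min_fixation_ms=cfg.min_fixation_ms, merge_gap_ms=cfg.merge_gap_ms,
        )
        run_meta["simulation_config_hash"] = sim_cfg.config_hash()
    else:
        sessions = read_sessions(cfg.event_log, cfg.metadata)
        if not sessions:
            raise DataError(f"no sessions found in {cfg.event_log} / {cfg.metadata}")
        gaze_dir = Path(cfg.gaze_dir or ".")
        streams = {}
        for s in sessions:
            path = gaze_dir / f"{s.scan_id}.csv"
            if not path.exists():
                raise DataError(f"missing gaze stream {path}")
            streams[s.scan_id] = read_gaze_csv(path)
        events = compute_bias_events(
            sessions, streams, std,
            min_fixation_ms=cfg.min_fixation_ms, merge_gap_ms=cfg.merge_gap_ms,
        )
    result = analyze_sessions(
        sessions,
        events,
        std,
        unchanged_tol_days=cfg.unchanged_tol_days,
        discordance_denominator=cfg.discordance_denominator,
        run_meta=run_meta,
    )
    write_bundle(result, cfg.out_dir)
    if cfg.make_figures:
        make_figures(result, cfg.out_dir)
    return result
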