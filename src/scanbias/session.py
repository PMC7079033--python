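"""Scan-session event model and expected-value-bias event logic.

A :class:`ScanSession` holds one growth scan: the expected gestational age E
(days, from the due date set at the dating scan), operator covariates, and a
time-ordered list of :class:`MeasurementEpisode` — one per caliper-measurement
attempt, each carrying the measurement-box AOI, the timestamped caliper value
trajectory and the save event.

A measurement is *biased* when the operator fixates on the measurement box at
any point during caliper adjustment — operationalised as the interval
[t_box_appear, t_save) — before saving.  The first qualifying fixation defines
the "before" value (the caliper value in force when the operator first looked);
the saved value defines "after".  Deviations from E of the observed GA implied
by those two values classify the adjustment as toward / away / unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError, InputError
from .gaze import AOI, Fixation, detect_fixations, fixations_in_window
from .growth import GrowthStandard, PLANES

TOWARD, AWAY, UNCHANGED, UNBIASED = "toward", "away", "unchanged", "unbiased"

#: default GA window (days) considered plausible for a growth scan
DEFAULT_SCAN_GA_WINDOW = (154.0, 301.0)


@dataclass(frozen=True)
class MeasurementEpisode:
    """One caliper-measurement attempt on a standard biometric plane."""

    plane: str
    box_aoi: AOI
    trajectory: tuple[tuple[float, float], ...]  # (t_ms, value_mm), time-sorted
    t_save: float

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise DataError(f"unknown plane {self.plane!r}")
        if not self.trajectory:
            raise DataError(f"episode ({self.plane}) has an empty value trajectory")
        ts = [t for t, _ in self.trajectory]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise DataError(f"episode ({self.plane}) trajectory not time-sorted")
        if ts[0] < self.t_box_appear - 1e-9 or ts[-1] > self.t_save + 1e-9:
            raise DataError(
                f"episode ({self.plane}) trajectory times outside "
                f"[{self.t_box_appear}, {self.t_save}]"
            )

    @property
    def t_box_appear(self) -> float:
        return self.box_aoi.t_start

    @property
    def saved_value(self) -> float:
        return self.trajectory[-1][1]

    @property
    def initial_value(self) -> float:
        """Caliper value at initial (automatic) placement."""
        return self.trajectory[0][1]

    def value_at(self, t_ms: float) -> float:
        """Caliper value in force at time t (step function over the trajectory).

        Before the first trajectory point the initial value is in force.
        """
        v = self.trajectory[0][1]
        for t, value in self.trajectory:
            if t <= t_ms:
                v = value
            else:
                break
        return v


@dataclass(frozen=True)
class ScanSession:
    scan_id: str
    operator_id: str
    expected_ga_days: float
    maternal_bmi: float
    operator_experience_years: float
    episodes: tuple[MeasurementEpisode, ...]

    def __post_init__(self) -> None:
        saves = [e.t_save for e in self.episodes]
        if any(b < a for a, b in zip(saves, saves[1:])):
            raise DataError(f"scan {self.scan_id}: episodes not time-ordered by save")

    def validate_ga_window(self, window: tuple[float, float] = DEFAULT_SCAN_GA_WINDOW) -> None:
        lo, hi = window
        if not (lo <= self.expected_ga_days <= hi):
            raise DataError(
                f"scan {self.scan_id}: expected GA {self.expected_ga_days} d outside "
                f"plausible window [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class BiasEvent:
    """First-look / saved value pair establishing a biased measurement."""

    scan_id: str
    episode_index: int
    plane: str
    t_first_look: float
    value_at_first_look: float
    saved_value: float
    observed_ga_at_first_look: float
    observed_ga_saved: float
    first_look_oor: bool
    saved_oor: bool
    n_looks: int


@dataclass(frozen=True)
class AdjustmentResult:
    """Adjustment class plus signed magnitude (days toward the expected GA)."""

    adjustment_class: str  # toward | away | unchanged | unbiased
    adjustment_days: float  # |d_before| - |d_after|; positive = toward; 0 if unbiased
    d_before: float | None
    d_after: float


# ---------------------------------------------------------------------------
# bias-event detection


def episode_fixations(episode: MeasurementEpisode, gaze_stream, **kwargs) -> list[Fixation]:
    """Fixations on one episode's measurement box during caliper adjustment."""
    fixes = detect_fixations(gaze_stream, episode.box_aoi, **kwargs)
    return fixations_in_window(fixes, episode.t_box_appear, episode.t_save)


def detect_bias_events(
    session: ScanSession,
    fixations_per_episode: Sequence[Sequence[Fixation]],
    std: GrowthStandard,
) -> list[BiasEvent]:
    """One :class:`BiasEvent` per episode with a qualifying box fixation.

    A fixation qualifies if it overlaps [t_box_appear, t_save) and starts
    strictly before the save.  ``value_at_first_look`` is the trajectory value
    in force at the start of the first qualifying fixation (a fixation that
    began before the box appeared counts from the box-appearance time).
    Episodes with no qualifying fixation yield no event: the measurement is
    unbiased.
    """
    if len(fixations_per_episode) != len(session.episodes):
        raise InputError(
            f"scan {session.scan_id}: got fixations for {len(fixations_per_episode)} "
            f"episodes, session has {len(session.episodes)}"
        )
    events: list[BiasEvent] = []
    for idx, (ep, fixes) in enumerate(zip(session.episodes, fixations_per_episode)):
        qualifying = [
            f
            for f in fixations_in_window(list(fixes), ep.t_box_appear, ep.t_save)
            if f.t_start < ep.t_save
        ]
        if not qualifying:
            continue
        first = min(qualifying, key=lambda f: f.t_start)
        t_look = max(first.t_start, ep.t_box_appear)
        v_look = ep.value_at(t_look)
        o_look = std.ga_from_measurement(ep.plane, v_look)
        o_saved = std.ga_from_measurement(ep.plane, ep.saved_value)
        events.append(
            BiasEvent(
                scan_id=session.scan_id,
                episode_index=idx,
                plane=ep.plane,
                t_first_look=t_look,
                value_at_first_look=v_look,
                saved_value=ep.saved_value,
                observed_ga_at_first_look=o_look.ga_days,
                observed_ga_saved=o_saved.ga_days,
                first_look_oor=o_look.out_of_range,
                saved_oor=o_saved.out_of_range,
                n_looks=len(qualifying),
            )
        )
    return events


def detect_bias_events_from_gaze(
    session: ScanSession,
    gaze_stream,
    std: GrowthStandard,
    min_fixation_ms: float = 100.0,
    merge_gap_ms: float = 400.0,
) -> list[BiasEvent]:
    """Convenience wrapper: run fixation detection per episode, then detect events."""
    per_episode = [
        episode_fixations(
            ep, gaze_stream, min_fixation_ms=min_fixation_ms, merge_gap_ms=merge_gap_ms
        )
        for ep in session.episodes
    ]
    return detect_bias_events(session, per_episode, std)


# ---------------------------------------------------------------------------
# adjustment classification


def classify_adjustment(
    event: BiasEvent | None,
    expected_ga_days: float,
    std: GrowthStandard,
    saved_value: float | None = None,
    plane: str | None = None,
    unchanged_tol_days: float = 0.25,
) -> AdjustmentResult:
    """Classify a saved measurement as toward / away / unchanged / unbiased.

    With d_before = O(first look) - E and d_after = O(saved) - E (days,
    signed), the class is *toward* iff |d_after| < |d_before|, *away* iff
    |d_after| > |d_before|, *unchanged* when they agree within
    ``unchanged_tol_days`` (absorbs the weeks+days display rounding).  A
    measurement with no bias event is *unbiased*; its (plane, saved_value)
    must then be supplied to compute d_after.
    """
    if event is None:
        if saved_value is None or plane is None:
            raise DataError("unbiased measurement needs plane and saved_value for d_after")
        d_after = std.ga_from_measurement(plane, saved_value).ga_days - expected_ga_days
        return AdjustmentResult(UNBIASED, 0.0, None, d_after)
    d_before = event.observed_ga_at_first_look - expected_ga_days
    d_after = event.observed_ga_saved - expected_ga_days
    adj = abs(d_before) - abs(d_after)
    if abs(adj) <= unchanged_tol_days:
        cls = UNCHANGED
    elif adj > 0:
        cls = TOWARD
    else:
        cls = AWAY
    return AdjustmentResult(cls, adj, d_before, d_after)


# ---------------------------------------------------------------------------
# repeats and candidate values


def group_repeats(session: ScanSession) -> list[bool]:
    """Per-episode ``is_repeat`` flags, aligned with ``session.episodes``.

    Within a scan, the first saved measurement of a plane (by save time) is
    the original; every later saved measurement of the same plane is a repeat.
    """
    order = sorted(range(len(session.episodes)), key=lambda i: session.episodes[i].t_save)
    seen: set[str] = set()
    flags = [False] * len(session.episodes)
    for i in order:
        plane = session.episodes[i].plane
        flags[i] = plane in seen
        seen.add(plane)
    return flags


def count_repeats(session: ScanSession) -> int:
    return sum(group_repeats(session))


def candidate_values(
    session: ScanSession,
    plane: str,
    bias_events: Iterable[BiasEvent],
    include_intermediate_looks: bool = False,
) -> tuple[float, float]:
    """(min_mm, max_mm) over the plane's bias-candidate value set.

    The candidate set holds, for every biased episode of the plane, both the
    first-look and the saved value; for every unbiased episode, the saved
    value only.  ``include_intermediate_looks`` is accepted for forward
    compatibility with logs that record every look; the two-point set is the
    default and the only one the standard event log can populate.
    """
    by_index = {ev.episode_index: ev for ev in bias_events if ev.scan_id == session.scan_id}
    candidates: list[float] = []
    for idx, ep in enumerate(session.episodes):
        if ep.plane != plane:
            continue
        candidates.append(ep.saved_value)
        ev = by_index.get(idx)
        if ev is not None:
            candidates.append(ev.value_at_first_look)
    if not candidates:
        raise DataError(f"scan {session.scan_id}: no saved {plane} measurement")
    return min(candidates), max(candidates)


# ---------------------------------------------------------------------------
# event-log and metadata I/O


def write_event_log(sessions: Iterable[ScanSession], path: str | Path) -> None:
    """Write episodes as JSON-lines, one record per measurement episode."""
    with open(path, "w") as fh:
        for s in sessions:
            for ep in s.episodes:
                rec = {
                    "scan_id": s.scan_id,
                    "plane": ep.plane,
                    "aoi": {
                        "left": ep.box_aoi.left,
                        "top": ep.box_aoi.top,
                        "right": ep.box_aoi.right,
                        "bottom": ep.box_aoi.bottom,
                        "t_start": ep.box_aoi.t_start,
                        "t_end": ep.box_aoi.t_end,
                    },
                    "trajectory": [[t, v] for t, v in ep.trajectory],
                    "t_save": ep.t_save,
                }
                fh.write(json.dumps(rec) + "\n")


def write_metadata_csv(sessions: Iterable[ScanSession], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "scan_id": s.scan_id,
                "operator_id": s.operator_id,
                "expected_ga_days": s.expected_ga_days,
                "bmi": s.maternal_bmi,
                "experience_years": s.operator_experience_years,
            }
            for s in sessions
        ]
    ).to_csv(path, index=False)


def read_sessions(event_log_path: str | Path, metadata_path: str | Path) -> list[ScanSession]:
    """Assemble sessions from a JSON-lines event log plus a metadata CSV."""
    meta = pd.read_csv(metadata_path, dtype={"scan_id": str, "operator_id": str})
    required = {"scan_id", "operator_id", "expected_ga_days", "bmi", "experience_years"}
    missing = required - set(meta.columns)
    if missing:
        raise InputError(f"metadata CSV missing columns {sorted(missing)}")
    episodes: dict[str, list[MeasurementEpisode]] = {}
    with open(event_log_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                aoi = AOI(
                    left=rec["aoi"]["left"],
                    top=rec["aoi"]["top"],
                    right=rec["aoi"]["right"],
                    bottom=rec["aoi"]["bottom"],
                    t_start=rec["aoi"]["t_start"],
                    t_end=rec["aoi"]["t_end"],
                )
                ep = MeasurementEpisode(
                    plane=rec["plane"],
                    box_aoi=aoi,
                    trajectory=tuple((float(t), float(v)) for t, v in rec["trajectory"]),
                    t_save=float(rec["t_save"]),
                )
            except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                raise InputError(f"{event_log_path}: malformed episode at line {lineno}: {exc}") from exc
            episodes.setdefault(str(rec["scan_id"]), []).append(ep)
    sessions = []
    for row in meta.itertuples(index=False):
        eps = episodes.get(str(row.scan_id), [])
        eps.sort(key=lambda e: e.t_save)
        sessions.append(
            ScanSession(
                scan_id=str(row.scan_id),
                operator_id=str(row.operator_id),
                expected_ga_days=float(row.expected_ga_days),
                maternal_bmi=float(row.bmi),
                operator_experience_years=float(row.experience_years),
                episodes=tuple(eps),
            )
        )
    unknown = set(episodes) - set(meta["scan_id"].astype(str))
    if unknown:
        raise InputError(f"event log has scans absent from metadata: {sorted(unknown)}")
    return sessions
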