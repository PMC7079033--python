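"""Fixation detection on an area of interest from a raw gaze-sample stream.

The rule of interest: a *fixation* on the measurement box is an uninterrupted
dwell of the operator's gaze on the box lasting at least ``min_fixation_ms``
(default 100 ms), where interruptions of at most ``merge_gap_ms`` (default
400 ms) — including tracker-loss gaps — are bridged and count as part of a
single episode.  Interruptions are merged *first*, then the duration minimum
is applied to the merged episode.

Gaze trackers emit point samples, not intervals, so a sample-to-interval rule
is needed: sample *i* is taken to occupy the half-open interval between the
midpoints to its neighbours (the first sample starts at its own timestamp, the
last ends at its own timestamp).  A sample is "in AOI" iff it is valid, lies
inside the AOI rectangle (left/top edges inclusive, right/bottom exclusive)
and falls within the AOI's active interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class GazeSample:
    t_ms: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class AOI:
    """Screen rectangle (pixels) active over [t_start, t_end) ms."""

    left: float
    top: float
    right: float
    bottom: float
    t_start: float
    t_end: float
    aoi_id: str = "box"

    def __post_init__(self) -> None:
        if not (self.left < self.right and self.top < self.bottom):
            raise InputError(f"degenerate AOI rectangle {self!r}")
        if not (self.t_start < self.t_end):
            raise InputError(f"AOI active interval empty: {self.t_start}..{self.t_end}")

    def contains(self, x: float, y: float) -> bool:
        return (self.left <= x < self.right) and (self.top <= y < self.bottom)


@dataclass(frozen=True)
class Fixation:
    t_start: float
    t_end: float
    aoi_id: str = "box"

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _stream_arrays(stream) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalise a stream (list of GazeSample or DataFrame) to numpy arrays."""
    if isinstance(stream, pd.DataFrame):
        t = stream["t_ms"].to_numpy(dtype=float)
        x = stream["x"].to_numpy(dtype=float)
        y = stream["y"].to_numpy(dtype=float)
        valid = stream["valid"].to_numpy(dtype=bool)
    else:
        samples = list(stream)
        t = np.array([s.t_ms for s in samples], dtype=float)
        x = np.array([s.x for s in samples], dtype=float)
        y = np.array([s.y for s in samples], dtype=float)
        valid = np.array([s.valid for s in samples], dtype=bool)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise InputError("gaze stream timestamps must be strictly increasing")
    return t, x, y, valid


def sample_occupancy(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-open occupancy interval [start, end) for each point sample.

    Boundaries sit at midpoints between consecutive samples; the first
    interval starts at t[0] and the last ends at t[-1].
    """
    if len(t) == 0:
        return np.empty(0), np.empty(0)
    mids = (t[:-1] + t[1:]) / 2.0
    starts = np.concatenate([[t[0]], mids])
    ends = np.concatenate([mids, [t[-1]]])
    return starts, ends


def detect_fixations(
    stream,
    aoi: AOI,
    min_fixation_ms: float = 100.0,
    merge_gap_ms: float = 400.0,
) -> list[Fixation]:
    """Detect AOI fixations >= ``min_fixation_ms`` after merging gaps <= ``merge_gap_ms``.

    Parameters
    ----------
    stream
        Time-sorted gaze samples: a sequence of :class:`GazeSample` or a
        DataFrame with columns ``t_ms, x, y, valid``.
    aoi
        The area of interest (measurement box) with its active interval;
        dwell episodes are clipped to that interval.

    Returns
    -------
    Sorted, non-overlapping fixations.  Any two raw dwell episodes separated
    by <= ``merge_gap_ms`` are merged before the duration threshold applies.
    """
    t, x, y, valid = _stream_arrays(stream)
    if len(t) == 0:
        return []
    in_aoi = (
        valid
        & (x >= aoi.left) & (x < aoi.right)
        & (y >= aoi.top) & (y < aoi.bottom)
    )
    starts, ends = sample_occupancy(t)
    # clip occupancy to the AOI active window
    starts = np.clip(starts, aoi.t_start, aoi.t_end)
    ends = np.clip(ends, aoi.t_start, aoi.t_end)
    keep = in_aoi & (ends > starts)

    # raw dwell episodes: union of consecutive overlapping/contiguous kept intervals
    episodes: list[list[float]] = []
    for s, e in zip(starts[keep], ends[keep]):
        if episodes and s <= episodes[-1][1]:  # contiguous (midpoints touch)
            episodes[-1][1] = max(episodes[-1][1], e)
        else:
            episodes.append([s, e])

    # merge interruptions <= merge_gap_ms, then apply the duration minimum
    merged: list[list[float]] = []
    for s, e in episodes:
        if merged and s - merged[-1][1] <= merge_gap_ms:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        Fixation(t_start=s, t_end=e, aoi_id=aoi.aoi_id)
        for s, e in merged
        if e - s >= min_fixation_ms
    ]


def fixations_in_window(
    fixations: Iterable[Fixation],
    t0: float,
    t1: float,
    clip: bool = False,
) -> list[Fixation]:
    """Fixations overlapping [t0, t1); clipped to the window iff ``clip``."""
    if not (t0 < t1):
        raise InputError(f"empty window [{t0}, {t1})")
    out = []
    for f in fixations:
        if f.t_end > t0 and f.t_start < t1:
            if clip:
                out.append(Fixation(max(f.t_start, t0), min(f.t_end, t1), f.aoi_id))
            else:
                out.append(f)
    return out


def read_gaze_csv(path) -> pd.DataFrame:
    """Read a gaze stream CSV with columns ``t_ms, x, y, valid``."""
    df = pd.read_csv(path)
    missing = {"t_ms", "x", "y", "valid"} - set(df.columns)
    if missing:
        raise InputError(f"gaze CSV {path} missing columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df
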