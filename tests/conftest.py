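"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from scanbias.gaze import AOI
from scanbias.growth import GrowthStandard, load_standard


@pytest.fixture(scope="session")
def std() -> GrowthStandard:
    return load_standard("hadlock")


def make_linear_standard(mm_per_day: float = 2.0) -> GrowthStandard:
    """Toy standard with measurement(mm) = mm_per_day * GA(days) on every plane.

    GA(weeks) as a function of cm is then (cm * 10 / mm_per_day) / 7.
    """
    slope = 10.0 / mm_per_day / 7.0
    plane_cfg = {
        "ga_weeks_from_cm": [0.0, slope],
        "valid_ga_days": [100, 280],
        "bracket_cm": [0.01, 200.0],
    }
    return GrowthStandard.from_dict(
        {
            "name": "toy-linear",
            "planes": {p: dict(plane_cfg) for p in ("HC", "AC", "FL")},
            "efw": {
                "type": "hadlock3_log10_cm",
                "intercept": 1.326,
                "hc": 0.0107,
                "ac": 0.0438,
                "fl": 0.158,
                "ac_fl": -0.00326,
                "domain_mm": {"HC": [80, 450], "AC": [80, 480], "FL": [15, 110]},
            },
            "efw_for_ga": {
                "mean_log_coeffs": [0.578, 0.332, -0.00354],
                "log_sd": 0.127,
                "valid_ga_days": [70, 294],
            },
        }
    )


@pytest.fixture
def linear_std() -> GrowthStandard:
    return make_linear_standard()


# ---------------------------------------------------------------------------
# independent fixation oracle: nearest-sample rasterization at 0.5 ms
# (all sample timestamps and AOI boundaries in oracle-based tests are integer
# ms, so every occupancy boundary is a multiple of 0.5 ms and the 0.5 ms grid
# is exact, not an approximation)


def oracle_fixations(t, x, y, valid, aoi: AOI, min_fixation_ms=100.0, merge_gap_ms=400.0):
    """Brute-force dwell detection over a fine time grid.

    For each 0.5 ms bin centre within the stream span, the owning sample is
    the nearest sample in time (bin centres at .25/.75 never tie with integer
    timestamps); the bin is "in" iff that sample is valid, inside the AOI
    rectangle and the bin centre lies in the AOI active interval.  Runs of
    in-bins become episodes; gaps <= merge_gap_ms merge; episodes shorter
    than min_fixation_ms drop.
    """
    t = np.asarray(t, dtype=float)
    if len(t) == 0:
        return []
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    edges = np.arange(t[0], t[-1], 0.5)
    if len(edges) == 0:
        return []
    tau = edges + 0.25
    right = np.searchsorted(t, tau)  # first sample index with t >= tau
    left = right - 1
    right = np.clip(right, 0, len(t) - 1)
    left = np.clip(left, 0, len(t) - 1)
    use_right = np.abs(t[right] - tau) < np.abs(tau - t[left])
    owner = np.where(use_right, right, left)
    in_bin = (
        valid[owner]
        & (x[owner] >= aoi.left)
        & (x[owner] < aoi.right)
        & (y[owner] >= aoi.top)
        & (y[owner] < aoi.bottom)
        & (tau >= aoi.t_start)
        & (tau < aoi.t_end)
    )
    # run-length episodes over the bin sequence
    episodes = []
    start = None
    for i, flag in enumerate(in_bin):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            episodes.append((edges[start], edges[i]))
            start = None
    if start is not None:
        episodes.append((edges[start], edges[-1] + 0.5))
    merged = []
    for s, e in episodes:
        if merged and s - merged[-1][1] <= merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_fixation_ms]


def random_stream(rng: np.random.Generator, hz: float, duration_ms: float, aoi: AOI):
    """Random gaze stream (integer ms) with in/out dwells and tracker loss."""
    period = 1000.0 / hz
    t = np.cumsum(rng.uniform(0.6 * period, 1.4 * period, size=max(2, int(duration_ms / period))))
    t = np.unique(np.round(t).astype(int))
    n = len(t)
    inside = np.zeros(n, dtype=bool)
    i = 0
    while i < n:  # alternate random-length in/out runs
        run = int(rng.integers(1, 25))
        inside[i : i + run] = rng.random() < 0.5
        i += run
    x = np.where(
        inside,
        rng.uniform(aoi.left, aoi.right, size=n),
        rng.uniform(0, aoi.left - 1, size=n),
    )
    y = np.where(
        inside,
        rng.uniform(aoi.top, aoi.bottom, size=n),
        rng.uniform(0, aoi.top - 1, size=n),
    )
    valid = rng.random(size=n) > 0.05
    return t.astype(float), x, y, valid
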