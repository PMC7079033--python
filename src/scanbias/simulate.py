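"""Synthetic growth-scan cohort simulator with known ground truth.

The generator emulates the behavioural model the analysis assumes: an
operator measuring a plane obtains an initial caliper value whose implied GA
deviates from the expected GA (fetal-size offset + plane-acquisition noise +
caliper noise); with probability ``p_look`` the operator fixates on the
measurement box (>= 100 ms) during adjustment and then closes a fraction
``beta`` of the gap between the observed and expected GA before saving; a
saved measurement still far from the expected GA (beyond ``repeat_threshold``)
triggers a repeat attempt with probability ``p_repeat``, re-measuring the same
underlying fetus.

All GA-scale quantities are converted to millimetres through a growth
standard's forward curve, so the emitted event logs and gaze streams have
exactly the shapes the analysis pipeline ingests, and a separate ground-truth
table (never read by the pipeline) records the per-episode latent state.

Defaults emulate the study conditions of a third-trimester growth-scan
cohort: 272 scans by 16 operators, expected GA roughly 28.5-40.5 weeks,
measurement-box look probability 0.914, and deviation SDs producing
one-to-two-week spreads of observed-minus-expected GA.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gaze import AOI, Fixation
from .growth import GrowthStandard, PLANES
from .session import MeasurementEpisode, ScanSession

#: measurement-box rectangle on the simulated screen (pixels)
BOX_RECT = (1000.0, 600.0, 1200.0, 660.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the simulated cohort.

    GA-scale SDs are in days; probabilities in [0, 1]; ``beta`` is the
    fraction of the observed-vs-expected gap closed after a look.
    """

    n_scans: int = 272
    n_operators: int = 16
    ga_range_days: tuple[float, float] = (200.0, 285.0)
    sigma_fetal_days: float = 9.0  # fetal-size offset shared by all planes of a scan
    sigma_plane_days: float = 5.0  # plane-acquisition offset, one per plane per scan
    sigma_meas_days: float = 4.0  # caliper noise, redrawn per episode
    p_look: float = 0.914
    beta: float = 0.3
    sigma_adj_days: float = 1.0  # post-look jitter (~weeks+days display resolution)
    repeat_threshold_days: float = 8.0
    p_repeat: float = 0.7
    max_repeats: int = 3
    gaze_hz: float = 60.0
    distractor_rate_hz: float = 0.10  # sub-threshold glances at the box, per second
    tracker_loss_rate_hz: float = 0.05  # brief valid=False gaps, per second
    bias_on_mm_scale: bool = False  # alternative: close the gap in mm, not days
    bmi_mean: float = 25.8
    bmi_sd: float = 5.3
    experience_range_years: tuple[float, float] = (0.3, 14.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_scans < 1 or self.n_operators < 1:
            raise ConfigurationError("n_scans and n_operators must be >= 1")
        lo, hi = self.ga_range_days
        if not lo < hi:
            raise ConfigurationError(f"ga_range_days {self.ga_range_days} must be increasing")
        for name in ("sigma_fetal_days", "sigma_plane_days", "sigma_meas_days", "sigma_adj_days"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("p_look", "p_repeat", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        if self.gaze_hz <= 0:
            raise ConfigurationError("gaze_hz must be > 0")
        if self.max_repeats < 0:
            raise ConfigurationError("max_repeats must be >= 0")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class SimulatedCohort:
    """Simulator output: pipeline inputs plus the latent ground truth."""

    config: SimulationConfig
    sessions: list[ScanSession]
    gaze_streams: dict[str, pd.DataFrame]  # scan_id -> t_ms, x, y, valid
    scripted_fixations: dict[str, list[list[Fixation]]]  # per scan, aligned to episodes
    ground_truth: pd.DataFrame


# ---------------------------------------------------------------------------


def _scripted_timeline(rng: np.random.Generator, t_cursor: float, look: bool):
    """Timestamps of one episode: box appearance, optional fixation, update, save."""
    t_box = t_cursor
    if look:
        t_fix_start = t_box + rng.uniform(800.0, 2000.0)
        fix_dur = rng.uniform(250.0, 600.0)
        t_fix_end = t_fix_start + fix_dur
        t_update = t_fix_end + rng.uniform(200.0, 800.0)
        t_save = t_update + rng.uniform(600.0, 1500.0)
        return t_box, (t_fix_start, t_fix_end), t_update, t_save
    t_save = t_box + rng.uniform(3000.0, 8000.0)
    return t_box, None, None, t_save


def _place_intervals(
    rng: np.random.Generator,
    n: int,
    window: tuple[float, float],
    dur_range: tuple[float, float],
    forbidden: list[tuple[float, float]],
    margin: float,
) -> list[tuple[float, float]]:
    """Place up to n non-overlapping intervals avoiding forbidden zones (+margin)."""
    placed: list[tuple[float, float]] = []
    lo, hi = window
    for _ in range(n):
        for _attempt in range(8):
            dur = rng.uniform(*dur_range)
            if hi - lo <= dur:
                break
            start = rng.uniform(lo, hi - dur)
            cand = (start, start + dur)
            zones = forbidden + placed
            if all(cand[1] + margin <= a or cand[0] - margin >= b for a, b in zones):
                placed.append(cand)
                break
    return placed


def _gaze_stream(
    rng: np.random.Generator,
    duration_ms: float,
    hz: float,
    fixation_intervals: list[tuple[float, float]],
    distractor_intervals: list[tuple[float, float]],
    loss_intervals: list[tuple[float, float]],
) -> pd.DataFrame:
    left, top, right, bottom = BOX_RECT
    t = np.arange(0.0, duration_ms, 1000.0 / hz)
    x = rng.uniform(100.0, 900.0, size=len(t))
    y = rng.uniform(100.0, 560.0, size=len(t))
    valid = np.ones(len(t), dtype=bool)
    for a, b in fixation_intervals + distractor_intervals:
        mask = (t >= a) & (t < b)
        x[mask] = rng.uniform(left + 5.0, right - 5.0, size=mask.sum())
        y[mask] = rng.uniform(top + 5.0, bottom - 5.0, size=mask.sum())
    for a, b in loss_intervals:
        valid[(t >= a) & (t < b)] = False
    return pd.DataFrame({"t_ms": t, "x": x, "y": y, "valid": valid})


def simulate_cohort(
    cfg: SimulationConfig,
    std: GrowthStandard,
    emit_gaze: bool = True,
) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``cfg``.

    With ``emit_gaze=False`` the (slow) raw gaze streams are skipped; the
    scripted fixations, which the streams encode exactly, are always returned
    and can be fed to bias detection directly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo_ga, hi_ga = cfg.ga_range_days
    operators = [
        (f"op{k:02d}", float(rng.uniform(*cfg.experience_range_years)))
        for k in range(cfg.n_operators)
    ]
    left, top, right, bottom = BOX_RECT

    sessions: list[ScanSession] = []
    gaze_streams: dict[str, pd.DataFrame] = {}
    scripted: dict[str, list[list[Fixation]]] = {}
    gt_rows: list[dict] = []

    for i in range(cfg.n_scans):
        scan_id = f"scan{i:04d}"
        op_id, op_exp = operators[int(rng.integers(cfg.n_operators))]
        expected_ga = float(np.floor(rng.uniform(lo_ga, hi_ga + 1.0)))
        bmi = float(max(15.0, rng.normal(cfg.bmi_mean, cfg.bmi_sd)))
        delta_scan = rng.normal(0.0, cfg.sigma_fetal_days)

        episodes: list[MeasurementEpisode] = []
        fixes_per_episode: list[list[Fixation]] = []
        fixation_intervals: list[tuple[float, float]] = []
        episode_windows: list[tuple[float, float]] = []
        t_cursor = 5000.0

        for plane in PLANES:
            eps_plane = rng.normal(0.0, cfg.sigma_plane_days)
            true_ga = expected_ga + delta_scan + eps_plane
            n_attempts = 0
            while True:
                o_before = true_ga + rng.normal(0.0, cfg.sigma_meas_days)
                look = bool(rng.random() < cfg.p_look)
                if look:
                    if cfg.bias_on_mm_scale:
                        v0 = std.measurement_from_ga(plane, o_before)
                        v_e = std.measurement_from_ga(plane, expected_ga)
                        # jitter expressed in days, converted via local slope
                        slope = (
                            std.measurement_from_ga(plane, o_before + 0.5)
                            - std.measurement_from_ga(plane, o_before - 0.5)
                        )
                        v1 = v0 + cfg.beta * (v_e - v0) + rng.normal(0.0, cfg.sigma_adj_days) * slope
                        o_after = std.ga_from_measurement(plane, v1).ga_days
                    else:
                        o_after = (
                            o_before
                            + cfg.beta * (expected_ga - o_before)
                            + rng.normal(0.0, cfg.sigma_adj_days)
                        )
                else:
                    o_after = o_before

                v_before = std.measurement_from_ga(plane, o_before)
                v_after = std.measurement_from_ga(plane, o_after)
                t_box, fix, t_update, t_save = _scripted_timeline(rng, t_cursor, look)
                traj: list[tuple[float, float]] = [(t_box, v_before)]
                if look and abs(v_after - v_before) > 0:
                    traj.append((t_update, v_after))
                aoi = AOI(
                    left=left, top=top, right=right, bottom=bottom,
                    t_start=t_box, t_end=t_save, aoi_id="measurement_box",
                )
                episodes.append(
                    MeasurementEpisode(
                        plane=plane, box_aoi=aoi, trajectory=tuple(traj), t_save=t_save
                    )
                )
                episode_windows.append((t_box, t_save))
                if fix is not None:
                    fixes_per_episode.append(
                        [Fixation(t_start=fix[0], t_end=fix[1], aoi_id="measurement_box")]
                    )
                    fixation_intervals.append(fix)
                else:
                    fixes_per_episode.append([])
                gt_rows.append(
                    {
                        "scan_id": scan_id,
                        "plane": plane,
                        "episode_index": len(episodes) - 1,
                        "true_ga_days": true_ga,
                        "look": look,
                        "observed_ga_before": o_before,
                        "observed_ga_after": o_after,
                        "is_repeat": n_attempts > 0,
                    }
                )
                t_cursor = t_save + rng.uniform(2000.0, 6000.0)
                n_attempts += 1
                far = abs(o_after - expected_ga) > cfg.repeat_threshold_days
                if far and n_attempts <= cfg.max_repeats and rng.random() < cfg.p_repeat:
                    continue
                break

        session = ScanSession(
            scan_id=scan_id,
            operator_id=op_id,
            expected_ga_days=expected_ga,
            maternal_bmi=bmi,
            operator_experience_years=op_exp,
            episodes=tuple(episodes),
        )
        sessions.append(session)
        scripted[scan_id] = fixes_per_episode

        if emit_gaze:
            duration = episodes[-1].t_save + 2000.0
            # distractor glances (30-80 ms, safely sub-threshold at >=50 Hz) and
            # tracker-loss gaps, both kept >=600 ms clear of scripted fixations
            # so merging can never bridge into or across a real look
            forbidden = list(fixation_intervals)
            n_distract = int(rng.poisson(cfg.distractor_rate_hz * duration / 1000.0))
            distractors: list[tuple[float, float]] = []
            for a, b in episode_windows:
                quota = max(0, int(round(n_distract * (b - a) / duration)))
                distractors += _place_intervals(
                    rng, quota, (a, b), (30.0, 80.0), forbidden + distractors, 600.0
                )
            n_loss = int(rng.poisson(cfg.tracker_loss_rate_hz * duration / 1000.0))
            losses = _place_intervals(
                rng, n_loss, (0.0, duration), (50.0, 300.0),
                forbidden + distractors, 600.0,
            )
            gaze_streams[scan_id] = _gaze_stream(
                rng, duration, cfg.gaze_hz, fixation_intervals, distractors, losses
            )

    ground_truth = pd.DataFrame(gt_rows)
    return SimulatedCohort(
        config=cfg,
        sessions=sessions,
        gaze_streams=gaze_streams,
        scripted_fixations=scripted,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# parameter recovery


def parameter_recovery_report(
    cfg: SimulationConfig,
    records: pd.DataFrame,
    ground_truth: pd.DataFrame,
) -> dict:
    """Compare pipeline outputs against the simulator's ground truth.

    ``beta`` is re-estimated as the OLS slope of (d_before - d_after) on
    d_before over biased measurements — under the generative model
    d_after = (1 - beta) * d_before + noise, so that slope is beta.
    """
    import statsmodels.api as sm

    biased = records[records["biased"]].dropna(subset=["d_before", "d_after"])
    out: dict = {
        "beta_true": cfg.beta,
        "p_look_true": cfg.p_look,
        "n_measurements": int(len(records)),
        "n_biased": int(len(biased)),
    }
    out["incidence_hat"] = float(records["biased"].mean()) if len(records) else np.nan
    out["incidence_true_empirical"] = float(ground_truth["look"].mean())
    out["incidence_error"] = out["incidence_hat"] - cfg.p_look
    n = len(records)
    toward = float((records["adjustment_class"] == "toward").mean()) if n else np.nan
    away = float((records["adjustment_class"] == "away").mean()) if n else np.nan
    out["toward_pct"] = 100.0 * toward
    out["away_pct"] = 100.0 * away
    if len(biased) >= 3 and biased["d_before"].std(ddof=1) > 0:
        X = sm.add_constant(biased["d_before"].to_numpy(float))
        yv = (biased["d_before"] - biased["d_after"]).to_numpy(float)
        fit = sm.OLS(yv, X).fit()
        out["beta_hat"] = float(fit.params[1])
        out["beta_hat_se"] = float(fit.bse[1])
        out["beta_error"] = out["beta_hat"] - cfg.beta
    else:
        out["beta_hat"] = np.nan
    return out
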