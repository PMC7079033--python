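"""Cohort-level expected-value-bias statistics.

Builds one deviation record per saved measurement (deviation of the observed
GA from the expected GA before and after the operator looked at the
measurement box), then derives:

* an incidence table in the layout of the study's per-plane summary (saved n,
  repeat n, measurements per scan, % biased, % adjusted toward / away from the
  expected GA, mean adjustment in days),
* paired before/after location tests (paired t and Wilcoxon signed-rank on
  |deviation|) and a Levene variance-equality test on the signed deviations,
* a repeated-vs-not comparison per plane (Mann-Whitney U),
* covariate-adjusted linear models (maternal BMI, operator experience), and
* the clinical-impact analysis: per-scan EFW bounds from the smallest/largest
  candidate measurements, percentage discordance, Z-score difference and
  SGA/AGA/LGA reclassification ("swing") proportions with binomial CIs.

Statistical tests come from scipy.stats; model fits and proportion CIs from
statsmodels.  No multiple-testing correction is applied (per-comparison
reporting); outputs flag this in their metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError
from .growth import AGA, LGA, SGA, PLANES, GrowthStandard
from .session import (
    AWAY,
    TOWARD,
    BiasEvent,
    ScanSession,
    candidate_values,
    classify_adjustment,
    group_repeats,
)

SWING_NONE = "none"
SWING_SGA = "SGA<->AGA"
SWING_LGA = "LGA<->AGA"
SWING_OTHER = "other"

_RECORD_COLUMNS = [
    "scan_id",
    "plane",
    "episode_index",
    "is_repeat",
    "biased",
    "d_before",
    "d_after",
    "abs_d_before",
    "abs_d_after",
    "adjustment_days",
    "adjustment_class",
    "saved_value_mm",
    "first_look_value_mm",
    "expected_ga_days",
    "bmi",
    "experience_years",
]


def build_deviation_records(
    sessions: Sequence[ScanSession],
    bias_events: Iterable[BiasEvent],
    std: GrowthStandard,
    unchanged_tol_days: float = 0.25,
) -> pd.DataFrame:
    """One row per saved measurement with its before/after deviations from E."""
    by_scan: dict[str, dict[int, BiasEvent]] = {}
    for ev in bias_events:
        by_scan.setdefault(ev.scan_id, {})[ev.episode_index] = ev
    rows = []
    for s in sessions:
        repeats = group_repeats(s)
        for idx, ep in enumerate(s.episodes):
            ev = by_scan.get(s.scan_id, {}).get(idx)
            res = classify_adjustment(
                ev,
                s.expected_ga_days,
                std,
                saved_value=ep.saved_value,
                plane=ep.plane,
                unchanged_tol_days=unchanged_tol_days,
            )
            rows.append(
                {
                    "scan_id": s.scan_id,
                    "plane": ep.plane,
                    "episode_index": idx,
                    "is_repeat": repeats[idx],
                    "biased": ev is not None,
                    "d_before": res.d_before if ev is not None else np.nan,
                    "d_after": res.d_after,
                    "abs_d_before": abs(res.d_before) if ev is not None else np.nan,
                    "abs_d_after": abs(res.d_after),
                    "adjustment_days": res.adjustment_days if ev is not None else np.nan,
                    "adjustment_class": res.adjustment_class,
                    "saved_value_mm": ep.saved_value,
                    "first_look_value_mm": ev.value_at_first_look if ev is not None else np.nan,
                    "expected_ga_days": s.expected_ga_days,
                    "bmi": s.maternal_bmi,
                    "experience_years": s.operator_experience_years,
                }
            )
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# incidence table


def incidence_table(records: pd.DataFrame, n_scans: int | None = None) -> pd.DataFrame:
    """Per-plane and total incidence summary.

    Percentages use all saved measurements of the plane as denominator (the
    remainder being unchanged-after-look or never-looked measurements); the
    ``*_biased_denom`` columns repeat them over biased measurements only.
    The mean adjustment toward the expected GA is reported both over biased
    measurements (``mean_adjustment_days``) and over all saved ones
    (``mean_adjustment_days_all``, unbiased contributing 0).
    """
    if records.empty:
        raise DataError("incidence_table requires at least one deviation record")
    if n_scans is None:
        n_scans = records["scan_id"].nunique()
    rows = {}
    for plane in (*PLANES, "Total"):
        sub = records if plane == "Total" else records[records["plane"] == plane]
        n_saved = len(sub)
        if n_saved == 0:
            rows[plane] = {"n_saved": 0, "n_repeat": 0}
            continue
        per_scan = (
            sub.groupby("scan_id").size().reindex(records["scan_id"].unique(), fill_value=0)
        )
        n_biased = int(sub["biased"].sum())
        n_toward = int((sub["adjustment_class"] == TOWARD).sum())
        n_away = int((sub["adjustment_class"] == AWAY).sum())
        adj_biased = sub.loc[sub["biased"], "adjustment_days"]
        adj_all = sub["adjustment_days"].fillna(0.0)
        rows[plane] = {
            "n_saved": n_saved,
            "n_repeat": int(sub["is_repeat"].sum()),
            "per_scan_mean": per_scan.mean(),
            "per_scan_sd": per_scan.std(ddof=1) if n_scans > 1 else 0.0,
            "pct_biased": 100.0 * n_biased / n_saved,
            "pct_toward": 100.0 * n_toward / n_saved,
            "pct_away": 100.0 * n_away / n_saved,
            "pct_toward_biased_denom": 100.0 * n_toward / n_biased if n_biased else np.nan,
            "pct_away_biased_denom": 100.0 * n_away / n_biased if n_biased else np.nan,
            "mean_adjustment_days": adj_biased.mean() if n_biased else np.nan,
            "sd_adjustment_days": adj_biased.std(ddof=1) if n_biased > 1 else np.nan,
            "mean_adjustment_days_all": adj_all.mean(),
            "sd_adjustment_days_all": adj_all.std(ddof=1) if n_saved > 1 else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "plane"
    return table


# ---------------------------------------------------------------------------
# hypothesis tests


def _paired_tests(before: np.ndarray, after: np.ndarray) -> dict:
    diffs = before - after
    out: dict = {"n_pairs": int(len(before)), "computable": len(before) >= 2}
    if len(before) < 2:
        return out
    out["mean_abs_before"] = float(np.mean(before))
    out["mean_abs_after"] = float(np.mean(after))
    out["mean_adjustment_days"] = float(np.mean(diffs))
    out["sd_adjustment_days"] = float(np.std(diffs, ddof=1))
    if np.allclose(diffs, 0.0):
        out["t_stat"], out["t_p"] = 0.0, 1.0
        out["wilcoxon_stat"], out["wilcoxon_p"] = 0.0, 1.0
    else:
        t_stat, t_p = sps.ttest_rel(before, after)
        out["t_stat"], out["t_p"] = float(t_stat), float(t_p)
        w_stat, w_p = sps.wilcoxon(before, after, zero_method="pratt")
        out["wilcoxon_stat"], out["wilcoxon_p"] = float(w_stat), float(w_p)
    return out


def before_after_tests(records: pd.DataFrame) -> dict:
    """Paired location tests and Levene variance test, per plane and pooled.

    Biased measurements only (they alone have a before value).  Two paired
    comparisons are reported: on the absolute deviations |d_before| vs
    |d_after| (did measurements move closer to the expected GA — a one-sided
    phenomenon) and on the signed deviations d_before vs d_after (did the
    mean observed GA shift — the comparison that is exactly mean-zero when
    the adjustment merely re-jitters the caliper).  Levene (center = median)
    compares the spread of the signed deviations before vs after.
    """
    biased = records[records["biased"]]
    out: dict = {}
    for key in ("pooled", *PLANES):
        sub = biased if key == "pooled" else biased[biased["plane"] == key]
        res = _paired_tests(
            sub["abs_d_before"].to_numpy(float), sub["abs_d_after"].to_numpy(float)
        )
        if res["computable"]:
            signed = _paired_tests(
                sub["d_before"].to_numpy(float), sub["d_after"].to_numpy(float)
            )
            res["signed_t_stat"] = signed.get("t_stat")
            res["signed_t_p"] = signed.get("t_p")
            res["signed_wilcoxon_p"] = signed.get("wilcoxon_p")
            res["signed_mean_shift_days"] = signed.get("mean_adjustment_days")
            d_b = sub["d_before"].to_numpy(float)
            d_a = sub["d_after"].to_numpy(float)
            res["var_before"] = float(np.var(d_b, ddof=1))
            res["var_after"] = float(np.var(d_a, ddof=1))
            if np.allclose(d_b - d_a, 0.0):
                res["levene_stat"], res["levene_p"] = 0.0, 1.0
            else:
                lev_stat, lev_p = sps.levene(d_b, d_a, center="median")
                res["levene_stat"], res["levene_p"] = float(lev_stat), float(lev_p)
        out[key] = res
    return out


def repeat_comparison(records: pd.DataFrame) -> dict:
    """|deviation| of repeated vs non-repeated saved measurements, per plane."""
    out: dict = {}
    for plane in (*PLANES, "pooled"):
        sub = records if plane == "pooled" else records[records["plane"] == plane]
        rep = sub.loc[sub["is_repeat"], "abs_d_after"].to_numpy(float)
        non = sub.loc[~sub["is_repeat"], "abs_d_after"].to_numpy(float)
        entry: dict = {
            "n_repeated": int(len(rep)),
            "n_not_repeated": int(len(non)),
            "repeated_mean": float(np.mean(rep)) if len(rep) else np.nan,
            "repeated_sd": float(np.std(rep, ddof=1)) if len(rep) > 1 else np.nan,
            "not_repeated_mean": float(np.mean(non)) if len(non) else np.nan,
            "not_repeated_sd": float(np.std(non, ddof=1)) if len(non) > 1 else np.nan,
        }
        if len(rep) and len(non):
            if np.ptp(np.concatenate([rep, non])) == 0:
                entry["mannwhitney_u"], entry["mannwhitney_p"] = (
                    float(len(rep) * len(non) / 2.0),
                    1.0,
                )
            else:
                u, p = sps.mannwhitneyu(rep, non, alternative="two-sided")
                entry["mannwhitney_u"], entry["mannwhitney_p"] = float(u), float(p)
        else:
            entry["group_empty"] = True
        out[plane] = entry
    return out


def _check_full_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise DataError(f"singular design matrix (columns {list(names)})")


def _ols_summary(model) -> dict:
    ci = model.conf_int()
    return {
        "n": int(model.nobs),
        "params": {k: float(v) for k, v in model.params.items()},
        "bse": {k: float(v) for k, v in model.bse.items()},
        "pvalues": {k: float(v) for k, v in model.pvalues.items()},
        "conf_int": {k: [float(ci.loc[k, 0]), float(ci.loc[k, 1])] for k in model.params.index},
        "r_squared": float(model.rsquared),
    }


def adjusted_models(records: pd.DataFrame) -> dict:
    """Covariate-adjusted models (maternal BMI, operator experience).

    (1) OLS of d_after on d_before + BMI + experience, biased measurements
    only — the regression relating the saved deviation to the first-look
    deviation.  (2) ANOVA (type II) of |d_after| on repeat status + BMI +
    experience.  Rows with missing covariates are dropped listwise; the
    dropped count is reported.
    """
    biased = records[records["biased"]].copy()
    cols = ["d_after", "d_before", "bmi", "experience_years"]
    complete = biased.dropna(subset=cols)
    n_dropped = len(biased) - len(complete)
    if len(complete) < 5:
        raise DataError("too few complete biased records for adjusted models")
    X = sm.add_constant(complete[["d_before", "bmi", "experience_years"]].astype(float))
    _check_full_rank(X.to_numpy(), X.columns)
    lm = sm.OLS(complete["d_after"].astype(float), X).fit()

    anova_data = records.dropna(subset=["abs_d_after", "bmi", "experience_years"]).copy()
    anova_data["is_repeat"] = anova_data["is_repeat"].astype(int)
    if anova_data["is_repeat"].nunique() < 2:
        anova = {"error": "no variation in repeat status"}
    else:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        Xa = sm.add_constant(anova_data[["is_repeat", "bmi", "experience_years"]].astype(float))
        _check_full_rank(Xa.to_numpy(), Xa.columns)
        fit = smf.ols("abs_d_after ~ C(is_repeat) + bmi + experience_years", data=anova_data).fit()
        aov = anova_lm(fit, typ=2)
        anova = {
            term: {
                "sum_sq": float(aov.loc[term, "sum_sq"]),
                "df": float(aov.loc[term, "df"]),
                "F": float(aov.loc[term, "F"]) if not math.isnan(aov.loc[term, "F"]) else None,
                "p": float(aov.loc[term, "PR(>F)"])
                if not math.isnan(aov.loc[term, "PR(>F)"])
                else None,
            }
            for term in aov.index
        }
    return {
        "n_dropped_missing_covariates": int(n_dropped),
        "linear_model_d_after": _ols_summary(lm),
        "anova_abs_deviation": anova,
    }


# ---------------------------------------------------------------------------
# proportion CIs


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    method: str  # "wald" | "wilson"
    proportion: float
    lower: float
    upper: float


def proportion_ci(k: int, n: int, method: str = "wilson", alpha: float = 0.05) -> ProportionCI:
    """95% (by default) binomial CI for k successes out of n."""
    if n <= 0:
        raise DataError("proportion_ci requires n > 0")
    if not 0 <= k <= n:
        raise DataError(f"k={k} outside [0, n={n}]")
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise DataError(f"unknown CI method {method!r} (use 'wald' or 'wilson')")
    lo, hi = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return ProportionCI(k=k, n=n, method=method, proportion=k / n, lower=float(lo), upper=float(hi))


# ---------------------------------------------------------------------------
# EFW impact


def _swing_label(class_min: str, class_max: str) -> str:
    pair = {class_min, class_max}
    if class_min == class_max:
        return SWING_NONE
    if pair == {SGA, AGA}:
        return SWING_SGA
    if pair == {LGA, AGA}:
        return SWING_LGA
    return SWING_OTHER


def efw_impact(
    sessions: Sequence[ScanSession],
    bias_events: Iterable[BiasEvent],
    std: GrowthStandard,
    discordance_denominator: str = "max",
) -> tuple[pd.DataFrame, dict]:
    """Per-scan EFW bounds and cohort-level clinical-impact aggregates.

    For each scan with at least one saved measurement of every plane, the
    lowest possible EFW combines the smallest candidate HC, AC and FL (the
    candidate set holding first-look and saved values of biased episodes and
    saved values of unbiased ones) and the highest EFW the largest candidates.
    Discordance is 100*(EFW_max - EFW_min)/EFW_max by default (twin-discordance
    convention); ``discordance_denominator="mean"`` uses the pairwise mean.
    Scans missing a plane are excluded and counted.
    """
    if discordance_denominator not in ("max", "mean"):
        raise DataError(f"unknown discordance denominator {discordance_denominator!r}")
    events = list(bias_events)
    rows = []
    excluded = []
    for s in sessions:
        planes_present = {ep.plane for ep in s.episodes}
        missing = [p for p in PLANES if p not in planes_present]
        if missing:
            excluded.append({"scan_id": s.scan_id, "reason": f"missing planes {missing}"})
            continue
        bounds = {p: candidate_values(s, p, events) for p in PLANES}
        efw_min = std.efw(bounds["HC"][0], bounds["AC"][0], bounds["FL"][0])
        efw_max = std.efw(bounds["HC"][1], bounds["AC"][1], bounds["FL"][1])
        denom = efw_max if discordance_denominator == "max" else 0.5 * (efw_max + efw_min)
        z_min = std.efw_zscore(efw_min, s.expected_ga_days)
        z_max = std.efw_zscore(efw_max, s.expected_ga_days)
        class_min = std.classify_size(efw_min, s.expected_ga_days)
        class_max = std.classify_size(efw_max, s.expected_ga_days)
        rows.append(
            {
                "scan_id": s.scan_id,
                "efw_min_g": efw_min,
                "efw_max_g": efw_max,
                "discordance_pct": 100.0 * (efw_max - efw_min) / denom,
                "z_min": z_min,
                "z_max": z_max,
                "z_diff": z_max - z_min,
                "class_min": class_min,
                "class_max": class_max,
                "swing": _swing_label(class_min, class_max),
            }
        )
    summaries = pd.DataFrame(
        rows,
        columns=[
            "scan_id",
            "efw_min_g",
            "efw_max_g",
            "discordance_pct",
            "z_min",
            "z_max",
            "z_diff",
            "class_min",
            "class_max",
            "swing",
        ],
    )
    n = len(summaries)
    cohort: dict = {
        "n_scans_included": n,
        "n_scans_excluded": len(excluded),
        "excluded": excluded,
        "discordance_denominator": discordance_denominator,
    }
    if n:
        cohort.update(
            {
                "discordance_pct_mean": float(summaries["discordance_pct"].mean()),
                "discordance_pct_sd": float(summaries["discordance_pct"].std(ddof=1)) if n > 1 else 0.0,
                "z_diff_mean": float(summaries["z_diff"].mean()),
                "z_diff_sd": float(summaries["z_diff"].std(ddof=1)) if n > 1 else 0.0,
            }
        )
        for label, key in ((SWING_SGA, "sga_aga_swing"), (SWING_LGA, "lga_aga_swing")):
            k = int((summaries["swing"] == label).sum())
            wald = proportion_ci(k, n, method="wald")
            wilson = proportion_ci(k, n, method="wilson")
            cohort[key] = {
                "k": k,
                "n": n,
                "pct": 100.0 * k / n,
                "ci95_wald_pct": [100.0 * wald.lower, 100.0 * wald.upper],
                "ci95_wilson_pct": [100.0 * wilson.lower, 100.0 * wilson.upper],
            }
    return summaries, cohort
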