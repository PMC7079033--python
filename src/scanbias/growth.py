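"""Fetal growth standards: biometry <-> gestational age, EFW and size classes.

A :class:`GrowthStandard` bundles, for each standard biometric plane (head
circumference HC, abdominal circumference AC, femur length FL):

* a gestational-age-from-measurement curve (the value an ultrasound machine
  displays in the measurement box next to the caliper reading),
* its numerical inverse, the measurement-for-GA curve used by the simulator,
* an estimated-fetal-weight (EFW) formula combining HC, AC and FL, and
* an EFW-for-GA reference (mean and SD of log EFW) for Z-scores, centiles and
  small/appropriate/large-for-gestational-age (SGA/AGA/LGA) classification.

All coefficients come from a YAML config (one shipped default, ``hadlock``);
nothing numeric is hard-coded in the logic, so a different scanner's tables can
be dropped in without code changes.  Units: measurements in mm, gestational age
in days, EFW in grams.  Closed-form curves take cm and weeks internally where
the published formulas do; conversion happens at the boundary.

When a measurement maps outside a plane's tabulated GA range — the situation a
Voluson-class machine reports as "OOR" — the curve is still evaluated
(extrapolated, never clamped) and the result carries an ``out_of_range`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationError, DataError, NumericalError

PLANES = ("HC", "AC", "FL")

#: classification labels
SGA, AGA, LGA = "SGA", "AGA", "LGA"


@dataclass(frozen=True)
class BiometricMeasurement:
    """One caliper reading: plane, length/circumference in mm, provenance."""

    plane: str
    value_mm: float
    t_ms: float = 0.0
    provenance: str = "saved"  # initial_placement | first_look | intermediate_look | saved

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ConfigurationError(f"unknown biometric plane {self.plane!r}")
        if not (self.value_mm > 0):
            raise DataError(f"non-positive measurement {self.value_mm!r} mm for {self.plane}")


@dataclass(frozen=True)
class ObservedGA:
    """Gestational age implied by a measurement, with the OOR flag."""

    ga_days: float
    out_of_range: bool

    def __float__(self) -> float:
        return self.ga_days


@dataclass(frozen=True)
class PlaneCurve:
    """GA-from-measurement polynomial for one plane plus its valid GA range."""

    plane: str
    coeffs: tuple[float, ...]  # GA weeks = sum c_k * (cm)^k
    valid_ga_days: tuple[float, float]
    bracket_cm: tuple[float, float]

    def ga_days_from_mm(self, value_mm: float) -> float:
        cm = value_mm / 10.0
        weeks = float(np.polynomial.polynomial.polyval(cm, self.coeffs))
        return weeks * 7.0

    def mm_from_ga_days(self, ga_days: float) -> float:
        """Invert the closed form by Brent root-finding (tolerance 0.01 day)."""
        lo, hi = self.bracket_cm
        target = ga_days

        def f(cm: float) -> float:
            return float(np.polynomial.polynomial.polyval(cm, self.coeffs)) * 7.0 - target

        flo, fhi = f(lo), f(hi)
        if flo > 0 or fhi < 0:
            raise NumericalError(
                f"cannot bracket inversion for plane {self.plane} at GA {ga_days:.1f} d "
                f"(bracket {lo}-{hi} cm)"
            )
        cm = brentq(f, lo, hi, xtol=1e-6)
        # xtol is in cm; 1e-6 cm is far below 0.01 day for any plausible slope
        return cm * 10.0


def _as_pair(x) -> tuple[float, float]:
    a, b = float(x[0]), float(x[1])
    if not a < b:
        raise ConfigurationError(f"range {x!r} must be increasing")
    return a, b


@dataclass(frozen=True)
class GrowthStandard:
    """A named, config-driven set of biometry/EFW reference curves."""

    name: str
    planes: Mapping[str, PlaneCurve]
    efw_coeffs: Mapping[str, float]
    efw_domain_mm: Mapping[str, tuple[float, float]]
    efw_mean_log_coeffs: tuple[float, ...]
    efw_log_sd: float
    efw_valid_ga_days: tuple[float, float]
    sga_centile: float = 10.0
    lga_centile: float = 90.0

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "GrowthStandard":
        try:
            planes = {}
            for plane, pc in cfg["planes"].items():
                if plane not in PLANES:
                    raise ConfigurationError(f"unknown plane {plane!r} in standard config")
                planes[plane] = PlaneCurve(
                    plane=plane,
                    coeffs=tuple(float(c) for c in pc["ga_weeks_from_cm"]),
                    valid_ga_days=_as_pair(pc["valid_ga_days"]),
                    bracket_cm=_as_pair(pc["bracket_cm"]),
                )
            efw = cfg["efw"]
            if efw.get("type", "hadlock3_log10_cm") != "hadlock3_log10_cm":
                raise ConfigurationError(f"unsupported EFW formula type {efw.get('type')!r}")
            ref = cfg["efw_for_ga"]
            return cls(
                name=str(cfg["name"]),
                planes=planes,
                efw_coeffs={k: float(efw[k]) for k in ("intercept", "hc", "ac", "fl", "ac_fl")},
                efw_domain_mm={p: _as_pair(v) for p, v in efw["domain_mm"].items()},
                efw_mean_log_coeffs=tuple(float(c) for c in ref["mean_log_coeffs"]),
                efw_log_sd=float(ref["log_sd"]),
                efw_valid_ga_days=_as_pair(ref["valid_ga_days"]),
                sga_centile=float(cfg.get("centile_cutoffs", {}).get("sga", 10.0)),
                lga_centile=float(cfg.get("centile_cutoffs", {}).get("lga", 90.0)),
            )
        except KeyError as exc:  # missing block/field
            raise ConfigurationError(f"growth-standard config missing key {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GrowthStandard":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- GA <-> measurement ----------------------------------------------

    def _curve(self, plane: str) -> PlaneCurve:
        try:
            return self.planes[plane]
        except KeyError:
            raise ConfigurationError(
                f"standard {self.name!r} has no coefficients for plane {plane!r}"
            ) from None

    def ga_from_measurement(self, plane: str, value_mm: float) -> ObservedGA:
        """GA (days) implied by a measurement; extrapolated and flagged if OOR."""
        if not (value_mm > 0):
            raise DataError(f"non-positive measurement {value_mm!r} mm for {plane}")
        curve = self._curve(plane)
        ga = curve.ga_days_from_mm(value_mm)
        lo, hi = curve.valid_ga_days
        return ObservedGA(ga_days=ga, out_of_range=not (lo <= ga <= hi))

    def measurement_from_ga(self, plane: str, ga_days: float) -> float:
        """Expected measurement (mm) at a GA; the simulator's forward curve."""
        return self._curve(plane).mm_from_ga_days(float(ga_days))

    def valid_ga_range(self, plane: str) -> tuple[float, float]:
        return self._curve(plane).valid_ga_days

    # -- EFW ---------------------------------------------------------------

    def efw(self, hc_mm: float, ac_mm: float, fl_mm: float) -> float:
        """Estimated fetal weight (g) from the three-plane log10 formula."""
        vals = {"HC": hc_mm, "AC": ac_mm, "FL": fl_mm}
        for plane, v in vals.items():
            if v is None or not math.isfinite(v) or v <= 0:
                raise DataError(f"EFW requires a positive {plane} measurement, got {v!r}")
        c = self.efw_coeffs
        hc, ac, fl = hc_mm / 10.0, ac_mm / 10.0, fl_mm / 10.0
        log10_g = c["intercept"] + c["hc"] * hc + c["ac"] * ac + c["fl"] * fl + c["ac_fl"] * ac * fl
        return float(10.0 ** log10_g)

    def efw_in_domain(self, hc_mm: float, ac_mm: float, fl_mm: float) -> bool:
        vals = {"HC": hc_mm, "AC": ac_mm, "FL": fl_mm}
        return all(self.efw_domain_mm[p][0] <= v <= self.efw_domain_mm[p][1] for p, v in vals.items())

    # -- EFW-for-GA reference ---------------------------------------------

    def _mean_log_efw(self, ga_days: float) -> float:
        weeks = ga_days / 7.0
        return float(np.polynomial.polynomial.polyval(weeks, self.efw_mean_log_coeffs))

    def efw_zscore(self, efw_g: float, ga_days: float) -> float:
        """Z-score of an EFW against the EFW-for-GA reference at a given GA.

        Z = (ln EFW - mean ln EFW at GA) / SD(ln EFW); the reference is
        extrapolated outside its valid GA range (use :meth:`efw_reference_oor`
        to test the flag).
        """
        if not (efw_g > 0):
            raise DataError(f"non-positive EFW {efw_g!r} g")
        return (math.log(efw_g) - self._mean_log_efw(ga_days)) / self.efw_log_sd

    def efw_reference_oor(self, ga_days: float) -> bool:
        lo, hi = self.efw_valid_ga_days
        return not (lo <= ga_days <= hi)

    def efw_centile(self, efw_g: float, ga_days: float) -> float:
        """Centile (0-100) of an EFW at a GA under the log-normal reference."""
        return float(norm.cdf(self.efw_zscore(efw_g, ga_days)) * 100.0)

    def median_efw(self, ga_days: float) -> float:
        """Reference median EFW (g) at a GA (Z = 0)."""
        return float(math.exp(self._mean_log_efw(ga_days)))

    def classify_size(self, efw_g: float, ga_days: float) -> str:
        """SGA / AGA / LGA by centile with strict cutoffs (boundary -> AGA)."""
        centile = self.efw_centile(efw_g, ga_days)
        if centile < self.sga_centile:
            return SGA
        if centile > self.lga_centile:
            return LGA
        return AGA


# ---------------------------------------------------------------------------
# registry

def _builtin_dir():
    return resources.files("scanbias") / "standards"


def available_standards() -> list[str]:
    """Names of growth standards shipped with the package."""
    return sorted(p.name[: -len(".yaml")] for p in _builtin_dir().iterdir() if p.name.endswith(".yaml"))


def load_standard(name_or_path: str = "hadlock") -> GrowthStandard:
    """Load a growth standard by built-in name or YAML path."""
    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml"} and p.exists():
        return GrowthStandard.from_yaml(p)
    builtin = _builtin_dir() / f"{name_or_path}.yaml"
    if builtin.is_file():
        return GrowthStandard.from_dict(yaml.safe_load(builtin.read_text()))
    raise ConfigurationError(f"unknown growth standard {name_or_path!r}")


def observed_ga(m: BiometricMeasurement, std: GrowthStandard) -> ObservedGA:
    """Observed GA (days) for one measurement — the value the machine displays."""
    return std.ga_from_measurement(m.plane, m.value_mm)
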