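"""Dual-luciferase reporter analysis.

Renilla luminescence (driven by a reporter carrying either a completely
matched, CM, or a tandem seed-matched, SM, target site) is normalized by
firefly luminescence per replicate; sample ratios relative to an unrelated
control siRNA give the relative luciferase activity in percent.

Two derived quantities follow:

* Substantial off-target activity (SOA) rescales how much a chemical
  modification restores SM-reporter expression relative to the unmodified
  siRNA::

      SOA (%) = (rel_modified − rel_unmodified) / (100 − rel_unmodified) × 100

  SOA is 0 when the modification changes nothing and 100 when it abolishes
  the off-target repression entirely.  Values are reported as computed, not
  clamped.

* IC50 by bracketing log-linear interpolation between the adjacent tested
  concentrations that straddle 50% inhibition::

      IC50 = 10 ^ ( log10(A/B) · (50 − C)/(D − C) + log10(B) )

  with A the concentration whose inhibition D is below 50% and B the
  concentration whose inhibition C is above 50%.  No sigmoidal model is fit.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import AssayError


@dataclass(frozen=True)
class ReporterMeasurement:
    """One well: raw Renilla and firefly luminescence for a condition."""

    sirna_id: str
    reporter: str  # "CM" | "SM"
    concentration: float  # nM
    renilla: float
    firefly: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.renilla <= 0 or self.firefly <= 0:
            raise AssayError(
                f"{self.sirna_id}: luminescence must be positive "
                f"(renilla={self.renilla}, firefly={self.firefly})")
        if self.concentration < 0:
            raise AssayError(f"{self.sirna_id}: negative concentration")

    @property
    def ratio(self) -> float:
        return self.renilla / self.firefly


@dataclass
class RelativeActivity:
    value: float  # % of control
    sd: float  # %
    n: int


@dataclass
class SOAResult:
    value: float  # %
    rel_modified: float
    rel_unmodified: float


@dataclass
class IC50Result:
    points: list[tuple[float, float]]  # (concentration nM, inhibition %)
    ic50: Optional[float]  # nM; None when not estimable
    bracket: Optional[tuple[float, float, float, float]]  # (A, B, C, D)

    @property
    def estimable(self) -> bool:
        return self.ic50 is not None


def relative_activity(
    samples: Sequence[ReporterMeasurement],
    controls: Sequence[ReporterMeasurement],
) -> RelativeActivity:
    """Sample mean Renilla/firefly ratio over control mean ratio, in percent.

    The SD is propagated from the sample replicates (SD of per-replicate
    ratios scaled by the control mean).
    """
    if not samples or not controls:
        raise AssayError("need at least one sample and one control replicate")
    sample_ratios = [m.ratio for m in samples]
    control_mean = statistics.fmean(m.ratio for m in controls)
    value = statistics.fmean(sample_ratios) / control_mean * 100.0
    sd = (statistics.stdev(sample_ratios) / control_mean * 100.0
          if len(sample_ratios) > 1 else 0.0)
    return RelativeActivity(value=value, sd=sd, n=len(sample_ratios))


def soa(rel_modified: float, rel_unmodified: float) -> SOAResult:
    """Substantial off-target activity from two relative activities (%)."""
    if rel_unmodified == 100.0:
        raise AssayError(
            "SOA undefined: unmodified relative activity equals 100% "
            "(zero off-target repression to restore)")
    value = (rel_modified - rel_unmodified) / (100.0 - rel_unmodified) * 100.0
    return SOAResult(value=value, rel_modified=rel_modified,
                     rel_unmodified=rel_unmodified)


def ic50(points: Sequence[tuple[float, float]]) -> IC50Result:
    """IC50 from (concentration, inhibition %) points.

    An exact 50% hit returns that concentration.  Otherwise the lowest-
    concentration adjacent pair bracketing 50% is interpolated on the log
    scale.  A curve that never crosses 50% yields a not-estimable result
    (``ic50 is None``), not an exception.
    """
    pts = sorted((float(c), float(i)) for c, i in points)
    if len(pts) < 2:
        raise AssayError("need at least two concentrations")
    if any(c <= 0 for c, _ in pts):
        raise AssayError("concentrations must be positive for log interpolation")

    for conc, inh in pts:
        if inh == 50.0:
            return IC50Result(points=pts, ic50=conc, bracket=None)

    for (conc_lo, inh_lo), (conc_hi, inh_hi) in zip(pts, pts[1:]):
        crosses = (inh_lo - 50.0) * (inh_hi - 50.0) < 0
        if not crosses:
            continue
        # A: concentration with inhibition below 50 (D); B: above 50 (C)
        if inh_lo < 50.0:
            A, D, B, C = conc_lo, inh_lo, conc_hi, inh_hi
        else:
            A, D, B, C = conc_hi, inh_hi, conc_lo, inh_lo
        log_ic50 = math.log10(A / B) * (50.0 - C) / (D - C) + math.log10(B)
        return IC50Result(points=pts, ic50=10.0 ** log_ic50, bracket=(A, B, C, D))

    return IC50Result(points=pts, ic50=None, bracket=None)
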