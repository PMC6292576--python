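"""Lethal end point detection and cohort survival summaries.

Two stage-appropriate death signatures are detected from the integrated
trait series:

* **Osmotic failure** (early stages): the embryo loses osmotic control,
  swelling rapidly then shrinking — a transient area peak.  The area
  series is smoothed with a rolling median (window 3); a lethal peak is a
  local maximum at least ``(1 + delta)`` times the pre-peak baseline
  median, followed by a sustained decline back to (or below) baseline.
  Death time is the peak time.

* **Activity cessation** (later stages, with functioning hearts): cardiac
  and gross-movement energy in the physiological band collapses.  The
  baseline is the median energy of the first ``k`` recordings; death is
  the first time the summed band energy stays below ``theta * baseline``
  for ``m`` consecutive recordings.  The persistence requirement rejects
  transient dips such as diapause-like pauses.

Embryos with no qualifying event are censored at the last observation.
Cohort survival uses the simple empirical proportion (all embryos share
the observation window); LT percentiles are read off the survival curve
by linear interpolation of the first crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: recognised developmental-stage labels and their primary detection
#: method; the earliest stage combines both signatures
STAGE_METHODS = {
    "E3": "area_peak",
    "E7": "energy_drop",
    "E9": "energy_drop",
    "E11": "energy_drop",
}


@dataclass(frozen=True)
class EndpointParams:
    """Detection thresholds (defaults robust on generator-scale noise)."""

    delta: float = 0.3      # area peak must exceed baseline by 30%
    baseline_k: int = 6     # recordings forming the energy baseline
    theta: float = 0.25     # energy must fall below theta * baseline
    persistence_m: int = 3  # consecutive recordings below threshold


@dataclass
class EndpointResult:
    """Per-embryo time-to-death call (or censoring)."""

    embryo_id: str
    stage: str
    death_time_h: float          # NaN when censored/undetermined
    censored: bool
    method: str                  # area_peak | energy_drop | combined | none
    diagnostics: dict = field(default_factory=dict)

    @property
    def died(self) -> bool:
        return not self.censored and np.isfinite(self.death_time_h)


def _rolling_median3(x: np.ndarray) -> np.ndarray:
    return (
        pd.Series(x).rolling(window=3, center=True, min_periods=1).median().to_numpy()
    )


def detect_endpoint_area_peak(
    times_h: Sequence[float],
    areas: Sequence[float],
    params: EndpointParams = EndpointParams(),
) -> tuple[float, dict]:
    """Detect an osmotic-failure area spike; NaN death time if censored.

    Returns ``(death_time_h, diagnostics)``.  Monotone growth never
    qualifies: a peak must both exceed the pre-peak baseline median by
    ``delta`` and be followed by a sustained decline reaching baseline.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(areas, dtype=float)
    if len(t) < 5:
        raise ValidationError("area-peak detection needs >= 5 timepoints")
    s = _rolling_median3(a)
    for i in range(1, len(s) - 1):
        if not np.isfinite(s[i]):
            continue
        pre = s[:i][np.isfinite(s[:i])]
        if len(pre) == 0:
            continue
        baseline = float(np.median(pre))
        if baseline <= 0 or s[i] < (1 + params.delta) * baseline:
            continue
        if not (s[i] >= s[i - 1] and s[i] >= s[i + 1]):
            continue
        post = s[i + 1 :]
        post_f = post[np.isfinite(post)]
        if len(post_f) == 0:
            continue
        m = min(params.persistence_m, len(post_f))
        declining = np.all(post_f[:m] < s[i])
        returns_to_baseline = float(np.min(post_f)) <= baseline
        if declining and returns_to_baseline:
            return float(t[i]), {
                "peak_ratio": float(s[i] / baseline),
                "baseline": baseline,
                "peak_index": i,
            }
    return float("nan"), {}


def detect_endpoint_energy_drop(
    times_h: Sequence[float],
    energies: Sequence[float],
    params: EndpointParams = EndpointParams(),
) -> tuple[float, dict]:
    """Detect a sustained collapse of in-band spectral energy.

    Death is the first recording at which the energy stays below
    ``theta * baseline`` for ``m`` consecutive recordings; a lone dip
    followed by recovery is censored.  Raising ``theta`` can only move a
    call earlier or leave it unchanged (monotone in the threshold).
    """
    t = np.asarray(times_h, dtype=float)
    e = np.asarray(energies, dtype=float)
    if len(t) < 5:
        raise ValidationError("energy-drop detection needs >= 5 timepoints")
    k = min(params.baseline_k, len(e))
    base_window = e[:k][np.isfinite(e[:k])]
    if len(base_window) == 0:
        return float("nan"), {"reason": "baseline all-NaN"}
    baseline = float(np.median(base_window))
    if baseline <= 0:
        return float("nan"), {"reason": "non-positive baseline"}
    thr = params.theta * baseline
    m = params.persistence_m
    below = np.isfinite(e) & (e < thr)
    run = 0
    for i in range(len(e)):
        run = run + 1 if below[i] else 0
        if run >= m:
            start = i - m + 1
            return float(t[start]), {
                "baseline": baseline,
                "energy_ratio": float(e[start] / baseline),
                "drop_index": start,
            }
    return float("nan"), {"baseline": baseline}


def identify_lethal_endpoints(
    traits: pd.DataFrame,
    stage: str,
    embryo_id: str = "",
    params: EndpointParams = EndpointParams(),
    energy_column: str = "band_energy",
    area_column: str = "area_mean",
) -> EndpointResult:
    """Stage-appropriate lethal end point for one embryo's trait series.

    Early (E3) embryos die by osmotic failure, so the area-peak detector
    is primary with the energy-drop detector as fallback (a combination
    of the two); later stages use the energy drop alone.  The method that
    produced the call is recorded.
    """
    stage = stage.strip().upper()
    if stage not in STAGE_METHODS:
        raise ValidationError(
            f"unknown stage {stage!r}; expected one of {sorted(STAGE_METHODS)}"
        )
    t = np.asarray(traits.index, dtype=float)
    if STAGE_METHODS[stage] == "area_peak":
        death, diag = detect_endpoint_area_peak(t, traits[area_column], params)
        method = "area_peak"
        if not np.isfinite(death) and energy_column in traits:
            death, diag = detect_endpoint_energy_drop(
                t, traits[energy_column], params
            )
            method = "combined" if np.isfinite(death) else "area_peak"
    else:
        death, diag = detect_endpoint_energy_drop(t, traits[energy_column], params)
        method = "energy_drop"
    censored = not np.isfinite(death)
    return EndpointResult(
        embryo_id=embryo_id,
        stage=stage,
        death_time_h=death,
        censored=censored,
        method=method if not censored else "none",
        diagnostics=diag,
    )


@dataclass
class SurvivalCurve:
    """Empirical cohort survival on a time grid."""

    times_h: np.ndarray
    surviving: np.ndarray   # proportion in [0, 1], non-increasing
    n_at_risk: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.surviving) > 1e-12):
            raise ValidationError("survival proportion must be non-increasing")


def survival_curve(
    results: Sequence[EndpointResult],
    time_grid_h: Sequence[float] | None = None,
) -> SurvivalCurve:
    """Empirical survival proportion over time.

    Deaths reduce the surviving proportion at their death time; censored
    embryos leave the risk set at their last observation but are never
    counted as deaths.  With a shared observation window this is the
    plain proportion surviving.
    """
    if not results:
        raise ValidationError("need at least one endpoint result")
    deaths = np.array([r.death_time_h for r in results if r.died])
    n = len(results)
    if time_grid_h is None:
        upper = np.nanmax(deaths) if len(deaths) else 1.0
        time_grid_h = np.unique(np.concatenate([[0.0], deaths, [upper]]))
    grid = np.asarray(time_grid_h, dtype=float)
    surviving = np.array(
        [1.0 - np.sum(deaths <= t) / n for t in grid]
    )
    at_risk = np.array([n - np.sum(deaths < t) for t in grid])
    return SurvivalCurve(times_h=grid, surviving=surviving, n_at_risk=at_risk)


def lt_percentiles(
    curve: SurvivalCurve, levels: Sequence[float] = (25, 50, 75)
) -> dict[float, float]:
    """Lethal-time percentiles: hours at which p% of the cohort has died.

    The empirical curve is a left-continuous step function: survival holds
    its value until the next death time, so the first grid time at which
    survival has reached 1 - p/100 *is* the crossing time (a cohort dying
    entirely at 10 h has LT50 = 10 h, not an interpolated midpoint).  NaN
    when the curve never reaches the level.  Whenever all are defined,
    LT25 <= LT50 <= LT75.
    """
    out = {}
    t, s = curve.times_h, curve.surviving
    for p in levels:
        if not 0 < p < 100:
            raise ValidationError("LT levels must be in (0, 100)")
        target = 1.0 - p / 100.0
        idx = np.flatnonzero(s <= target + 1e-12)
        out[p] = float(t[idx[0]]) if len(idx) else float("nan")
    return out
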