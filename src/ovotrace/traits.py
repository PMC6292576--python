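"""Integration of per-frame measures into per-timepoint and global traits.

Per recording: size statistics (min/max/mean area over valid frames),
movement (summed frame-to-frame Euclidean centroid displacement — gross
path length, not net displacement) and the spectral band energies carried
through from the block spectra.  Per embryo: growth rate (OLS slope of
mean area against hours) and cumulative movement.  Timepoints with zero
valid frames become all-NaN rows and are never dropped, so time axes stay
aligned across embryos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .segmentation import FrameMeasures
from .signals_spectra import BandEnergy

#: columns always present in a trait row (band energies are appended)
TRAIT_COLUMNS = [
    "area_min",
    "area_max",
    "area_mean",
    "movement",
    "mean_distance_moved",
    "n_valid_frames",
    "total_energy",
]


def integrate_timepoint(
    frame_measures: Sequence[FrameMeasures],
    band_energy: BandEnergy | None = None,
    scale: float | None = None,
) -> dict:
    """Collapse one recording's frame measures into a trait row.

    Areas are converted to um^2 and movement to um when ``scale`` (um/px)
    is given, else left in pixel units.  Movement sums displacement over
    consecutive *valid* frame pairs only.  A recording with no valid frame
    yields an all-NaN row (the timepoint is retained by callers).
    """
    s = scale if scale else 1.0
    s2 = s * s
    areas = np.array([fm.area for fm in frame_measures if fm.valid])
    row = {c: np.nan for c in TRAIT_COLUMNS}
    row["n_valid_frames"] = int(len(areas))
    if len(areas):
        row["area_min"] = float(areas.min()) * s2
        row["area_max"] = float(areas.max()) * s2
        row["area_mean"] = float(areas.mean()) * s2
        movement = 0.0
        n_steps = 0
        prev = None
        for fm in frame_measures:
            if not fm.valid:
                prev = None
                continue
            if prev is not None:
                movement += float(
                    np.hypot(
                        fm.centroid[0] - prev[0], fm.centroid[1] - prev[1]
                    )
                )
                n_steps += 1
            prev = fm.centroid
        row["movement"] = movement * s
        row["mean_distance_moved"] = movement * s / n_steps if n_steps else 0.0
    if band_energy is not None:
        row["total_energy"] = band_energy.total_energy
        for i in range(len(band_energy.energy)):
            lo, hi = band_energy.band_edges[i], band_energy.band_edges[i + 1]
            row[f"energy_{lo:g}_{hi:g}Hz"] = float(band_energy.energy[i])
    return row


def build_trait_table(rows: Sequence[dict], times_h: Sequence[float]) -> pd.DataFrame:
    """Assemble trait rows into a time-indexed table (hours)."""
    if len(rows) != len(times_h):
        raise ValidationError("one trait row per timepoint required")
    df = pd.DataFrame(list(rows), index=pd.Index(times_h, name="time_h"))
    return df


@dataclass
class GrowthRate:
    """OLS growth estimate: area per hour, with uncertainty."""

    slope: float
    stderr: float
    intercept: float
    n_points: int
    reason: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.slope)


def growth_rate(series: pd.DataFrame, column: str = "area_mean") -> GrowthRate:
    """Growth rate: OLS slope of mean area against time in hours.

    NaN timepoints are excluded pairwise; fewer than 3 finite points gives
    an undefined (NaN) rate with a reason code.
    """
    t = np.asarray(series.index, dtype=float)
    y = np.asarray(series[column], dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    if ok.sum() < 3:
        return GrowthRate(
            slope=np.nan,
            stderr=np.nan,
            intercept=np.nan,
            n_points=int(ok.sum()),
            reason="fewer than 3 finite timepoints",
        )
    if np.allclose(y[ok], y[ok][0]):
        return GrowthRate(
            slope=0.0, stderr=0.0, intercept=float(y[ok][0]), n_points=int(ok.sum())
        )
    res = stats.linregress(t[ok], y[ok])
    return GrowthRate(
        slope=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        n_points=int(ok.sum()),
    )


@dataclass
class CumulativeMovement:
    total: float
    n_missing: int


def cumulative_movement(series: pd.DataFrame) -> CumulativeMovement:
    """Sum of per-timepoint movement; NaNs skipped but counted."""
    m = np.asarray(series["movement"], dtype=float)
    missing = int(np.sum(~np.isfinite(m)))
    return CumulativeMovement(total=float(np.nansum(m)), n_missing=missing)


def trait_summary(series: pd.DataFrame) -> dict:
    """Per-embryo global summary row (growth rate, movement)."""
    g = growth_rate(series)
    cm = cumulative_movement(series)
    mdm = np.asarray(series["mean_distance_moved"], dtype=float)
    return {
        "growth_rate": g.slope,
        "growth_rate_stderr": g.stderr,
        "cumulative_movement": cm.total,
        "mean_distance_moved": float(np.nanmean(mdm)) if np.isfinite(mdm).any() else np.nan,
        "n_missing_timepoints": cm.n_missing,
    }
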