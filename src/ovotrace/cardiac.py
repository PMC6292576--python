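"""Cardiac-frequency identification and ontogeny modelling.

The heart occupies only part of the embryo and is often hidden as the
embryo moves, so no single region can be trusted: instead, every block
spectrum is searched for its in-band PSD peak, blocks whose peak stands
out from the in-band background (peak >= 3x the in-band median PSD)
qualify, and the reported estimate is the power-weighted median of the
qualifying blocks' peak frequencies.  When no block qualifies the
estimate is NaN — the heart was not visible, not "frequency zero".

Ontogeny models per embryo: ordinary least squares (linear kind, suited
to a steadily accelerating tubular heart) or a continuous single-breakpoint
piecewise-linear fit (segmented kind, suited to hearts whose rate first
rises steeply then plateaus).  The breakpoint is chosen by exhaustive
search over interior observed timepoints, which is deterministic and
serves as its own brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .experiment_io import ImageSequence
from .segmentation import EggROI, locate_egg
from .signals_spectra import (
    Spectrum,
    SpectrumSet,
    WelchParams,
    blockwise_signals,
    compute_spectra,
)

#: default physiological band, Hz: excludes DC/rotation drift below and
#: Nyquist-adjacent noise above, and covers both a ~1.5 Hz snail heart
#: and a ~3.5 Hz amphipod heart
DEFAULT_BAND = (0.5, 5.0)

#: a block qualifies when its in-band peak is at least this multiple of
#: the in-band median PSD
QUALITY_FLOOR_RATIO = 3.0


@dataclass
class CardiacEstimate:
    """Cardiac frequency identified at one timepoint."""

    timepoint: int
    frequency_hz: float          # NaN when no block qualifies
    power: float                 # PSD at the accepted peak
    source_block: tuple[int, int] | None  # (level, block index)
    quality: float               # in [0, 1]; 1 - median/peak at the source


def _block_peak(spec: Spectrum, band: tuple[float, float]):
    """In-band peak frequency, power and quality of one block spectrum.

    A maximum sitting on the first or last in-band frequency bin is not a
    peak: it is out-of-band power (centroid drift below, Nyquist-adjacent
    noise above) truncated by the band boundary, and is rejected.
    """
    sel = (spec.frequencies > band[0]) & (spec.frequencies <= band[1])
    if sel.sum() < 3:
        return None
    psd = spec.psd[sel]
    freqs = spec.frequencies[sel]
    if not np.isfinite(psd).all() or psd.max() <= 0:
        return None
    k = int(np.argmax(psd))
    if k == 0 or k == len(psd) - 1:
        return None
    peak = float(psd[k])
    med = float(np.median(psd))
    quality = 1.0 - med / peak if peak > 0 else 0.0
    return float(freqs[k]), peak, quality


def identify_cardiac_frequency(
    spectra: SpectrumSet,
    band: tuple[float, float] = DEFAULT_BAND,
    timepoint: int = 0,
    quality_floor_ratio: float = QUALITY_FLOOR_RATIO,
) -> CardiacEstimate:
    """Identify the cardiac frequency of one recording from block spectra.

    ``band`` is the physiological (fmin, fmax) window in Hz.  Returns a
    NaN-frequency estimate with quality 0 when no block's peak clears the
    acceptance floor.
    """
    fmin, fmax = band
    if not (0 < fmin < fmax):
        raise ValidationError("band must satisfy 0 < fmin < fmax")
    nyq = spectra.fs / 2.0
    if fmax >= nyq + 1e-9:
        raise ValidationError(f"band max {fmax} Hz must be below Nyquist {nyq} Hz")

    # quality floor expressed on the [0, 1] scale: peak >= r * median
    # corresponds to quality 1 - 1/r
    floor = 1.0 - 1.0 / quality_floor_ratio

    cands = []  # (freq, power, quality, (level, block))
    for key, spec in spectra.available().items():
        got = _block_peak(spec, band)
        if got is None:
            continue
        freq, power, quality = got
        if quality >= floor:
            cands.append((freq, power, quality, key))
    if not cands:
        return CardiacEstimate(
            timepoint=timepoint,
            frequency_hz=float("nan"),
            power=float("nan"),
            source_block=None,
            quality=0.0,
        )
    cands.sort(key=lambda c: c[0])
    freqs = np.array([c[0] for c in cands])
    weights = np.array([c[1] for c in cands])
    cum = np.cumsum(weights)
    j = int(np.searchsorted(cum, 0.5 * cum[-1]))
    chosen = cands[j]
    return CardiacEstimate(
        timepoint=timepoint,
        frequency_hz=chosen[0],
        power=chosen[1],
        source_block=chosen[3],
        quality=chosen[2],
    )


def estimate_sequence_heart_rate(
    sequence: ImageSequence,
    roi: EggROI | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    welch: WelchParams | None = None,
) -> CardiacEstimate:
    """Cardiac frequency of one recording, straight from the frames.

    Runs egg localisation (unless an ROI is supplied), blockwise signal
    extraction and Welch estimation, then identifies the cardiac
    frequency — the frequency-domain path only, no per-frame embryo
    segmentation.
    """
    if roi is None:
        roi = locate_egg(sequence)
    signals = blockwise_signals(sequence, roi)
    spectra = compute_spectra(signals, welch)
    return identify_cardiac_frequency(
        spectra, band, timepoint=sequence.timepoint_index
    )


@dataclass
class CardiacModel:
    """Fitted cardiac ontogeny model for one embryo."""

    kind: str                      # linear | segmented
    intercept: float = float("nan")
    slope: float = float("nan")    # Hz/h (linear)
    breakpoint_h: float = float("nan")
    slope_left: float = float("nan")
    slope_right: float = float("nan")
    value_at_breakpoint: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    reason: str = ""

    @property
    def defined(self) -> bool:
        return not self.reason

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "linear":
            return self.intercept + self.slope * t
        left = self.value_at_breakpoint + self.slope_left * (t - self.breakpoint_h)
        right = self.value_at_breakpoint + self.slope_right * (t - self.breakpoint_h)
        return np.where(t <= self.breakpoint_h, left, right)


def _fit_linear(t: np.ndarray, y: np.ndarray) -> CardiacModel:
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return CardiacModel(
        kind="linear",
        intercept=float(coef[0]),
        slope=float(coef[1]),
        rss=float(resid @ resid),
        n_points=len(t),
    )


def _fit_segmented(t: np.ndarray, y: np.ndarray) -> CardiacModel:
    # continuous hinge basis: y = b0 + b1*(t - bp) + b2*max(0, t - bp);
    # exhaustive breakpoint grid over interior observed timepoints keeps
    # the fit deterministic (two points minimum on each side)
    best = None
    for bp in np.unique(t)[2:-2]:
        x = t - bp
        A = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        rss = float(resid @ resid)
        if best is None or rss < best[0]:
            best = (rss, bp, coef)
    rss, bp, coef = best
    b0, b1, b2 = (float(c) for c in coef)
    return CardiacModel(
        kind="segmented",
        breakpoint_h=float(bp),
        slope_left=b1,
        slope_right=b1 + b2,
        value_at_breakpoint=b0,
        rss=rss,
        n_points=len(t),
    )


def fit_cardiac_model(
    times_h: Sequence[float],
    frequencies_hz: Sequence[float],
    kind: str = "segmented",
) -> CardiacModel:
    """Fit a cardiac ontogeny model to per-timepoint frequency estimates.

    Requires >= 5 finite estimates for a linear fit, >= 7 for segmented;
    otherwise returns an undefined model with a reason code.  A segmented
    fit never has larger residual sum of squares than the linear fit of
    the same data (the hinge basis nests the straight line).
    """
    if kind not in ("linear", "segmented"):
        raise ValidationError(f"unknown model kind {kind!r}")
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(frequencies_hz, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    need = 5 if kind == "linear" else 7
    if len(t) < need:
        return CardiacModel(
            kind=kind,
            n_points=len(t),
            reason=f"needs >= {need} finite estimates, got {len(t)}",
        )
    order = np.argsort(t)
    t, y = t[order], y[order]
    if kind == "linear":
        return _fit_linear(t, y)
    if len(np.unique(t)) < 7:
        return CardiacModel(
            kind=kind, n_points=len(t), reason="too few distinct timepoints"
        )
    return _fit_segmented(t, y)


def heart_rate_report(
    embryo_series: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    kind: str = "segmented",
) -> pd.DataFrame:
    """Per-embryo cardiac summary table.

    ``embryo_series`` maps embryo id to (times_h, frequency estimates).
    Rows carry the rate series summary and fitted model parameters; an
    embryo with no qualifying estimates gets NaN parameters and a reason.
    Deterministic for identical input.
    """
    rows = []
    for eid, (t, f) in embryo_series.items():
        f = np.asarray(f, dtype=float)
        model = fit_cardiac_model(t, f, kind=kind)
        finite = f[np.isfinite(f)]
        rows.append(
            {
                "embryo_id": eid,
                "n_estimates": int(len(finite)),
                "mean_rate_hz": float(finite.mean()) if len(finite) else np.nan,
                "min_rate_hz": float(finite.min()) if len(finite) else np.nan,
                "max_rate_hz": float(finite.max()) if len(finite) else np.nan,
                "model_kind": model.kind,
                "intercept_hz": model.intercept,
                "slope_hz_per_h": model.slope,
                "breakpoint_h": model.breakpoint_h,
                "slope_left_hz_per_h": model.slope_left,
                "slope_right_hz_per_h": model.slope_right,
                "rss": model.rss,
                "reason": model.reason,
            }
        )
    return pd.DataFrame(rows)
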