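"""Multiresolution blockwise intensity signals and Welch spectra.

Each recording's egg ROI bounding box is tiled with L x L grids at levels
1, 2, 4, 8 and 16; the mean pixel intensity of every block (restricted to
pixels inside the ROI ellipse) forms one time series per block.  Grid
boundaries at level L are ``floor(i * side / L)``, so the partitions nest
exactly across the 1-2-4-8-16 chain and the pixel-count-weighted mean of a
block's four children always reproduces the parent value.  The grids are
anchored to the (static) egg ROI rather than the moving embryo, keeping
block identity stable across frames — a fixed spatial reference is what
makes per-block frequency analysis meaningful.

Block signals are turned into one-sided power spectral densities with
Welch's method (Hann window, segment length min(256, N), 50% overlap,
constant detrend — the cited estimator's standard defaults; at 20 fps and
600 frames the bin width is ~0.078 Hz, ample for cardiac bands).  Short
NaN gaps from failed frames are linearly interpolated (<= 5 frames);
longer gaps mark the spectrum unavailable, which propagates as NaN traits
rather than exceptions.

Band energies integrate the PSD over contiguous frequency bands
(trapezoid with interpolated band edges, so refining a partition never
changes the total).  "Total energy" — the sum over all bands — measures
the power of grey-level fluctuation at all temporal frequencies and is
the package's holistic activity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .errors import ValidationError
from .experiment_io import ImageSequence
from .segmentation import EggROI

DEFAULT_LEVELS = (1, 2, 4, 8, 16)


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator settings (None nperseg means min(256, N))."""

    nperseg: int | None = None
    overlap_frac: float = 0.5
    window: str = "hann"
    detrend: str = "constant"
    max_gap: int = 5  # longest NaN run repaired by linear interpolation


@dataclass
class Spectrum:
    """One-sided PSD of one block signal, or an unavailability marker."""

    frequencies: np.ndarray | None
    psd: np.ndarray | None
    params: WelchParams = field(default_factory=WelchParams)
    available: bool = True
    reason: str = ""

    @classmethod
    def unavailable(cls, reason: str, params: WelchParams | None = None):
        return cls(
            frequencies=None,
            psd=None,
            params=params or WelchParams(),
            available=False,
            reason=reason,
        )

    @property
    def nyquist_hz(self) -> float:
        if not self.available:
            return float("nan")
        return float(self.frequencies[-1])


@dataclass
class BlockSignalSet:
    """Blockwise mean-intensity time series at each grid level.

    ``levels[L]`` is an (L*L, n_frames) array in row-major block order;
    blocks with no ROI pixel are NaN rows.  ``counts[L]`` holds each
    block's ROI pixel count (the hierarchy weights).
    """

    levels: dict[int, np.ndarray]
    counts: dict[int, np.ndarray]
    timestamps: np.ndarray
    bbox: tuple[int, int, int, int]

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class SpectrumSet:
    """Welch PSDs for every block at every level of one recording."""

    spectra: dict[tuple[int, int], Spectrum]
    fs: float
    params: WelchParams

    def at(self, level: int, block: int) -> Spectrum:
        return self.spectra[(level, block)]

    def available(self) -> dict[tuple[int, int], Spectrum]:
        return {k: s for k, s in self.spectra.items() if s.available}


def _partition_edges(side: int, level: int) -> np.ndarray:
    return (np.arange(level) * side) // level


def blockwise_signals(
    sequence: ImageSequence,
    roi: EggROI,
    levels: Iterable[int] = DEFAULT_LEVELS,
) -> BlockSignalSet:
    """Mean intensity per grid block per frame, inside the ROI ellipse."""
    levels = tuple(sorted(set(int(L) for L in levels)))
    if not set(levels) <= {1, 2, 4, 8, 16}:
        raise ValidationError(f"levels must be within {{1,2,4,8,16}}, got {levels}")
    roi.validate_bounds(sequence.frame_shape)
    top, left, h, w = roi.bbox()
    frames = sequence.frames[:, top : top + h, left : left + w].astype(np.float64)
    mask = roi.mask(sequence.frame_shape)[top : top + h, left : left + w]
    masked = frames * mask  # NaN frames propagate through the sums

    out_levels: dict[int, np.ndarray] = {}
    out_counts: dict[int, np.ndarray] = {}
    for L in levels:
        re = _partition_edges(h, L)
        ce = _partition_edges(w, L)
        sums = np.add.reduceat(np.add.reduceat(masked, re, axis=1), ce, axis=2)
        counts = np.add.reduceat(
            np.add.reduceat(mask.astype(np.int64), re, axis=0), ce, axis=1
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts[None]
        means[:, counts == 0] = np.nan
        out_levels[L] = means.reshape(len(frames), L * L).T.copy()
        out_counts[L] = counts.reshape(L * L).copy()
    return BlockSignalSet(
        levels=out_levels,
        counts=out_counts,
        timestamps=np.asarray(sequence.timestamps, dtype=float),
        bbox=(top, left, h, w),
    )


def _fill_gaps(x: np.ndarray, max_gap: int) -> np.ndarray | None:
    """Linearly interpolate NaN runs of length <= max_gap (edge runs are
    extended from the nearest finite value); None when irreparable."""
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if finite.all():
        return x
    if not finite.any():
        return None
    idx = np.flatnonzero(~finite)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if max(len(r) for r in runs) > max_gap:
        return None
    xp = np.flatnonzero(finite)
    return np.interp(np.arange(len(x)), xp, x[finite])


def welch_psd(
    x: np.ndarray, fs: float, params: WelchParams | None = None
) -> Spectrum:
    """One-sided Welch PSD of one signal (density normalisation).

    Deterministic; NaN-gapped or too-short signals yield an unavailable
    spectrum instead of raising.
    """
    params = params or WelchParams()
    if fs <= 0:
        raise ValidationError("fs must be > 0")
    x = np.asarray(x, dtype=float)
    filled = _fill_gaps(x, params.max_gap)
    if filled is None:
        return Spectrum.unavailable("gap in signal exceeds max_gap", params)
    n = len(filled)
    if n < 8:  # not even two 50%-overlapping 4-sample segments of signal
        return Spectrum.unavailable("signal too short", params)
    nperseg = min(params.nperseg or 256, n)
    freqs, psd = sps.welch(
        filled,
        fs=fs,
        window=params.window,
        nperseg=nperseg,
        noverlap=int(nperseg * params.overlap_frac),
        detrend=params.detrend,
        scaling="density",
        return_onesided=True,
    )
    return Spectrum(frequencies=freqs, psd=psd, params=params)


def compute_spectra(
    signals: BlockSignalSet, params: WelchParams | None = None
) -> SpectrumSet:
    """Welch PSD of every block signal at every level."""
    params = params or WelchParams()
    fs = signals.fs
    spectra: dict[tuple[int, int], Spectrum] = {}
    for L, arr in signals.levels.items():
        n = arr.shape[1]
        good_rows, good_idx = [], []
        for b in range(arr.shape[0]):
            filled = _fill_gaps(arr[b], params.max_gap)
            if filled is None:
                spectra[(L, b)] = Spectrum.unavailable(
                    "gap in signal exceeds max_gap", params
                )
            elif n < 8:
                spectra[(L, b)] = Spectrum.unavailable("signal too short", params)
            else:
                good_rows.append(filled)
                good_idx.append(b)
        if good_rows:
            nperseg = min(params.nperseg or 256, n)
            freqs, psd = sps.welch(
                np.stack(good_rows),
                fs=fs,
                window=params.window,
                nperseg=nperseg,
                noverlap=int(nperseg * params.overlap_frac),
                detrend=params.detrend,
                scaling="density",
                return_onesided=True,
                axis=-1,
            )
            for b, p in zip(good_idx, psd):
                spectra[(L, b)] = Spectrum(
                    frequencies=freqs, psd=p, params=params
                )
    return SpectrumSet(spectra=spectra, fs=fs, params=params)


@dataclass
class BandEnergy:
    """PSD integrated over contiguous frequency bands."""

    band_edges: np.ndarray      # n_bands + 1 ascending edges, Hz
    energy: np.ndarray          # per band
    total_energy: float
    relative_energy: np.ndarray  # band / total; NaN when total == 0


def default_band_edges(nyquist_hz: float, width_hz: float = 0.5) -> np.ndarray:
    """Contiguous bins of ``width_hz`` from 0 up to the Nyquist frequency.

    The last band absorbs any remainder (no sliver band is created when
    the Nyquist frequency sits within ~1% of a bin edge).
    """
    edges = np.arange(0.0, nyquist_hz, width_hz)
    if len(edges) > 1 and nyquist_hz - edges[-1] < 0.01 * width_hz:
        edges = edges[:-1]
    return np.append(edges, nyquist_hz)


def band_energies(
    spectrum: Spectrum, band_edges: Sequence[float]
) -> BandEnergy:
    """Integrate a PSD over a band partition (trapezoid quadrature).

    Band edges must ascend and lie within [0, Nyquist].  Energies are
    additive under partition refinement because each band's energy is a
    difference of the same cumulative integral.
    """
    edges = np.asarray(band_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValidationError("need at least two band edges")
    if not np.all(np.diff(edges) > 0):
        raise ValidationError("band edges must be strictly ascending")
    if not spectrum.available:
        n_bands = len(edges) - 1
        return BandEnergy(
            band_edges=edges,
            energy=np.full(n_bands, np.nan),
            total_energy=float("nan"),
            relative_energy=np.full(n_bands, np.nan),
        )
    nyq = spectrum.nyquist_hz
    if edges[0] < -1e-12 or edges[-1] > nyq + 1e-9:
        raise ValidationError(
            f"band edges must lie within [0, {nyq:.4g}] Hz"
        )
    freqs, psd = spectrum.frequencies, spectrum.psd
    cum = np.concatenate([[0.0], cumulative_trapezoid(psd, freqs)])
    cum_at = np.interp(np.clip(edges, freqs[0], freqs[-1]), freqs, cum)
    energy = np.diff(cum_at)
    total = float(energy.sum())
    if total > 0:
        relative = energy / total
    else:
        relative = np.full_like(energy, np.nan)
    return BandEnergy(
        band_edges=edges,
        energy=energy,
        total_energy=total,
        relative_energy=relative,
    )


def band_power(spectrum: Spectrum, fmin: float, fmax: float) -> float:
    """PSD integral over a single (fmin, fmax] band (NaN if unavailable)."""
    if not spectrum.available:
        return float("nan")
    return float(band_energies(spectrum, [fmin, fmax]).energy[0])
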