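"""End-to-end per-embryo analysis and batch orchestration.

One embryo's recordings flow through: egg localisation (first recording)
-> per-frame segmentation -> blockwise signals -> Welch spectra -> band
energies -> trait integration -> cardiac-frequency identification, and
the results land in a PhenomeDataset written to HDF5.  Batch runs isolate
failures per embryo: one unreadable embryo is marked failed and the run
continues; the manifest (written even on partial failure) accounts for
every embryo as analysed, failed or excluded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .cardiac import DEFAULT_BAND, identify_cardiac_frequency
from .errors import OvotraceError, ValidationError
from .experiment_io import (
    ExperimentLayout,
    ImageSequence,
    PhenomeDataset,
    read_sequence,
    write_dataset,
)
from .segmentation import EggROI, locate_egg, segment_sequence
from .signals_spectra import (
    BandEnergy,
    WelchParams,
    band_energies,
    band_power,
    blockwise_signals,
    compute_spectra,
    default_band_edges,
)
from .traits import build_trait_table, integrate_timepoint, trait_summary

logger = logging.getLogger(__name__)

#: grid level whose summed block energies form the trait energy columns.
#: The whole-ROI (level 1) mean is nearly blind to a constant-brightness
#: embryo moving inside the ROI, so a finer grid is needed to see
#: movement as well as cardiac intensity fluctuation.
ENERGY_LEVEL = 4


def _summed_level_band_energy(
    spectra, level: int, edges: np.ndarray
) -> BandEnergy | None:
    """Sum per-band energies over all available blocks of one level."""
    acc = None
    for (L, b), spec in spectra.available().items():
        if L != level:
            continue
        be = band_energies(spec, edges)
        acc = be.energy if acc is None else acc + be.energy
    if acc is None:
        return None
    total = float(acc.sum())
    return BandEnergy(
        band_edges=edges,
        energy=acc,
        total_energy=total,
        relative_energy=acc / total if total > 0 else np.full_like(acc, np.nan),
    )


def analyse_sequence(
    sequence: ImageSequence,
    roi: EggROI,
    scale: float | None = None,
    welch: WelchParams | None = None,
    cardiac_band: tuple[float, float] = DEFAULT_BAND,
    band_width_hz: float = 0.5,
):
    """Analyse one recording: returns (trait row, cardiac estimate, spectra).

    The trait row gains a ``band_energy`` column holding the summed
    physiological-band energy used by endpoint detection.
    """
    measures = segment_sequence(sequence, roi, scale=scale)
    signals = blockwise_signals(sequence, roi)
    spectra = compute_spectra(signals, welch)
    nyq = spectra.fs / 2.0
    edges = default_band_edges(nyq, band_width_hz)
    summed = _summed_level_band_energy(spectra, ENERGY_LEVEL, edges)
    row = integrate_timepoint(measures, summed, scale=scale)
    band_lo = cardiac_band[0]
    band_hi = min(cardiac_band[1], nyq * 0.98)
    inband = [
        band_power(spec, band_lo, band_hi)
        for (L, b), spec in spectra.available().items()
        if L == ENERGY_LEVEL
    ]
    row["band_energy"] = float(np.nansum(inband)) if inband else np.nan
    estimate = identify_cardiac_frequency(
        spectra, (band_lo, band_hi), timepoint=sequence.timepoint_index
    )
    return row, estimate, spectra


def process_embryo(
    embryo_id: str,
    sequences: Sequence[ImageSequence],
    scale: float | None = None,
    roi: EggROI | None = None,
    welch: WelchParams | None = None,
    cardiac_band: tuple[float, float] = DEFAULT_BAND,
    keep_spectra_levels: Iterable[int] = (1, ENERGY_LEVEL),
) -> PhenomeDataset:
    """Run the full analysis for one embryo's recordings.

    The egg ROI is located once, on the first recording (the capsule is
    static), unless an override ROI is supplied.  Failed recordings
    produce NaN rows, never gaps.
    """
    if not sequences:
        raise ValidationError(f"embryo {embryo_id}: no sequences")
    if roi is None:
        roi = locate_egg(sequences[0])
    times_h, rows = [], []
    cardiac_freqs, cardiac_quality = [], []
    psd_store: dict[int, list] = {L: [] for L in keep_spectra_levels}
    freq_axis = None
    for seq in sequences:
        times_h.append(seq.timestamps[0] / 3600.0)
        try:
            row, est, spectra = analyse_sequence(
                seq, roi, scale=scale, welch=welch, cardiac_band=cardiac_band
            )
        except OvotraceError:
            raise
        except Exception as exc:  # isolate per-recording failures as NaNs
            logger.warning(
                "embryo %s tp %d failed: %s", embryo_id, seq.timepoint_index, exc
            )
            rows.append({})
            cardiac_freqs.append(np.nan)
            cardiac_quality.append(np.nan)
            for L in psd_store:
                psd_store[L].append(None)
            continue
        rows.append(row)
        cardiac_freqs.append(est.frequency_hz)
        cardiac_quality.append(est.quality)
        for L in psd_store:
            block_psds = []
            for b in range(L * L):
                spec = spectra.at(L, b)
                if spec.available:
                    if freq_axis is None:
                        freq_axis = spec.frequencies
                    block_psds.append(spec.psd)
                else:
                    block_psds.append(None)
            psd_store[L].append(block_psds)

    traits = build_trait_table(rows, times_h)

    data_vars: dict[str, xr.DataArray] = {}
    for col in traits.columns:
        unit = (
            "um^2" if col.startswith("area") and scale
            else "px^2" if col.startswith("area")
            else "um" if col in ("movement", "mean_distance_moved") and scale
            else "px" if col in ("movement", "mean_distance_moved")
            else "intensity^2/Hz*Hz" if "energy" in col
            else "count"
        )
        data_vars[col] = xr.DataArray(
            traits[col].to_numpy(dtype=float),
            dims=("time",),
            attrs={"units": unit, "group": "traits"},
        )
    data_vars["cardiac_frequency"] = xr.DataArray(
        np.asarray(cardiac_freqs, dtype=float),
        dims=("time",),
        attrs={"units": "Hz", "group": "cardiac"},
    )
    data_vars["cardiac_quality"] = xr.DataArray(
        np.asarray(cardiac_quality, dtype=float),
        dims=("time",),
        attrs={"units": "dimensionless", "group": "cardiac"},
    )
    coords = {"time": xr.DataArray(np.asarray(times_h), dims=("time",),
                                   attrs={"units": "h"})}
    if freq_axis is not None:
        coords["freq"] = xr.DataArray(
            freq_axis, dims=("freq",), attrs={"units": "Hz"}
        )
        nfreq = len(freq_axis)
        for L, per_tp in psd_store.items():
            arr = np.full((len(times_h), L * L, nfreq), np.nan)
            for ti, blocks in enumerate(per_tp):
                if blocks is None:
                    continue
                for bi, p in enumerate(blocks):
                    if p is not None and len(p) == nfreq:
                        arr[ti, bi] = p
            data_vars[f"psd_level{L}"] = xr.DataArray(
                arr,
                dims=("time", f"block{L}", "freq"),
                attrs={"units": "intensity^2/Hz", "group": "spectra"},
            )

    ds = xr.Dataset(data_vars=data_vars, coords=coords)
    ds.attrs["roi_center_row"] = float(roi.center[0])
    ds.attrs["roi_center_col"] = float(roi.center[1])
    ds.attrs["roi_semi_a"] = float(roi.semi_axes[0])
    ds.attrs["roi_semi_b"] = float(roi.semi_axes[1])
    ds.attrs["roi_angle_deg"] = float(roi.angle_deg)
    ds.attrs["roi_source"] = roi.source
    return PhenomeDataset(embryo_id=embryo_id, data=ds)


@dataclass
class RunManifest:
    """Bookkeeping for one batch run; counts always conserve."""

    config: dict
    version: str = __version__
    total: int = 0
    analysed: int = 0
    failed: int = 0
    excluded: int = 0
    status: dict = field(default_factory=dict)  # embryo id -> status string

    def record(self, embryo_id: str, status: str) -> None:
        assert status in ("analysed", "failed", "excluded")
        self.status[embryo_id] = status
        setattr(self, status, getattr(self, status) + 1)

    @property
    def conserved(self) -> bool:
        return self.analysed + self.failed + self.excluded == self.total

    @property
    def exit_code(self) -> int:
        """0: all analysed; 3: partial; 1: nothing analysed."""
        if self.analysed == self.total - self.excluded and self.total > 0:
            return 0
        return 3 if self.analysed > 0 else 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _load_embryo_sequences(
    embryo_dir: Path, frame_rate: float
) -> list[ImageSequence]:
    tps = sorted(p for p in embryo_dir.iterdir() if p.is_dir())
    if not tps:
        raise ValidationError(f"no recordings under {embryo_dir}")
    return [
        read_sequence(tp, frame_rate=frame_rate,
                      embryo_id=embryo_dir.name, timepoint_index=i)
        for i, tp in enumerate(tps)
    ]


def run_pipeline(
    layout: ExperimentLayout,
    input_dir: str | Path,
    out_dir: str | Path,
    exclude: Iterable[str] = (),
    rois: Mapping[str, EggROI] | None = None,
    cardiac_band: tuple[float, float] = DEFAULT_BAND,
) -> RunManifest:
    """Analyse every embryo of an experiment tree; failures are isolated.

    Writes one HDF5 dataset per embryo plus ``run_manifest.json`` and a
    per-embryo summary CSV (growth rate, mean distance moved, mean heart
    rate) to ``out_dir``.  The manifest is written even when embryos fail.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not input_dir.is_dir():
        raise ValidationError(f"input tree not found: {input_dir}")
    exclude = set(exclude)
    manifest = RunManifest(
        config={
            "input_dir": str(input_dir),
            "scale": layout.scale,
            "species": layout.species,
            "n_timepoints": layout.schedule.n_timepoints,
        },
        total=len(layout.embryo_ids),
    )
    if manifest.total == 0:
        raise ValidationError("experiment has no embryos")
    summary_rows = []
    try:
        for eid in layout.embryo_ids:
            if eid in exclude:
                manifest.record(eid, "excluded")
                continue
            try:
                seqs = _load_embryo_sequences(
                    input_dir / eid, layout.schedule.frame_rate
                )
                pds = process_embryo(
                    eid,
                    seqs,
                    scale=layout.scale,
                    roi=(rois or {}).get(eid),
                    cardiac_band=cardiac_band,
                )
                write_dataset(pds, out_dir / f"{eid}.h5")
                traits = _traits_frame(pds)
                summary = trait_summary(traits)
                summary["embryo_id"] = eid
                summary["mean_heart_rate_hz"] = float(
                    np.nanmean(pds.data["cardiac_frequency"].values)
                ) if np.isfinite(pds.data["cardiac_frequency"].values).any() else np.nan
                summary_rows.append(summary)
                manifest.record(eid, "analysed")
                logger.info("embryo %s analysed", eid)
            except Exception as exc:
                logger.error("embryo %s failed: %s", eid, exc)
                logger.debug("%s", traceback.format_exc())
                manifest.record(eid, "failed")
    finally:
        (out_dir / "run_manifest.json").write_text(manifest.to_json())
        if summary_rows:
            cols = ["embryo_id", "growth_rate", "growth_rate_stderr",
                    "cumulative_movement", "mean_distance_moved",
                    "mean_heart_rate_hz", "n_missing_timepoints"]
            pd.DataFrame(summary_rows)[cols].to_csv(
                out_dir / "embryo_summary.csv", index=False
            )
    return manifest


def _traits_frame(pds: PhenomeDataset) -> pd.DataFrame:
    """Trait table view of a PhenomeDataset (time-indexed DataFrame)."""
    time = np.asarray(pds.data["time"].values, dtype=float)
    cols = {
        name: np.asarray(var.values, dtype=float)
        for name, var in pds.data.data_vars.items()
        if var.dims == ("time",)
    }
    return pd.DataFrame(cols, index=pd.Index(time, name="time_h"))
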