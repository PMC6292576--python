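"""Experiment data model and I/O.

Defines the recording schedule and experiment layout, reads acquired image
sequences (TIFF frames plus optional JSON metadata sidecar), computes
acquisition-schedule expectations, and round-trips per-embryo phenome
datasets through an HDF5 container.

An experiment is a directory tree of per-embryo, per-timepoint image
sequences acquired on a fixed repeating schedule: ``frames_per_sequence``
frames at ``frame_rate`` fps, repeated every ``repeat_interval_min``
minutes for ``n_timepoints`` recordings.  Timepoint counting is always
explicit in the configuration — never inferred from the experiment
duration, because inclusive and exclusive conventions both occur in
practice.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import tifffile
import xarray as xr
import yaml

from .errors import (
    ConfigurationError,
    FormatError,
    FrameReadError,
    MigrationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

LAYOUT_VERSION = 1

#: HDF5 group each variable is filed under, by the ``group`` attr of the
#: variable (falling back to /traits for 1-D time series and /spectra for
#: anything with a frequency dimension).
_KNOWN_GROUPS = ("traits", "spectra", "cardiac", "endpoints")


@dataclass(frozen=True)
class RecordingSchedule:
    """A repeating acquisition schedule.

    Parameters
    ----------
    frames_per_sequence:
        Number of frames in each recording (>= 2).
    frame_rate:
        Acquisition rate within a recording, frames per second.
    repeat_interval_min:
        Minutes between the starts of consecutive recordings.
    n_timepoints:
        Number of recordings per embryo (explicit; >= 1).
    """

    frames_per_sequence: int
    frame_rate: float
    repeat_interval_min: float
    n_timepoints: int

    def __post_init__(self):
        if self.frames_per_sequence < 2:
            raise ValidationError("frames_per_sequence must be >= 2")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        if self.n_timepoints < 1:
            raise ValidationError("n_timepoints must be >= 1")
        if self.repeat_interval_min <= 0:
            raise ValidationError("repeat_interval_min must be > 0")
        if self.sequence_duration_s >= self.repeat_interval_min * 60.0:
            raise ValidationError(
                "sequence duration must fit inside the repeat interval"
            )

    @property
    def sequence_duration_s(self) -> float:
        return self.frames_per_sequence / self.frame_rate

    @property
    def duration_hours(self) -> float:
        """Total schedule span, counting every repeat interval once."""
        return self.n_timepoints * self.repeat_interval_min / 60.0

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate / 2.0

    def timepoint_hours(self) -> np.ndarray:
        """Start time of each recording in hours since experiment start."""
        return np.arange(self.n_timepoints) * self.repeat_interval_min / 60.0


@dataclass(frozen=True)
class ExperimentLayout:
    """Validated description of one experiment.

    ``embryos`` maps embryo id -> treatment label; ``scale`` is microns per
    pixel and converts pixel geometry to physical units (areas via scale**2).
    """

    embryos: Mapping[str, str]
    schedule: RecordingSchedule
    scale: float
    species: str
    roi_size: int

    def __post_init__(self):
        if self.scale <= 0:
            raise ValidationError("scale must be > 0 um/px")
        if self.roi_size <= 0:
            raise ValidationError("roi_size must be > 0 px")
        ids = list(self.embryos)
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate embryo ids")

    @property
    def embryo_ids(self) -> list[str]:
        return list(self.embryos)


_CONFIG_KEYS = {
    "schedule",
    "scale",
    "species",
    "roi_size",
    "embryos",
    "data_dir",
}
_SCHEDULE_KEYS = {
    "frames_per_sequence",
    "frame_rate",
    "repeat_interval_min",
    "n_timepoints",
}


def load_experiment(config_path: str | Path) -> ExperimentLayout:
    """Load and validate an experiment configuration (YAML).

    The config declares the schedule, scale (um/px), species, ROI size and
    either an explicit embryo roster (list of ids, or of ``{id, treatment}``
    mappings) or a ``data_dir`` whose subdirectory names become embryo ids.
    Unknown keys are rejected so typos fail loudly.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigurationError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")

    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    missing = {"schedule", "scale", "species"} - set(raw)
    if missing:
        raise ConfigurationError(f"missing config keys: {sorted(missing)}")

    sched_raw = raw["schedule"]
    unknown = set(sched_raw) - _SCHEDULE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown schedule keys: {sorted(unknown)}")
    try:
        schedule = RecordingSchedule(
            frames_per_sequence=int(sched_raw["frames_per_sequence"]),
            frame_rate=float(sched_raw["frame_rate"]),
            repeat_interval_min=float(sched_raw["repeat_interval_min"]),
            n_timepoints=int(sched_raw["n_timepoints"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"schedule missing key: {exc}") from exc

    embryos: dict[str, str] = {}
    if "embryos" in raw and raw["embryos"] is not None:
        for entry in raw["embryos"]:
            if isinstance(entry, str):
                eid, treatment = entry, ""
            else:
                eid = str(entry["id"])
                treatment = str(entry.get("treatment", ""))
            if eid in embryos:
                raise ConfigurationError(f"duplicate embryo id: {eid}")
            embryos[eid] = treatment
    elif "data_dir" in raw:
        data_dir = Path(raw["data_dir"])
        if not data_dir.is_dir():
            raise ConfigurationError(f"data_dir not found: {data_dir}")
        for sub in sorted(p for p in data_dir.iterdir() if p.is_dir()):
            embryos[sub.name] = ""

    return ExperimentLayout(
        embryos=embryos,
        schedule=schedule,
        scale=float(raw["scale"]),
        species=str(raw["species"]),
        roi_size=int(raw.get("roi_size", 750)),
    )


@dataclass
class ImageSequence:
    """One recording: an ordered frame stack plus per-frame timestamps.

    ``frames`` is (n_frames, H, W), integer (<= 16-bit) or float;
    ``timestamps`` are seconds since experiment start, strictly increasing.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    embryo_id: str = ""
    timepoint_index: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (T, H, W) stack")
        if len(self.timestamps) != len(self.frames):
            raise ValidationError("one timestamp per frame required")
        if np.issubdtype(self.frames.dtype, np.integer):
            if self.frames.dtype.itemsize > 2:
                raise ValidationError("integer frames must be <= 16-bit")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_rate(self) -> float:
        """Median inverse frame interval (Hz)."""
        dt = np.median(np.diff(self.timestamps))
        return 1.0 / float(dt)


_FRAME_INDEX_RE = re.compile(r"(\d+)")


def _metadata_timestamps(meta: dict, n_frames: int) -> np.ndarray | None:
    """Extract per-frame elapsed seconds from a metadata dict.

    Accepts ``{"elapsed_ms": [...]}`` or a MicroManager-style
    ``{"frames": [{"ElapsedTime-ms": ...}, ...]}``.
    """
    if "elapsed_ms" in meta:
        ms = np.asarray(meta["elapsed_ms"], dtype=float)
    elif "frames" in meta:
        try:
            ms = np.asarray(
                [f["ElapsedTime-ms"] for f in meta["frames"]], dtype=float
            )
        except (KeyError, TypeError):
            return None
    else:
        return None
    if len(ms) != n_frames:
        raise FormatError(
            f"metadata has {len(ms)} timestamps for {n_frames} frames"
        )
    return ms / 1000.0


def read_sequence(
    path: str | Path,
    frame_rate: float | None = None,
    embryo_id: str = "",
    timepoint_index: int = 0,
) -> ImageSequence:
    """Read one image sequence from disk.

    ``path`` is either a directory of single-frame TIFFs (ordered by the
    numeric index embedded in each filename, falling back to lexicographic
    order) or a single multipage TIFF.  A ``metadata.json`` sidecar with
    per-frame elapsed milliseconds provides timestamps; without it, a
    nominal clock is synthesized from ``frame_rate`` (logged, since the
    synthesized clock hides acquisition jitter).
    """
    path = Path(path)
    meta: dict | None = None

    if path.is_dir():
        frame_files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: (
                int(m.group(1)) if (m := _FRAME_INDEX_RE.search(p.stem)) else -1,
                p.name,
            ),
        )
        if not frame_files:
            raise FormatError(f"no TIFF frames in {path}")
        frames = []
        shape = None
        for i, fp in enumerate(frame_files):
            try:
                frame = tifffile.imread(fp)
            except Exception as exc:
                raise FrameReadError(i, f"frame {i} ({fp.name}): {exc}") from exc
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise FormatError(
                    f"frame {i} shape {frame.shape} != first frame {shape}"
                )
            frames.append(frame)
        stack = np.stack(frames)
        meta_path = path / "metadata.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
    else:
        if not path.exists():
            raise FormatError(f"sequence not found: {path}")
        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        meta_path = path.with_suffix(".json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())

    timestamps = None
    if meta is not None:
        timestamps = _metadata_timestamps(meta, len(stack))
    if timestamps is None:
        if frame_rate is None or frame_rate <= 0:
            raise ConfigurationError(
                "no timestamp metadata and no frame_rate to synthesize a clock"
            )
        timestamps = np.arange(len(stack)) / float(frame_rate)
        logger.info(
            "synthesized clock for %s (%d frames @ %.3g fps)",
            path, len(stack), frame_rate,
        )

    return ImageSequence(
        frames=stack,
        timestamps=timestamps,
        embryo_id=embryo_id,
        timepoint_index=timepoint_index,
    )


def expected_image_count(n_embryos: int, schedule: RecordingSchedule) -> int:
    """Total images an experiment is expected to acquire.

    Multiplicative in every factor:
    ``n_embryos * frames_per_sequence * n_timepoints``.
    """
    if n_embryos < 0:
        raise ValidationError("n_embryos must be >= 0")
    return n_embryos * schedule.frames_per_sequence * schedule.n_timepoints


# ---------------------------------------------------------------------------
# PhenomeDataset: per-embryo results container
# ---------------------------------------------------------------------------


@dataclass
class PhenomeDataset:
    """Per-embryo results: an xarray Dataset plus identity metadata.

    Variables share a ``time`` axis (recording index, coord in hours);
    spectral variables add block and frequency dimensions.  Every variable
    must carry a ``units`` attribute, and may carry a ``group`` attribute
    naming its HDF5 group (traits, spectra, cardiac, endpoints).
    """

    embryo_id: str
    data: xr.Dataset = field(default_factory=xr.Dataset)

    def __post_init__(self):
        for name, var in self.data.data_vars.items():
            if "units" not in var.attrs:
                raise ValidationError(f"variable {name!r} missing units attr")
            grp = var.attrs.get("group")
            if grp is not None and grp not in _KNOWN_GROUPS:
                raise ValidationError(f"variable {name!r} unknown group {grp!r}")

    def identical(self, other: "PhenomeDataset") -> bool:
        return self.embryo_id == other.embryo_id and self.data.identical(
            other.data
        )


def _default_group(var: xr.DataArray) -> str:
    return "spectra" if any("freq" in d for d in var.dims) else "traits"


def write_dataset(dataset: PhenomeDataset, path: str | Path) -> None:
    """Write a PhenomeDataset to an HDF5 file (one embryo per file).

    Layout: ``/coords/<name>`` for coordinates; variables filed under
    ``/traits``, ``/spectra``, ``/cardiac`` or ``/endpoints``; dims and
    attrs stored as JSON attributes.  Floats round-trip bit-exactly.
    """
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["layout_version"] = LAYOUT_VERSION
        fh.attrs["embryo_id"] = dataset.embryo_id
        fh.attrs["dataset_attrs"] = json.dumps(dict(dataset.data.attrs))
        cgrp = fh.create_group("coords")
        for name, coord in dataset.data.coords.items():
            ds = cgrp.create_dataset(str(name), data=np.asarray(coord.values))
            ds.attrs["dims"] = json.dumps([str(d) for d in coord.dims])
            ds.attrs["var_attrs"] = json.dumps(dict(coord.attrs))
        for name, var in dataset.data.data_vars.items():
            group = var.attrs.get("group", _default_group(var))
            grp = fh.require_group(group)
            ds = grp.create_dataset(str(name), data=np.asarray(var.values))
            ds.attrs["dims"] = json.dumps([str(d) for d in var.dims])
            ds.attrs["var_attrs"] = json.dumps(dict(var.attrs))


def read_dataset(path: str | Path) -> PhenomeDataset:
    """Read a PhenomeDataset written by :func:`write_dataset`."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("layout_version", -1))
        if version != LAYOUT_VERSION:
            raise MigrationError(
                f"dataset layout version {version} != supported {LAYOUT_VERSION}"
            )
        coords = {}
        for name, ds in fh["coords"].items():
            dims = tuple(json.loads(ds.attrs["dims"]))
            arr = ds[()]
            da = xr.DataArray(arr, dims=dims)
            da.attrs.update(json.loads(ds.attrs["var_attrs"]))
            coords[name] = da
        data_vars = {}
        for group in _KNOWN_GROUPS:
            if group not in fh:
                continue
            for name, ds in fh[group].items():
                dims = tuple(json.loads(ds.attrs["dims"]))
                da = xr.DataArray(ds[()], dims=dims)
                da.attrs.update(json.loads(ds.attrs["var_attrs"]))
                data_vars[name] = da
        xds = xr.Dataset(data_vars=data_vars, coords=coords)
        xds.attrs.update(json.loads(fh.attrs["dataset_attrs"]))
        return PhenomeDataset(embryo_id=str(fh.attrs["embryo_id"]), data=xds)
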