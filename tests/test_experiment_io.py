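"""Experiment configuration, sequence reading, schedule arithmetic, and
HDF5 dataset round trips."""

import json

import numpy as np
import pytest
import tifffile
import xarray as xr
import yaml

from ovotrace import (
    ConfigurationError,
    FormatError,
    FrameReadError,
    ImageSequence,
    MigrationError,
    PhenomeDataset,
    RecordingSchedule,
    ValidationError,
    expected_image_count,
    load_experiment,
    read_dataset,
    read_sequence,
    write_dataset,
)


def _write_config(path, **overrides):
    cfg = {
        "schedule": {
            "frames_per_sequence": 600,
            "frame_rate": 20.0,
            "repeat_interval_min": 60.0,
            "n_timepoints": 25,
        },
        "scale": 1.0,
        "species": "radix",
        "roi_size": 750,
        "embryos": [{"id": f"e{i:02d}", "treatment": "ctl"} for i in range(48)],
    }
    cfg.update(overrides)
    path.write_text(yaml.safe_dump(cfg))
    return path


class TestSchedule:
    def test_hourly_snail_schedule_validates(self):
        s = RecordingSchedule(600, 20.0, 60.0, 25)
        assert s.sequence_duration_s == pytest.approx(30.0)
        assert s.nyquist_hz == pytest.approx(10.0)
        assert s.duration_hours == pytest.approx(25.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frames_per_sequence=1),
            dict(frame_rate=0.0),
            dict(n_timepoints=0),
            dict(repeat_interval_min=0.4),  # 600 frames @ 20 fps do not fit
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        base = dict(
            frames_per_sequence=600,
            frame_rate=20.0,
            repeat_interval_min=60.0,
            n_timepoints=25,
        )
        base.update(kwargs)
        with pytest.raises(ValidationError):
            RecordingSchedule(**base)


class TestLoadExperiment:
    def test_full_roster_layout(self, tmp_path):
        layout = load_experiment(_write_config(tmp_path / "c.yaml"))
        assert len(layout.embryo_ids) == 48
        assert layout.schedule.frames_per_sequence == 600
        assert layout.schedule.frame_rate == 20.0
        assert layout.schedule.repeat_interval_min == 60.0

    def test_empty_roster_is_valid(self, tmp_path):
        layout = load_experiment(_write_config(tmp_path / "c.yaml", embryos=[]))
        assert layout.embryo_ids == []
        assert expected_image_count(0, layout.schedule) == 0

    def test_negative_scale_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            load_experiment(_write_config(tmp_path / "c.yaml", scale=-1))

    def test_unknown_keys_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError, match="unknown"):
            load_experiment(_write_config(tmp_path / "c.yaml", typo_key=1))

    def test_duplicate_ids_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError, match="duplicate"):
            load_experiment(
                _write_config(tmp_path / "c.yaml", embryos=["a", "a"])
            )

    def test_roster_from_directory_scan(self, tmp_path):
        for name in ("embA", "embB"):
            (tmp_path / "data" / name).mkdir(parents=True)
        cfg = _write_config(tmp_path / "c.yaml", embryos=None,
                            data_dir=str(tmp_path / "data"))
        assert load_experiment(cfg).embryo_ids == ["embA", "embB"]


class TestExpectedImageCount:
    def test_hourly_snail_experiment(self):
        # 48 embryos, 600-frame recordings, 25 hourly timepoints
        s = RecordingSchedule(600, 20.0, 60.0, 25)
        assert expected_image_count(48, s) == 720_000

    def test_amphipod_experiment(self):
        # 4 embryos, 2100-frame recordings, 24 hourly timepoints
        s = RecordingSchedule(2100, 38.0, 60.0, 24)
        assert expected_image_count(4, s) == 201_600

    def test_multiplicative_in_timepoints(self):
        full = RecordingSchedule(600, 20.0, 60.0, 24)
        half = RecordingSchedule(600, 20.0, 60.0, 12)
        assert expected_image_count(10, full) == 2 * expected_image_count(10, half)


class TestImageSequence:
    def test_timestamps_must_strictly_increase(self):
        frames = np.zeros((3, 4, 4), dtype=np.uint16)
        with pytest.raises(ValidationError):
            ImageSequence(frames, np.array([0.0, 1.0, 1.0]))

    def test_frame_count_timestamp_mismatch(self):
        with pytest.raises(ValidationError):
            ImageSequence(np.zeros((3, 4, 4), np.uint16), np.array([0.0, 1.0]))


class TestReadSequence:
    def _write_frames(self, d, n=10, shape=(8, 8)):
        d.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            tifffile.imwrite(
                d / f"frame_{i:04d}.tif",
                np.full(shape, i, dtype=np.uint16),
            )

    def test_metadata_timestamps_used(self, tmp_path):
        d = tmp_path / "seq"
        self._write_frames(d, n=6)
        ms = [0, 50, 100, 151, 200, 250]
        (d / "metadata.json").write_text(json.dumps({"elapsed_ms": ms}))
        seq = read_sequence(d)
        assert np.allclose(seq.timestamps, np.array(ms) / 1000.0)
        # frames come back in acquisition order
        assert [int(f[0, 0]) for f in seq.frames] == list(range(6))

    def test_synthesized_clock_without_metadata(self, tmp_path):
        d = tmp_path / "seq"
        self._write_frames(d, n=10)
        seq = read_sequence(d, frame_rate=20.0)
        assert np.allclose(seq.timestamps, np.arange(10) * 0.05)

    def test_no_metadata_no_fps_is_an_error(self, tmp_path):
        d = tmp_path / "seq"
        self._write_frames(d, n=4)
        with pytest.raises(ConfigurationError):
            read_sequence(d)

    def test_corrupt_frame_reports_its_index(self, tmp_path):
        d = tmp_path / "seq"
        self._write_frames(d, n=10)
        (d / "frame_0003.tif").write_bytes(b"not a tiff")
        with pytest.raises(FrameReadError) as err:
            read_sequence(d, frame_rate=20.0)
        assert err.value.frame_index == 3

    def test_mixed_frame_shapes_rejected(self, tmp_path):
        d = tmp_path / "seq"
        self._write_frames(d, n=4, shape=(8, 8))
        tifffile.imwrite(d / "frame_0004.tif", np.zeros((9, 8), np.uint16))
        with pytest.raises(FormatError, match="shape"):
            read_sequence(d, frame_rate=20.0)


def _demo_dataset(n_time=4, with_nan=True):
    t = np.arange(n_time, dtype=float)
    area = 100.0 + 10 * t
    if with_nan and n_time:
        area[-1] = np.nan
    psd = np.arange(n_time * 4 * 3, dtype=float).reshape(n_time, 4, 3)
    ds = xr.Dataset(
        {
            "area_mean": xr.DataArray(
                area, dims=("time",), attrs={"units": "px^2", "group": "traits"}
            ),
            "psd_level2": xr.DataArray(
                psd,
                dims=("time", "block2", "freq"),
                attrs={"units": "intensity^2/Hz", "group": "spectra"},
            ),
        },
        coords={
            "time": xr.DataArray(t, dims=("time",), attrs={"units": "h"}),
            "freq": xr.DataArray([0.0, 1.0, 2.0], dims=("freq",),
                                 attrs={"units": "Hz"}),
        },
        attrs={"species": "radix"},
    )
    return PhenomeDataset(embryo_id="e01", data=ds)


class TestDatasetRoundTrip:
    def test_round_trip_identity_with_nans(self, tmp_path):
        pds = _demo_dataset()
        write_dataset(pds, tmp_path / "e01.h5")
        back = read_dataset(tmp_path / "e01.h5")
        assert back.identical(pds)
        # NaN mask preserved bit-exactly
        assert np.isnan(back.data["area_mean"].values[-1])

    def test_empty_dataset_round_trips(self, tmp_path):
        pds = _demo_dataset(n_time=0, with_nan=False)
        write_dataset(pds, tmp_path / "empty.h5")
        back = read_dataset(tmp_path / "empty.h5")
        assert back.data.sizes["time"] == 0
        assert back.identical(pds)

    def test_incompatible_layout_version_raises(self, tmp_path):
        import h5py

        path = tmp_path / "old.h5"
        write_dataset(_demo_dataset(), path)
        with h5py.File(path, "a") as fh:
            fh.attrs["layout_version"] = 999
        with pytest.raises(MigrationError):
            read_dataset(path)

    def test_variables_require_units(self):
        ds = xr.Dataset(
            {"x": xr.DataArray(np.arange(3.0), dims=("time",))},
            coords={"time": np.arange(3.0)},
        )
        with pytest.raises(ValidationError, match="units"):
            PhenomeDataset(embryo_id="e", data=ds)
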