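"""Blockwise signals, Welch spectra and band energies against direct
per-pixel and DFT oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovotrace import (
    ImageSequence,
    ValidationError,
    band_energies,
    blockwise_signals,
    compute_spectra,
    default_band_edges,
    welch_psd,
)
from ovotrace.segmentation import EggROI
from ovotrace.signals_spectra import WelchParams, _fill_gaps


def _seq(frames, fs=20.0):
    frames = np.asarray(frames)
    return ImageSequence(frames, np.arange(len(frames)) / fs)


def _rect_roi(h, w):
    # largest inscribed ellipse of the test image
    return EggROI(
        center=((h - 1) / 2, (w - 1) / 2),
        semi_axes=((h - 1) / 2, (w - 1) / 2),
    )


def _brute_force_block_means(frame, mask, level):
    """Per-pixel oracle: mean over each block of the nested partition."""
    h, w = frame.shape
    re = (np.arange(level + 1) * h) // level
    ce = (np.arange(level + 1) * w) // level
    out = np.full(level * level, np.nan)
    for i in range(level):
        for j in range(level):
            m = mask[re[i]:re[i + 1], ce[j]:ce[j + 1]]
            v = frame[re[i]:re[i + 1], ce[j]:ce[j + 1]]
            if m.any():
                out[i * level + j] = v[m].mean()
    return out


class TestBlockwiseSignals:
    def test_constant_field_constant_blocks(self):
        frames = np.full((12, 32, 32), 500, dtype=np.uint16)
        sig = blockwise_signals(_seq(frames), _rect_roi(32, 32))
        for L, arr in sig.levels.items():
            finite = arr[np.isfinite(arr)]
            assert np.allclose(finite, 500.0)

    def test_checkerboard_matches_per_pixel_oracle(self):
        h = w = 32
        frame = np.full((h, w), 100, dtype=np.uint16)
        frame[:16, 16:] = 300
        frame[16:, :16] = 300
        frames = np.repeat(frame[None], 12, axis=0)
        roi = _rect_roi(h, w)
        mask = roi.mask((h, w))
        sig = blockwise_signals(_seq(frames), roi, levels=(1, 2))
        top, left, hh, ww = sig.bbox
        crop = frame[top:top + hh, left:left + ww]
        mcrop = mask[top:top + hh, left:left + ww]
        for L in (1, 2):
            oracle = _brute_force_block_means(crop, mcrop, L)
            got = sig.levels[L][:, 0]
            assert got == pytest.approx(oracle, nan_ok=True)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_hierarchy_identity_random_frames(self, seed):
        """Pixel-count-weighted mean of level-2L children equals parent."""
        rng = np.random.default_rng(seed)
        h = int(rng.integers(20, 50))
        w = int(rng.integers(20, 50))
        frames = rng.integers(0, 4096, size=(3, h, w)).astype(np.uint16)
        roi = EggROI(center=((h - 1) / 2, (w - 1) / 2),
                     semi_axes=(h * 0.45, w * 0.45))
        sig = blockwise_signals(_seq(frames), roi, levels=(1, 2, 4, 8, 16))
        for L in (1, 2, 4, 8):
            parent = sig.levels[L]
            child = sig.levels[2 * L]
            ccounts = sig.counts[2 * L].reshape(2 * L, 2 * L)
            cvals = child.T.reshape(-1, 2 * L, 2 * L)
            for i in range(L):
                for j in range(L):
                    blk_counts = ccounts[2*i:2*i+2, 2*j:2*j+2]
                    blk_vals = cvals[:, 2*i:2*i+2, 2*j:2*j+2]
                    tot = blk_counts.sum()
                    got = parent[i * L + j]
                    if tot == 0:
                        assert np.isnan(got).all()
                        continue
                    weighted = (
                        np.nansum(blk_vals * blk_counts, axis=(1, 2)) / tot
                    )
                    assert got == pytest.approx(weighted, rel=1e-10)

    def test_zero_pixel_blocks_are_nan(self):
        # tiny ellipse inside a big box: corner blocks have no ROI pixels
        roi = EggROI(center=(15.5, 15.5), semi_axes=(4.0, 4.0))
        frames = np.full((10, 32, 32), 100, np.uint16)
        sig = blockwise_signals(_seq(frames), roi, levels=(16,))
        assert np.isnan(sig.levels[16]).any()

    def test_invalid_level_rejected(self):
        frames = np.zeros((10, 16, 16), np.uint16)
        with pytest.raises(ValidationError):
            blockwise_signals(_seq(frames), _rect_roi(16, 16), levels=(3,))


class TestWelchPsd:
    def test_constant_signal_near_zero_power(self):
        spec = welch_psd(np.full(600, 1234.5), fs=20.0)
        assert spec.available
        assert np.all(spec.psd[spec.frequencies > 0] < 1e-12 * 1234.5**2)

    @pytest.mark.parametrize("fs,f0", [(20.0, 1.5), (38.0, 3.5), (20.0, 0.8)])
    def test_tone_peak_matches_dft_argmax_bin(self, fs, f0):
        n = 600
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f0 * t)
        spec = welch_psd(x, fs)
        # independent oracle: plain DFT argmax over positive frequencies
        dft_freqs = np.fft.rfftfreq(n, 1 / fs)
        dft_peak = dft_freqs[np.argmax(np.abs(np.fft.rfft(x))[1:]) + 1]
        welch_peak = spec.frequencies[np.argmax(spec.psd[1:]) + 1]
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(welch_peak - dft_peak) <= df
        assert abs(welch_peak - f0) <= df

    def test_white_noise_parseval_consistency(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 3.0, size=2000)
        spec = welch_psd(x, fs=20.0)
        df = spec.frequencies[1] - spec.frequencies[0]
        # one-sided density integrates to the signal variance
        assert np.trapezoid(spec.psd, dx=df) == pytest.approx(
            np.var(x), rel=0.10
        )

    def test_short_nan_gaps_interpolated(self):
        t = np.arange(600) / 20.0
        x = np.sin(2 * np.pi * 1.5 * t)
        x[100:104] = np.nan
        spec = welch_psd(x, 20.0)
        assert spec.available
        peak = spec.frequencies[np.argmax(spec.psd[1:]) + 1]
        assert peak == pytest.approx(1.5, abs=0.08)

    def test_long_gap_marks_unavailable(self):
        x = np.sin(np.arange(600) * 0.3)
        x[100:120] = np.nan
        spec = welch_psd(x, 20.0)
        assert not spec.available
        assert "gap" in spec.reason

    def test_all_nan_unavailable(self):
        assert not welch_psd(np.full(600, np.nan), 20.0).available

    def test_gap_filling_is_linear(self):
        x = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
        assert _fill_gaps(x, max_gap=2) == pytest.approx([0, 1, 2, 3, 4])


class TestBandEnergies:
    def _tone_spectrum(self, f0=1.5, fs=20.0, n=600):
        t = np.arange(n) / fs
        return welch_psd(np.sin(2 * np.pi * f0 * t), fs)

    def test_tone_energy_concentrates_in_peak_band(self):
        spec = self._tone_spectrum()
        edges = default_band_edges(spec.nyquist_hz, 0.5)
        be = band_energies(spec, edges)
        # the band containing 1.5 Hz plus its neighbours hold >= 90%
        k = np.searchsorted(edges, 1.5, side="left") - 1
        neighbourhood = be.energy[max(0, k - 1):k + 2].sum()
        assert neighbourhood / be.total_energy >= 0.90

    def test_relative_energies_sum_to_one(self):
        spec = self._tone_spectrum()
        be = band_energies(spec, default_band_edges(spec.nyquist_hz))
        assert be.relative_energy.sum() == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_doubling_quadruples_total(self):
        fs, n = 20.0, 600
        t = np.arange(n) / fs
        e1 = band_energies(
            welch_psd(np.sin(2 * np.pi * 1.5 * t), fs),
            [0.0, 5.0, 10.0],
        )
        e2 = band_energies(
            welch_psd(2 * np.sin(2 * np.pi * 1.5 * t), fs),
            [0.0, 5.0, 10.0],
        )
        assert e2.total_energy == pytest.approx(4 * e1.total_energy, rel=1e-9)
        assert e2.relative_energy == pytest.approx(e1.relative_energy, rel=1e-9)

    def test_refining_partition_preserves_total(self):
        spec = self._tone_spectrum()
        coarse = band_energies(spec, [0.0, 5.0, 10.0])
        fine = band_energies(spec, default_band_edges(10.0, 0.5))
        assert fine.total_energy == pytest.approx(coarse.total_energy, rel=1e-12)

    def test_edges_beyond_nyquist_rejected(self):
        spec = self._tone_spectrum()
        with pytest.raises(ValidationError):
            band_energies(spec, [0.0, 12.0])

    def test_non_ascending_edges_rejected(self):
        spec = self._tone_spectrum()
        with pytest.raises(ValidationError):
            band_energies(spec, [0.0, 2.0, 1.0])

    def test_unavailable_spectrum_gives_nan_bands(self):
        spec = welch_psd(np.full(600, np.nan), 20.0)
        be = band_energies(spec, [0.0, 1.0, 2.0])
        assert np.isnan(be.energy).all() and np.isnan(be.total_energy)


class TestComputeSpectra:
    def test_heart_block_carries_the_tone(self, clean_sequence):
        (seq, truth), spec_syn = clean_sequence
        roi = EggROI(center=(80.0, 80.0), semi_axes=(57.0, 50.0))
        sig = blockwise_signals(seq, roi)
        spectra = compute_spectra(sig)
        # the level-1 (whole ROI) signal must show 1.5 Hz: the heart adds
        # intensity, which survives spatial averaging
        s = spectra.at(1, 0)
        peak = s.frequencies[np.argmax(s.psd[1:]) + 1]
        df = s.frequencies[1] - s.frequencies[0]
        assert abs(peak - spec_syn.heart_base_hz) <= df
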