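"""Coherence, partial coherence, contrasts, band averages, ROI picking."""

import numpy as np
import pytest

from _helpers import csd_of_recording, white_noise_epochs
from silenttrack.connectivity import (CoherenceSpectrum, ContrastSpectrum,
                                      band_average, coherence,
                                      condition_contrast, partial_coherence,
                                      roi_peak_select)
from silenttrack.spectral import CSD, accumulate_csd, default_freq_grid, \
    mtm_spectra
from silenttrack.synthgen import make_common_source_pair


def _csd_from(data_builder, n_epochs=10, seed=0):
    rng = np.random.default_rng(seed)
    ep = white_noise_epochs(rng, n_epochs=n_epochs, n_channels=1,
                            roles=["ocular"])
    data = data_builder(rng, n_epochs)
    ep.data = data
    ep.channel_names = [f"ch{i}" for i in range(data.shape[1])]
    ep.channel_roles = ["neural"] * (data.shape[1] - 1) + ["ocular"]
    return accumulate_csd(mtm_spectra(ep))


class TestCoherence:
    def test_exact_copy_is_one_everywhere(self):
        def build(rng, n_ep):
            x = rng.standard_normal((n_ep, 1, 900))
            return np.concatenate([x, x], axis=1)
        coh = coherence(_csd_from(build), 0, 1)
        assert np.allclose(coh.values, 1.0)

    def test_chance_level_matches_one_over_n_est(self):
        """E[coherence] = 1/n_est for independent channels: mean over bins
        and 20 replicates within +/-50% of 1/50."""
        means = []
        for r in range(20):
            rng = np.random.default_rng(r)
            ep = white_noise_epochs(rng, n_epochs=10)
            csd = accumulate_csd(mtm_spectra(ep))
            means.append(coherence(csd, 0, 1).values.mean())
        assert csd.n_est == 50
        assert 0.5 / 50 < np.mean(means) < 1.5 / 50

    def test_common_sinusoid_high_coherence_at_bin(self):
        t = np.arange(900) / 150.0
        s = np.sin(2 * np.pi * 0.5 * t)

        def build(rng, n_ep):
            noise = 0.05 * rng.standard_normal((n_ep, 2, 900))
            return s[None, None, :] + noise
        coh = coherence(_csd_from(build), 0, 1)
        bin_05 = np.argmin(np.abs(coh.freqs - 0.5))
        assert coh.values[bin_05] > 0.9

    def test_bounded_everywhere(self, rng):
        csd = accumulate_csd(mtm_spectra(white_noise_epochs(rng,
                                                            n_channels=3)))
        for a in range(3):
            for b in range(a + 1, 3):
                v = coherence(csd, a, b).values
                assert np.all((v >= 0) & (v <= 1))

    def test_self_coherence_rejected(self, rng):
        csd = accumulate_csd(mtm_spectra(white_noise_epochs(rng)))
        with pytest.raises(ValueError):
            coherence(csd, 0, 0)


class TestPartialCoherence:
    def test_common_source_removed(self):
        """Channels sharing one latent source: raw in-band coherence is
        high, partializing the (near-clean) ocular copy brings it to
        chance."""
        rec = make_common_source_pair(duration=240, seed=1)
        csd = csd_of_recording(rec)
        raw = coherence(csd, "neural00", "neural01")
        par = partial_coherence(csd, "neural00", "neural01", "ocular")
        band = (raw.freqs >= 0.5) & (raw.freqs <= 2.0)
        assert raw.values[band].mean() > 0.5
        assert par.values[band].mean() <= 2.0 / csd.n_est

    def test_independent_third_channel_is_noop(self):
        """With three independent drivers, partialization changes nothing
        beyond estimation error (paired runs, mean over replicates within
        2 Monte-Carlo SE)."""
        diffs = []
        for r in range(20):
            rec = make_common_source_pair(duration=120, seed=100 + r,
                                          shared=False)
            csd = csd_of_recording(rec)
            raw = coherence(csd, "neural00", "neural01")
            par = partial_coherence(csd, "neural00", "neural01", "ocular")
            diffs.append(par.values - raw.values)
        diffs = np.asarray(diffs)
        mean_band = diffs.mean(axis=1)  # per-replicate mean over bins
        se = mean_band.std(ddof=1) / np.sqrt(len(mean_band))
        assert abs(mean_band.mean()) <= 2 * se + 1e-4
        # per-bin means stay within a multiplicity-adjusted band
        per_bin_se = diffs.std(axis=0, ddof=1) / np.sqrt(diffs.shape[0])
        assert np.all(np.abs(diffs.mean(axis=0)) <= 4 * per_bin_se + 1e-4)

    def test_degenerate_partial_channel_is_noop_with_warning(self):
        def build(rng, n_ep):
            x = rng.standard_normal((n_ep, 2, 900))
            return np.concatenate([x, np.zeros((n_ep, 1, 900))], axis=1)
        csd = _csd_from(build)
        raw = coherence(csd, 0, 1)
        with pytest.warns(RuntimeWarning, match="zero-power"):
            par = partial_coherence(csd, 0, 1, 2)
        assert np.allclose(par.values, raw.values)

    def test_partialization_idempotent(self, rng):
        """Partializing an already-partialized CSD is a no-op (the
        partial channel has zero residual power)."""
        csd = accumulate_csd(mtm_spectra(white_noise_epochs(rng,
                                                            n_channels=3)))
        once = partial_coherence(csd, 0, 1, 2)
        m = csd.matrices
        z = 2
        szz = m[:, z, z][:, None, None]
        projected = m - m[:, :, z][:, :, None] * m[:, z, :][:, None, :] / szz
        csd2 = CSD(matrices=projected, freqs=csd.freqs, n_est=csd.n_est,
                   channel_names=csd.channel_names)
        with pytest.warns(RuntimeWarning):
            twice = partial_coherence(csd2, 0, 1, 2)
        assert np.allclose(twice.values, once.values, atol=1e-10)

    def test_z_must_differ_from_pair(self, rng):
        csd = accumulate_csd(mtm_spectra(white_noise_epochs(rng,
                                                            n_channels=3)))
        with pytest.raises(ValueError):
            partial_coherence(csd, 0, 1, 0)


class TestContrastAndBands:
    freqs = default_freq_grid()

    def _coh(self, values, partialized=None):
        return CoherenceSpectrum(values=np.asarray(values, float),
                                 freqs=self.freqs, pair=("a", "b"),
                                 n_est=50, partialized=partialized)

    def test_equal_spectra_give_zero_contrast(self):
        c = self._coh(np.linspace(0, 0.5, 30))
        assert np.allclose(condition_contrast(c, c).values, 0.0)

    def test_antisymmetry(self, rng):
        a = self._coh(rng.uniform(0, 1, 30))
        b = self._coh(rng.uniform(0, 1, 30))
        assert np.allclose(condition_contrast(a, b).values,
                           -condition_contrast(b, a).values)

    def test_grid_mismatch_rejected(self):
        a = self._coh(np.zeros(30))
        b = CoherenceSpectrum(values=np.zeros(10), freqs=self.freqs[:10],
                              pair=("a", "b"), n_est=50)
        with pytest.raises(ValueError):
            condition_contrast(a, b)

    def test_band_average_constant(self):
        assert band_average(self._coh(np.full(30, 0.3)),
                            (0, 1)) == pytest.approx(0.3)

    def test_band_membership_below_one_hertz(self):
        # bins at k/6 Hz with k/6 < 1: k in 1..5 -> 5 bins
        vals = np.zeros(30)
        vals[:5] = 1.0
        assert band_average(self._coh(vals), (0, 1)) == pytest.approx(1.0)
        assert np.sum((self.freqs >= 0) & (self.freqs < 1 - 1e-9)) == 5

    def test_upper_edge_convention(self):
        vals = np.zeros(30)
        vals[5] = 1.0  # the 1.0 Hz bin
        open_avg = band_average(self._coh(vals), (0, 1))
        closed_avg = band_average(self._coh(vals), (0, 1),
                                  include_upper=True)
        assert open_avg == 0.0
        assert closed_avg == pytest.approx(1.0 / 6.0)

    def test_nan_bins_excluded(self):
        vals = np.full(30, 0.4)
        vals[2] = np.nan
        assert band_average(self._coh(vals), (0, 1)) == pytest.approx(0.4)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_average(self._coh(np.zeros(30)), (20, 30))


class TestRoiPeakSelect:
    freqs = default_freq_grid()

    def _contrast(self, values):
        return ContrastSpectrum(values=np.asarray(values, float),
                                freqs=self.freqs, pair=("x", "envelope"))

    def test_single_channel_roi(self):
        d = {"a": self._contrast(np.zeros(30))}
        assert roi_peak_select(d, ["a"], (0, 1)) == "a"

    def test_all_equal_ties_break_by_order(self):
        d = {k: self._contrast(np.full(30, 0.1)) for k in "abc"}
        assert roi_peak_select(d, ["b", "a", "c"], (0, 1)) == "b"

    def test_strongest_channel_selected_under_noise(self):
        hits = 0
        for r in range(20):
            g = np.random.default_rng(r)
            d = {}
            for ch in ("v1", "a1", "m1"):
                base = g.normal(0, 0.02, 30)
                if ch == "a1":
                    base[:5] += 0.1  # strong sub-1-Hz effect
                d[ch] = self._contrast(base)
            hits += roi_peak_select(d, ["v1", "a1", "m1"], (0, 1)) == "a1"
        assert hits >= 18

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_peak_select({}, [], (0, 1))
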