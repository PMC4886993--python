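"""Peak detection: radial background statistics, component search, saturation."""

import numpy as np
import pytest

from serialmon.geometry import DetectorFrame, build_pixel_maps
from serialmon.peaks import (Peak, PeakSearchParams, compute_radial_statistics,
                             count_saturated_peaks, find_peaks)
from serialmon.synth import generate_sfx_frame


def brute_force_sigma_clip(values, clip_sigma, iterations):
    """Independent per-bin sigma-clip oracle: plain python loop."""
    vals = list(values)
    mean = sum(vals) / len(vals)
    std = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
    for _ in range(iterations):
        kept = [v for v in vals if not v > mean + clip_sigma * std]
        if len(kept) == len(vals):
            break
        vals = kept
        mean = sum(vals) / len(vals)
        std = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
    return mean, std


class TestRadialStatistics:
    def test_uniform_frame_every_bin_mean_c_std_zero(self, maps128):
        frame = DetectorFrame(data=np.full((128, 128), 42.0), timestamp=1.0)
        prof = compute_radial_statistics(frame, maps128.radius_px)
        assert np.allclose(prof.mean[prof.valid], 42.0)
        assert np.allclose(prof.stddev[prof.valid], 0.0)

    def test_outlier_rejected_matches_brute_force_oracle(self):
        # one radial bin: 100 background pixels of 10 plus one outlier 1000
        rng = np.random.default_rng(0)
        values = np.full(101, 10.0)
        values[50] = 1000.0
        # build a frame where all these pixels share one bin (flat radius map)
        data = values.reshape(101, 1)
        radius = np.full((101, 1), 3.4)
        frame = DetectorFrame(data=data, timestamp=1.0)
        params = PeakSearchParams(clip_sigma=3.0, clip_iterations=2)
        prof = compute_radial_statistics(frame, radius, params)
        exp_mean, exp_std = brute_force_sigma_clip(values, 3.0, 2)
        b = int(3.4 // params.radial_bin_px)
        assert prof.mean[b] == pytest.approx(exp_mean)
        assert prof.mean[b] == pytest.approx(10.0)
        assert prof.stddev[b] == pytest.approx(exp_std)
        assert prof.count[b] == 100

    def test_sigma_clip_matches_oracle_on_random_bins(self, maps128):
        rng = np.random.default_rng(7)
        data = rng.normal(10.0, 2.0, (128, 128))
        data[rng.random((128, 128)) < 0.01] += 200.0  # sparse outliers
        frame = DetectorFrame(data=data, timestamp=1.0)
        params = PeakSearchParams(radial_bin_px=4.0, clip_sigma=3.0,
                                  clip_iterations=2)
        prof = compute_radial_statistics(frame, maps128.radius_px, params)
        bins = np.floor(maps128.radius_px / 4.0).astype(int)
        for b in (3, 7, 12):
            exp_mean, exp_std = brute_force_sigma_clip(
                data[bins == b].tolist(), 3.0, 2)
            assert prof.mean[b] == pytest.approx(exp_mean, rel=1e-12)
            assert prof.stddev[b] == pytest.approx(exp_std, rel=1e-9)

    def test_fully_masked_frame_all_bins_invalid(self, maps128):
        frame = DetectorFrame(data=np.ones((128, 128)), timestamp=1.0,
                              valid=np.zeros((128, 128), bool))
        prof = compute_radial_statistics(frame, maps128.radius_px)
        assert not prof.valid.any()

    def test_zero_pixel_bin_flagged_invalid(self):
        radius = np.full((4, 4), 0.5)
        radius[0, 0] = 10.5  # bins 1..9 have no pixels
        frame = DetectorFrame(data=np.ones((4, 4)), timestamp=1.0)
        prof = compute_radial_statistics(frame, radius)
        assert prof.valid[0] and prof.valid[10]
        assert not prof.valid[5]
        assert np.isnan(prof.mean[5])


def threshold_and_label_oracle(data, thresh_map, min_px, max_px):
    """Exhaustive flood-fill on the same frame: independent of find_peaks."""
    above = data > thresh_map
    seen = np.zeros_like(above)
    comps = []
    n_slow, n_fast = data.shape
    for s0 in range(n_slow):
        for f0 in range(n_fast):
            if above[s0, f0] and not seen[s0, f0]:
                stack, comp = [(s0, f0)], []
                seen[s0, f0] = True
                while stack:
                    s, f = stack.pop()
                    comp.append((s, f))
                    for ds in (-1, 0, 1):
                        for df in (-1, 0, 1):
                            ss, ff = s + ds, f + df
                            if (0 <= ss < n_slow and 0 <= ff < n_fast
                                    and above[ss, ff] and not seen[ss, ff]):
                                seen[ss, ff] = True
                                stack.append((ss, ff))
                if min_px <= len(comp) <= max_px:
                    comps.append(sorted(comp))
    return comps


class TestFindPeaks:
    def test_flat_zero_frame_gives_empty_list(self, maps128):
        frame = DetectorFrame(data=np.zeros((128, 128)), timestamp=1.0)
        prof = compute_radial_statistics(frame, maps128.radius_px)
        assert find_peaks(frame, maps128, prof) == []

    def test_single_blob_found_against_flood_fill_oracle(self, maps128):
        rng = np.random.default_rng(11)
        data = rng.normal(0.0, 1.0, (128, 128))
        cs, cf = 40, 70
        for ds in (-1, 0, 1):
            for df in (-1, 0, 1):
                data[cs + ds, cf + df] += 100.0
        frame = DetectorFrame(data=data, timestamp=1.0)
        params = PeakSearchParams(snr_min=8.0, intensity_min=5.0,
                                  pixel_count_min=2, pixel_count_max=60)
        prof = compute_radial_statistics(frame, maps128.radius_px, params)
        peaks = find_peaks(frame, maps128, prof, params)
        assert len(peaks) == 1
        assert abs(peaks[0].centroid_slow - cs) <= 0.5
        assert abs(peaks[0].centroid_fast - cf) <= 0.5
        # oracle: same eligibility map, independent flood fill
        bins = np.floor(maps128.radius_px / params.radial_bin_px).astype(int)
        thr = np.maximum(prof.mean[bins] + 8.0 * prof.stddev[bins], 5.0)
        comps = threshold_and_label_oracle(data, thr, 2, 60)
        assert len(comps) == 1
        assert (peaks[0].seed_slow, peaks[0].seed_fast) in comps[0]
        assert peaks[0].n_pixels == len(comps[0])

    def test_component_below_min_size_discarded(self, maps128):
        data = np.zeros((128, 128))
        data[10, 10] = 500.0
        data[10, 11] = 500.0  # a 2-pixel component
        frame = DetectorFrame(data=data, timestamp=1.0)
        params = PeakSearchParams(snr_min=5.0, intensity_min=1.0,
                                  pixel_count_min=3, pixel_count_max=60)
        prof = compute_radial_statistics(frame, maps128.radius_px, params)
        assert find_peaks(frame, maps128, prof, params) == []

    def test_constant_offset_absorbed_by_background_model(self, maps128,
                                                          stream_peak_params):
        frame, _ = generate_sfx_frame(n_peaks=12, ring_radii_px=(25., 35., 45., 55.),
                                   shape=(128, 128), seed=5)
        shifted = DetectorFrame(data=frame.data + 50.0, timestamp=1.0)
        p0 = find_peaks(frame, maps128,
                        compute_radial_statistics(frame, maps128.radius_px,
                                                  stream_peak_params),
                        stream_peak_params)
        params_shifted = PeakSearchParams(
            snr_min=8.0, intensity_min=65.0,  # absolute floor moves with c
            pixel_count_min=2, pixel_count_max=60)
        p1 = find_peaks(shifted, maps128,
                        compute_radial_statistics(shifted, maps128.radius_px,
                                                  params_shifted),
                        params_shifted)
        assert len(p0) == len(p1) > 0
        for a, b in zip(p0, p1):
            assert (a.seed_slow, a.seed_fast) == (b.seed_slow, b.seed_fast)
            assert b.integrated_intensity == pytest.approx(
                a.integrated_intensity + 50.0 * a.n_pixels, rel=1e-9)

    def test_ordering_intensity_descending(self, maps128, stream_peak_params):
        frame, _ = generate_sfx_frame(n_peaks=15, ring_radii_px=(25., 35., 45., 55.),
                                   shape=(128, 128), seed=9)
        prof = compute_radial_statistics(frame, maps128.radius_px,
                                         stream_peak_params)
        peaks = find_peaks(frame, maps128, prof, stream_peak_params)
        intensities = [p.integrated_intensity for p in peaks]
        assert intensities == sorted(intensities, reverse=True)

    def test_max_pixel_never_exceeds_integrated_intensity(self, maps128,
                                                          stream_peak_params):
        frame, _ = generate_sfx_frame(n_peaks=15, ring_radii_px=(25., 35., 45., 55.),
                                   shape=(128, 128), seed=13)
        prof = compute_radial_statistics(frame, maps128.radius_px,
                                         stream_peak_params)
        for p in find_peaks(frame, maps128, prof, stream_peak_params):
            assert p.max_pixel <= p.integrated_intensity


def _peak(max_pixel):
    return Peak(0, 0, 0.0, 0.0, max_pixel + 1.0, max_pixel, 1, 0.0, 10.0)


class TestSaturation:
    def test_all_below_threshold(self):
        assert count_saturated_peaks([_peak(10.0)] * 5, 100.0) == 0

    def test_counts_at_or_above_threshold(self):
        peaks = [_peak(99.0)] * 16 + [_peak(100.0)] * 2 + [_peak(150.0)] * 2
        assert count_saturated_peaks(peaks, 100.0) == 4

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            count_saturated_peaks([], 0.0)
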