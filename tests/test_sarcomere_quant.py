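"""Profile extraction, peak detection and spacing statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podomech import (
    BoundsError, StriationImage, alternation_index, compute_spacings,
    detect_peaks, extract_profile, generate_striation_image,
    spacing_statistics,
)
from podomech.sarcomere_quant import FiberProfile, measure_image


def cosine_profile(period=1.0, length=6.0, step=0.05):
    s = np.arange(0.0, length + 1e-9, step)
    return FiberProfile(arclength=s,
                        intensity={"ch": np.cos(2 * np.pi * s / period)},
                        source_polyline=np.array([[0, 0], [length, 0]]),
                        sampling_step=step)


class TestExtractProfile:

    def test_constant_image_gives_flat_profile(self):
        img = StriationImage(np.full((1, 50, 50), 0.4), ("ch",), 0.1)
        prof = extract_profile(img, [[0.5, 0.5], [4.0, 4.0]], width=0.2)
        assert np.allclose(prof.intensity["ch"], 0.4)

    def test_maxima_at_ground_truth_band_centers(self, straight_fiber_spec):
        spec = straight_fiber_spec(spacing=1.0, noise_sd=0.0)
        img, gt = generate_striation_image(spec)
        prof = extract_profile(img, spec.fiber_polyline, step=0.05)
        y = prof.intensity["synpo"]
        for center in gt["synpo"]["band_arclengths"][1:-1]:
            sel = np.abs(prof.arclength - center) <= 0.45
            local_max = prof.arclength[sel][np.argmax(y[sel])]
            assert abs(local_max - center) <= prof.sampling_step / 2 + 1e-9

    def test_polyline_outside_image_raises(self, straight_fiber_spec):
        img, _ = generate_striation_image(straight_fiber_spec())
        with pytest.raises(BoundsError):
            extract_profile(img, [[1.0, 7.0], [30.0, 7.0]])

    def test_zero_length_polyline_rejected(self, straight_fiber_spec):
        img, _ = generate_striation_image(straight_fiber_spec())
        with pytest.raises(ValueError):
            extract_profile(img, [[1.0, 7.0], [1.0, 7.0]])


class TestDetectPeaks:

    def test_cosine_peaks_at_integer_periods(self):
        peaks = detect_peaks(cosine_profile(), "ch")
        assert np.allclose(peaks, np.arange(0.0, 6.1, 1.0), atol=0.01)

    def test_flat_profile_yields_no_peaks(self):
        s = np.arange(0, 5, 0.05)
        prof = FiberProfile(s, {"ch": np.full_like(s, 0.3)},
                            np.array([[0, 0], [5, 0]]), 0.05)
        assert len(detect_peaks(prof, "ch")) == 0

    def test_matches_exhaustive_local_maximum_scan(self,
                                                   straight_fiber_spec):
        spec = straight_fiber_spec(spacing=0.9, noise_sd=0.05, seed=42)
        img, gt = generate_striation_image(spec)
        prof = extract_profile(img, spec.fiber_polyline, step=0.05)
        peaks = detect_peaks(prof, "synpo")
        truth = gt["synpo"]["band_arclengths"]
        # one detected peak within 0.1 um of every true band, none spurious
        d_truth = np.abs(peaks[:, None] - truth[None, :]).min(axis=1)
        d_peaks = np.abs(truth[:, None] - peaks[None, :]).min(axis=1)
        assert len(peaks) == len(truth)
        assert d_truth.max() <= 0.1 and d_peaks.max() <= 0.1
        # oracle: exhaustive scan of sample-level local maxima (endpoints
        # included), same range-relative prominence rule
        y = prof.intensity["synpo"]
        from scipy.signal import peak_prominences
        cand = [i for i in range(1, len(y) - 1)
                if y[i] > y[i - 1] and y[i] >= y[i + 1]]
        prom = peak_prominences(y, cand)[0]
        thresh = 0.2 * (y.max() - y.min())
        strong = [c for c, p in zip(cand, prom) if p >= thresh]
        if y[0] >= y[1] and y[0] - y.min() >= thresh:
            strong.insert(0, 0)
        if y[-1] >= y[-2] and y[-1] - y.min() >= thresh:
            strong.append(len(y) - 1)
        assert len(strong) == len(peaks)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(offset=st.floats(-0.5, 0.5), scale=st.floats(0.1, 10.0))
    def test_invariant_to_offset_and_rescale(self, offset, scale):
        prof = cosine_profile()
        shifted = FiberProfile(prof.arclength,
                               {"ch": scale * prof.intensity["ch"] + offset},
                               prof.source_polyline, prof.sampling_step)
        assert np.allclose(detect_peaks(prof, "ch"),
                           detect_peaks(shifted, "ch"), atol=1e-12)


class TestSpacings:

    def test_successive_differences_and_mean(self):
        ss = compute_spacings(np.array([0.0, 1.0, 2.0, 3.0]),
                              fiber_length=10.0)
        assert np.allclose(ss.spacings, 1.0)
        assert ss.per_fiber_mean == pytest.approx(1.0)

    def test_short_fiber_excluded_from_per_fiber_mean(self):
        ss = compute_spacings(np.array([0.0, 1.0, 2.0]), fiber_length=5.0)
        assert len(ss.spacings) == 2
        assert ss.per_fiber_mean is None and not ss.eligible

    def test_single_peak_no_spacings(self):
        ss = compute_spacings(np.array([2.0]), fiber_length=10.0)
        assert len(ss.spacings) == 0 and ss.per_fiber_mean is None

    def test_unsorted_peaks_rejected(self):
        with pytest.raises(ValueError):
            compute_spacings(np.array([1.0, 0.5]), fiber_length=10.0)


class TestAlternation:

    def test_perfect_alternation(self):
        assert alternation_index([0, 1, 2], [0.5, 1.5]) == 1.0

    def test_no_partner_channel(self):
        assert alternation_index([0, 1, 2], []) == 0.0

    def test_single_peak_undefined(self):
        assert alternation_index([0.5], [0.2, 0.8]) is None

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_interval_count(self, seed):
        rng = np.random.default_rng(seed)
        a = np.arange(0.0, 10.1, 1.0)
        b = np.unique(rng.uniform(-1, 11, size=200))
        expected = np.mean([
            sum(1 for x in b if lo < x < hi) == 1
            for lo, hi in zip(a[:-1], a[1:])])
        assert alternation_index(a, b) == pytest.approx(expected)


class TestSpacingStatistics:

    def test_uniform_spacings_zero_sd(self):
        ss = compute_spacings(np.arange(0.0, 8.1, 1.0), fiber_length=8.0)
        stats = spacing_statistics([ss], ["g"])
        row = stats["pooled"].iloc[0]
        assert row.mean_um == pytest.approx(1.0) and row.sd_um == 0.0
        assert stats["per_fiber"].iloc[0].n == 1

    def test_group_means_recover_truth_and_order(self, straight_fiber_spec):
        sets, labels = [], []
        for true_s, group in [(1.0, "stiff"), (1.4, "soft")]:
            for k in range(5):
                spec = straight_fiber_spec(spacing=true_s, noise_sd=0.05,
                                           seed=100 * k + int(10 * true_s))
                img, _ = generate_striation_image(spec)
                prof = extract_profile(img, spec.fiber_polyline)
                peaks = detect_peaks(prof, "synpo")
                sets.append(compute_spacings(peaks, prof.length))
                labels.append(group)
        table = stats = spacing_statistics(sets, labels)["per_fiber"]
        means = dict(zip(table.group, table.mean_um))
        assert means["stiff"] == pytest.approx(1.0, rel=0.05)
        assert means["soft"] == pytest.approx(1.4, rel=0.05)
        assert means["stiff"] < means["soft"]

    def test_group_without_eligible_fibers_warned_and_excluded(self):
        good = compute_spacings(np.arange(0.0, 8.1, 1.0), fiber_length=8.0)
        short = compute_spacings(np.array([0.0, 1.0]), fiber_length=3.0)
        with pytest.warns(UserWarning, match="eligible"):
            stats = spacing_statistics([good, short], ["a", "b"])
        assert list(stats["per_fiber"].group) == ["a"]
        assert "b" in list(stats["pooled"].group)   # pooled spacings remain

    def test_measure_image_tidy_output(self, straight_fiber_spec):
        spec = straight_fiber_spec()
        img, _ = generate_striation_image(spec)
        df = measure_image(img, {"f0": spec.fiber_polyline},
                           channels=["synpo"])
        assert set(df.columns) == {"fiber_id", "channel", "position_um",
                                   "spacing_um"}
        assert df.spacing_um.dropna().mean() == pytest.approx(1.0, rel=0.02)
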