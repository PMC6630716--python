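"""Smoothing, peak detection, alignment, and blank filtering."""

import numpy as np
import pytest

from lipidbridge.msdata import Chromatogram
from lipidbridge.peaks import (
    align,
    blank_filter,
    detect_peaks,
    find_features,
    smooth,
)


def chrom(y, dt=0.01, mz=500.0):
    y = np.asarray(y, dtype=float)
    return Chromatogram(times=np.arange(len(y)) * dt, intensities=y,
                        descriptor={"target_mz": mz})


def gaussian_trace(center, sigma, height, n=200, dt=0.01):
    t = np.arange(n) * dt
    return Chromatogram(times=t,
                        intensities=height * np.exp(-0.5 * ((t - center) / sigma) ** 2),
                        descriptor={"target_mz": 500.0})


class TestSmooth:
    def test_level_zero_is_identity(self):
        c = chrom([1, 5, 2, 8])
        assert smooth(c, 0) is c

    def test_level_one_triangular_kernel(self):
        out = smooth(chrom([0, 0, 9, 0, 0]), 1)
        assert np.allclose(out.intensities, [0, 2.25, 4.5, 2.25, 0])

    @pytest.mark.parametrize("level", [1, 2, 3, 5])
    def test_constant_trace_unchanged(self, level):
        out = smooth(chrom([7.0] * 20), level)
        assert np.allclose(out.intensities, 7.0)

    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_signal_conservation_on_interior_support(self, level):
        y = np.zeros(100)
        y[40:60] = np.hanning(20) * 1000
        out = smooth(chrom(y), level)
        assert abs(out.intensities.sum() - y.sum()) / y.sum() < 1e-9

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            smooth(chrom([1.0]), -1)


class TestDetectPeaks:
    def test_single_gaussian(self):
        c = gaussian_trace(center=1.0, sigma=0.05, height=10000)
        feats = detect_peaks(smooth(c, 3), 5, 1000, raw=c)
        assert len(feats) == 1
        f = feats[0]
        assert abs(f.apex_rt - 1.0) <= 0.01
        assert f.height == pytest.approx(10000, rel=0.01)
        # trapezoid area of a Gaussian ~ height * sigma * sqrt(2 pi)
        assert f.area == pytest.approx(10000 * 0.05 * np.sqrt(2 * np.pi),
                                       rel=0.02)

    def test_all_zero_trace(self):
        assert detect_peaks(chrom(np.zeros(50)), 5, 100) == []

    def test_two_separated_gaussians(self):
        t = np.arange(300) * 0.01
        y = (8000 * np.exp(-0.5 * ((t - 0.8) / 0.05) ** 2)
             + 4000 * np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2))
        c = Chromatogram(times=t, intensities=y,
                         descriptor={"target_mz": 500.0})
        feats = detect_peaks(smooth(c, 3), 5, 1000, raw=c)
        assert len(feats) == 2
        assert feats[0].apex_rt < feats[1].apex_rt
        assert feats[0].height > feats[1].height

    def test_scaling_invariance_above_threshold(self):
        rng = np.random.default_rng(5)
        t = np.arange(300) * 0.01
        y = (8000 * np.exp(-0.5 * ((t - 0.8) / 0.05) ** 2)
             + 5000 * np.exp(-0.5 * ((t - 1.6) / 0.06) ** 2))
        y *= 1 + 0.03 * rng.standard_normal(len(y))
        y = np.clip(y, 0, None)
        c = Chromatogram(times=t, intensities=y, descriptor={})
        base = detect_peaks(smooth(c, 3), 5, 100, raw=c)
        scaled_c = Chromatogram(times=t, intensities=10 * y, descriptor={})
        scaled = detect_peaks(smooth(scaled_c, 3), 5, 1000, raw=scaled_c)
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert (a.left_edge, a.right_edge) == (b.left_edge, b.right_edge)
            assert b.height == pytest.approx(10 * a.height, rel=1e-9)

    def test_higher_smoothing_merges_coeluted_peaks(self, showcase):
        """Feature count at smoothing level 3 never exceeds level 1 on the
        co-elution scenario (the rationale for using level 1 in the
        targeted stage)."""
        from lipidbridge.msdata import extract_xic
        for sample, (run, truth) in showcase[0].items():
            x = extract_xic(run, truth.precursor_mz[0], 0.05)
            n1 = len(detect_peaks(smooth(x, 1), 5, 1000, raw=x))
            n3 = len(detect_peaks(smooth(x, 3), 5, 1000, raw=x))
            assert n3 <= n1


class TestFindFeatures:
    def test_merged_isomer_peak_is_single_feature(self, showcase):
        for sample, (run, _) in showcase[0].items():
            feats = find_features(run)
            assert len(feats) == 1


class TestAlign:
    def feature(self, mz, rt, height=1000.0):
        from lipidbridge.peaks import PeakFeature
        return PeakFeature(apex_rt=rt, apex_index=0, left_edge=0,
                           right_edge=10, height=height, area=height,
                           mz=mz)

    def test_identical_feature_in_three_samples(self):
        samples = [[self.feature(500.0, 5.0)] for _ in range(3)]
        table = align(samples)
        assert len(table.rows) == 1
        assert len(table.rows[0].heights) == 3

    def test_distant_rt_stays_separate(self):
        table = align([[self.feature(500.0, 5.0), self.feature(500.0, 5.2)]],
                      rt_tol=0.05)
        assert len(table.rows) == 2

    def test_jittered_features_collapse_to_true_count(self):
        rng = np.random.default_rng(2)
        true = [(500.0, 5.0), (500.5, 5.0), (600.0, 7.0)]
        samples = []
        for _ in range(4):
            samples.append([
                self.feature(mz + rng.uniform(-0.005, 0.005),
                             rt + rng.uniform(-0.02, 0.02))
                for mz, rt in true])
        table = align(samples, rt_tol=0.05, mz_tol=0.015)
        assert len(table.rows) == len(true)

    def test_requires_one_sample(self):
        with pytest.raises(ValueError):
            align([])


class TestBlankFilter:
    def make_table(self, sample_max, blank_height):
        f = TestAlign().feature
        samples = [[f(500.0, 5.0, sample_max)], [f(500.0, 5.0, blank_height)]]
        return align(samples)

    def test_kept_at_fold_threshold(self):
        table = blank_filter(self.make_table(1000, 100), blank_samples=[1],
                             fold=5)
        assert not table.rows[0].blank_flagged

    def test_flagged_below_threshold_but_retained(self):
        table = blank_filter(self.make_table(400, 100), blank_samples=[1],
                             fold=5)
        assert table.rows[0].blank_flagged
        assert len(table.rows) == 1

    def test_zero_blank_always_kept(self):
        f = TestAlign().feature
        table = align([[f(500.0, 5.0, 50)], []])
        table = blank_filter(table, blank_samples=[1], fold=5)
        assert not table.rows[0].blank_flagged

    def test_no_blanks_warns_noop(self):
        table = self.make_table(400, 100)
        with pytest.warns(UserWarning, match="no-op"):
            blank_filter(table, blank_samples=[])
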