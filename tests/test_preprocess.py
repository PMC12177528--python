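"""Curation pipeline: resampling, noise, normalization, corner filter."""

import numpy as np
import pytest

from phasedprior.preprocess import (
    SliceRecord,
    add_background_noise,
    conform_resample,
    corner_patch_stats,
    filter_slices,
    normalize_slice,
    preprocess_volume,
    split_axial,
)
from phasedprior.types import MagnitudeVolume


def _vol(data, **kw):
    return MagnitudeVolume(np.asarray(data, dtype=float), **kw)


class TestConform:
    def test_identity_at_target_size(self, rng):
        data = rng.uniform(size=(32, 32, 3))
        out = conform_resample(_vol(data), target_size=32)
        np.testing.assert_allclose(out.data, data)

    def test_constant_volume_stays_constant(self):
        out = conform_resample(_vol(np.full((20, 24, 5), 3.5)), target_size=32)
        np.testing.assert_allclose(out.data, 3.5)
        assert out.data.shape == (32, 32, 5)

    def test_ramp_matches_linear_interpolation_oracle(self):
        # a linear ramp is reproduced exactly by linear interpolation at
        # the sample points of the coarse grid
        ramp = np.tile(np.arange(32, dtype=float)[:, None, None], (1, 32, 2))
        out = conform_resample(_vol(ramp), target_size=64)
        # oracle: the resampled ramp must remain affine along axis 0 in the
        # interior and preserve the value range
        interior = out.data[2:-2, 16, 0]
        d2 = np.diff(interior, n=2)
        assert np.abs(d2).max() < 1e-6
        assert out.data.min() >= 0 and out.data.max() <= 31 + 1e-9

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            conform_resample(_vol(np.zeros((0, 4, 4))))


class TestSplit:
    def test_slice_count_and_restack(self, rng):
        data = rng.uniform(size=(16, 16, 10))
        vol = _vol(data)
        slices = split_axial(vol)
        assert len(slices) == 10
        np.testing.assert_array_equal(np.stack(slices, axis=2), data)

    def test_orientation_permutation_gives_same_slices(self, rng):
        data = rng.uniform(size=(16, 16, 6))
        vol = _vol(data, orientation=("R", "A", "S"))
        # move the through-plane (S) axis first and relabel
        permuted = _vol(np.transpose(data, (2, 0, 1)), orientation=("S", "R", "A"))
        a = split_axial(conform_resample(vol, target_size=16))
        b = split_axial(conform_resample(permuted, target_size=16))
        assert len(a) == len(b) == 6
        for sa, sb in zip(a, b):
            np.testing.assert_allclose(sa, sb)


class TestNoiseAndNormalize:
    def test_zero_sigma_is_uniform_shift(self):
        slc = np.zeros((8, 8))
        out = add_background_noise(slc, mu=0.003, sigma=0.0, seed=0)
        np.testing.assert_allclose(out, 0.003)

    def test_rectified_gaussian_mean(self):
        # E[max(g, 0)] for g ~ N(mu, s^2): closed form via the Gaussian
        # density and CDF (independent oracle for the clip-at-zero)
        from scipy.stats import norm

        mu, s = 0.003, 5.0
        expected = mu * norm.cdf(mu / s) + s * norm.pdf(mu / s)
        out = add_background_noise(np.zeros((256, 256)), mu=mu, sigma=s, seed=1)
        assert abs(out.mean() - expected) / expected < 0.02

    def test_noise_deterministic(self):
        a = add_background_noise(np.ones((16, 16)), seed=3)
        b = add_background_noise(np.ones((16, 16)), seed=3)
        np.testing.assert_array_equal(a, b)

    def test_normalize(self, rng):
        slc = rng.uniform(0, 7, size=(8, 8))
        slc.flat[3] = 7.0
        out = normalize_slice(slc)
        assert out.max() == 1.0
        np.testing.assert_allclose(out, slc / 7.0)
        np.testing.assert_array_equal(normalize_slice(out), out)  # idempotent

    def test_normalize_rejects_zero_slice(self):
        with pytest.raises(ValueError):
            normalize_slice(np.zeros((8, 8)))


class TestCornerStats:
    def test_constant_slice(self):
        mu, sd = corner_patch_stats(np.full((64, 64), 0.25))
        assert (mu, sd) == (0.25, 0.0)

    def test_half_zeros_half_ones(self):
        slc = np.zeros((30, 30))
        slc[:15, :] = 1.0
        patch = np.zeros((256, 256))
        patch[:30, :30] = slc
        mu, sd = corner_patch_stats(patch, patch_size=30)
        assert mu == pytest.approx(0.5)
        assert sd == pytest.approx(0.5)  # population convention

    def test_matches_two_pass_oracle(self, rng):
        slc = rng.uniform(size=(256, 256))
        mu, sd = corner_patch_stats(slc)
        patch = slc[:30, :30].ravel()
        mu2 = sum(patch) / patch.size
        sd2 = np.sqrt(sum((p - mu2) ** 2 for p in patch) / patch.size)
        assert abs(mu - mu2) < 1e-12 and abs(sd - sd2) < 1e-12


class TestFilter:
    @staticmethod
    def _rec(mu, sd):
        return SliceRecord(np.zeros((4, 4)), mu, sd, True, ("v", 0))

    def test_blank_slice_excluded(self):
        assert filter_slices([self._rec(0.0, 0.0)]) == []

    def test_single_condition_keeps(self):
        # only the std is below threshold -> kept (conjunction)
        recs = [self._rec(0.05, 0.001)]
        assert filter_slices(recs) == recs

    def test_matches_brute_force_predicate(self):
        mus = [0.0, 0.03, 0.04, 0.05, 0.1]
        sds = [0.0, 0.005, 0.0061, 0.007]
        recs = [self._rec(m, s) for m in mus for s in sds]
        kept = filter_slices(recs)
        expected = [r for r in recs if not (r.patch_mean < 0.04 and r.patch_std < 0.0061)]
        assert kept == expected
        assert all(r.kept == (r in expected) for r in recs)

    def test_or_mode(self):
        recs = [self._rec(0.05, 0.001)]
        assert filter_slices(recs, combine="or") == []


class TestPipeline:
    def test_deterministic_and_normalized(self, rng):
        data = rng.uniform(0, 100, size=(24, 24, 6))
        vol = MagnitudeVolume(data)
        a = preprocess_volume(vol, target_size=32, seed=5)
        b = preprocess_volume(vol, target_size=32, seed=5)
        assert len(a) == 6
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.image, rb.image)
            assert (ra.patch_mean, ra.patch_std, ra.kept) == (
                rb.patch_mean, rb.patch_std, rb.kept)
        for r in a:
            if r.kept:
                assert r.image.max() == 1.0
                assert r.image.shape == (32, 32)
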