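"""PICS and NLINV solvers, wavelet prox, Sobolev weight."""

import numpy as np
import pytest

from phasedprior import (
    GaussianPrior,
    NlinvConfig,
    NlinvModel,
    PicsConfig,
    PicsModel,
    build_schedule,
    l1wav_prox,
    make_coil_maps,
    make_complex_phantom,
    make_mask_1d,
    simulate_kspace,
    sobolev_weight,
)
from phasedprior.types import SamplingMask
from tests.conftest import random_complex


def cg_normal_equations(A, At, y, alpha, shape, iters=600, tol=1e-14):
    """Independent oracle: CG on (A^H A + alpha I) x = A^H y."""
    b = At(y)
    x = np.zeros(shape, complex)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(iters):
        q = At(A(p)) + alpha * p
        a = rs / np.vdot(p, q).real
        x += a * p
        r -= a * q
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new) < tol:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


@pytest.fixture(scope="module")
def undersampled32():
    truth = make_complex_phantom(n=32, seed=0)
    coils = make_coil_maps(32, 4, seed=1)
    mask = make_mask_1d(32, 3, 8)
    y = simulate_kspace(truth, coils, mask, noise_std=0.003, seed=2)
    return truth, coils, y


class TestPics:
    def test_l2_matches_cg_oracle(self, undersampled32):
        truth, coils, y = undersampled32
        cfg = PicsConfig(regularizer="l2", alpha=0.05, iters=1200)
        model = PicsModel(y, coils, cfg)
        res = model.fit()
        zf = model._At(y.data)
        scale = np.abs(zf).max()
        xcg = cg_normal_equations(model._A, model._At, y.data / scale,
                                  cfg.alpha, truth.data.shape) * scale
        rel = np.linalg.norm(res.image.data - xcg) / np.linalg.norm(xcg)
        assert rel < 1e-6

    def test_full_mask_near_exact_inverse(self):
        truth = make_complex_phantom(n=32, seed=3)
        coils = make_coil_maps(32, 4, seed=4)
        full = SamplingMask(np.ones((32, 32), dtype=bool))
        y = simulate_kspace(truth, coils, full, noise_std=0.0)
        res = PicsModel(y, coils, PicsConfig(regularizer="l2", alpha=1e-6,
                                             iters=200)).fit()
        rel = np.linalg.norm(res.image.data - truth.data) / np.linalg.norm(truth.data)
        assert rel < 1e-3

    def test_objective_non_increasing_convex_regs(self, undersampled32):
        _, coils, y = undersampled32
        for reg, alpha in [("l2", 0.05), ("l1wav", 0.003)]:
            res = PicsModel(y, coils, PicsConfig(regularizer=reg, alpha=alpha,
                                                 iters=80)).fit()
            obj = res.objective
            # FISTA with adaptive restart: allow the standard small ripple
            assert np.all(np.diff(obj) <= np.abs(obj[:-1]) * 1e-6 + 1e-12)
            assert not res.diverged

    def test_prior_mode_requires_prior(self, undersampled32):
        _, coils, y = undersampled32
        with pytest.raises(ValueError, match="prior"):
            PicsModel(y, coils, PicsConfig(regularizer="prior"))

    def test_gaussian_prior_reconstruction_stays_bounded(self, undersampled32):
        _, coils, y = undersampled32
        sch = build_schedule(N=10)
        res = PicsModel(y, coils, PicsConfig(regularizer="prior", alpha=0.3,
                                             iters=60),
                        prior=GaussianPrior(0.5), schedule=sch).fit()
        # the problem is normalized to max 1 on entry; no blow-up allowed
        assert np.abs(res.image.data).max() <= 1.5 * res.scale

    def test_summary_mentions_key_fields(self, undersampled32):
        _, coils, y = undersampled32
        res = PicsModel(y, coils, PicsConfig(regularizer="l2", iters=5)).fit()
        s = res.summary()
        assert "regularizer" in s and "l2" in s and "objective" in s


class TestL1WavProx:
    def test_zero_threshold_identity(self, rng):
        z = random_complex(rng, (32, 32))
        np.testing.assert_allclose(l1wav_prox(z, 0.0), z, atol=1e-10)

    def test_subthreshold_details_removed(self, rng):
        import pywt

        level = pywt.dwtn_max_level((32, 32), "db4")
        # construct an image whose detail coefficients are all tiny
        coeffs = pywt.wavedec2(np.zeros((32, 32)), "db4", mode="periodization",
                               level=level)
        coeffs[0][:] = 5.0  # pure approximation content
        base = pywt.waverec2(coeffs, "db4", mode="periodization")
        noisy = base + 1e-4 * random_complex(rng, (32, 32))
        out = l1wav_prox(noisy, threshold=1e-2)
        rec = pywt.wavedec2(out, "db4", mode="periodization", level=level)
        for detail in rec[1:]:
            for band in detail:
                assert np.abs(band).max() < 1e-8

    def test_nonexpansive(self, rng):
        for _ in range(5):
            z1 = random_complex(rng, (16, 16))
            z2 = random_complex(rng, (16, 16))
            d_out = np.linalg.norm(l1wav_prox(z1, 0.1) - l1wav_prox(z2, 0.1))
            assert d_out <= np.linalg.norm(z1 - z2) + 1e-10


class TestSobolev:
    def test_dc_value_one(self):
        w = sobolev_weight(32)
        assert w[16, 16] == 1.0

    def test_radially_non_decreasing(self):
        w = sobolev_weight(32, a=220, b=16)
        center = 16
        for ray in [w[center, center:], w[center:, center],
                    np.diag(w)[center:]]:
            assert np.all(np.diff(ray) >= 0)

    def test_corner_value_hand_arithmetic(self):
        n, a, b = 32, 220.0, 16.0
        w = sobolev_weight(n, a, b)
        k2 = 2 * (n // 2) ** 2  # corner at (0, 0): offsets (-16, -16)
        expected = (1 + a * (16**2 + 16**2) / k2) ** (b / 2)
        assert w[0, 0] == pytest.approx(expected, rel=1e-12)


class TestNlinv:
    def test_alphas_betas_strictly_decreasing(self):
        truth = make_complex_phantom(n=32, seed=0)
        coils = make_coil_maps(32, 4, seed=1)
        full = SamplingMask(np.ones((32, 32), dtype=bool))
        y = simulate_kspace(truth, coils, full, noise_std=0.0)
        res = NlinvModel(y, NlinvConfig(gn_steps=6, stage1_steps=3)).fit()
        assert np.all(np.diff(res.alphas) < 0)
        assert np.all(np.diff(res.betas) < 0)

    def test_noiseless_recovery_of_coil_product(self):
        truth = make_complex_phantom(n=32, seed=0)
        coils = make_coil_maps(32, 4, seed=1)
        full = SamplingMask(np.ones((32, 32), dtype=bool))
        y = simulate_kspace(truth, coils, full, noise_std=0.0)
        # at 32x32 the coil spectrum occupies relatively more of the grid,
        # so the Sobolev order is relaxed to b=8 for adequate bandwidth
        cfg = NlinvConfig(regularizer="l2", gn_steps=16, stage1_steps=8, q=0.4,
                          sobolev_b=8.0)
        res = NlinvModel(y, cfg).fit()
        true_cp = truth.data[:, :, None] * coils.data
        rel = np.linalg.norm(res.coil_product() - true_cp) / np.linalg.norm(true_cp)
        assert rel < 1e-2
        assert res.residuals[-1] < res.residuals[0]

    def test_invariant_to_data_scale(self):
        # multiplying the data by a constant rescales x but leaves the
        # aligned coil product unchanged
        from phasedprior.types import KSpace

        truth = make_complex_phantom(n=32, seed=5)
        coils = make_coil_maps(32, 3, seed=6)
        full = SamplingMask(np.ones((32, 32), dtype=bool))
        y = simulate_kspace(truth, coils, full, noise_std=0.0)
        cfg = NlinvConfig(gn_steps=8, stage1_steps=4)
        r1 = NlinvModel(y, cfg).fit()
        r2 = NlinvModel(KSpace(y.data * 12.5, y.mask), cfg).fit()
        np.testing.assert_allclose(r2.coil_product(), 12.5 * r1.coil_product(),
                                   rtol=1e-6, atol=1e-8)

    def test_misconfiguration_rejected(self):
        with pytest.raises(ValueError):
            NlinvConfig(gn_steps=5, stage1_steps=5)
        with pytest.raises(ValueError):
            NlinvConfig(q=1.5)
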