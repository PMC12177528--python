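"""Linear (PICS) and nonlinear (NLINV) parallel-imaging reconstruction.

PICS solves  min_x 1/2 ||F_c(x) - y||^2 + alpha R(x)  by FISTA with a
proximal step per iteration; R is l2, l1-wavelet, or a learned log-prior
applied through a one-gradient-step proximal approximation whose noise
scale index follows the iteration counter.

NLINV jointly estimates image and coil sensitivities by the iteratively
regularized Gauss-Newton method: at step k the linearized sub-problem

    min_dm 1/2 ||DF(m_k) dm + F(m_k) - y||^2
           + beta_k W(c_k + dc) + alpha_k R(x_k + dx)

is solved with alpha_k = alpha0 q^k, beta_k = beta0 q^k. The coil penalty
W(c) = ||w * Fc||^2 suppresses high Fourier coefficients of the maps; the
coil variable is kept in the Sobolev-preconditioned k-space domain where W
is a plain l2 norm. Early Gauss-Newton steps use l2/CG (the image is
still smooth); later steps use FISTA with the configured proximal.

Both solvers are exposed statsmodels-style: a Model object built from the
data whose ``fit()`` returns a Results object with the estimates,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pywt

from .operators import fft2c, ifft2c
from .priors import PriorModel, prox_step
from .schedule import NoiseSchedule, build_schedule
from .types import ComplexImage, CoilSensitivities, KSpace

__all__ = [
    "PicsConfig",
    "PicsModel",
    "PicsResults",
    "NlinvConfig",
    "NlinvModel",
    "NlinvResults",
    "sobolev_weight",
    "l1wav_prox",
]


# ---------------------------------------------------------------------------
# shared pieces

def sobolev_weight(n: int, a: float = 220.0, b: float = 16.0) -> np.ndarray:
    """Centered Sobolev weight w(k) = (1 + a ||k||^2 / ||k_max||^2)^(b/2).

    Value 1 at DC, radially non-decreasing; ||k_max|| is the distance from
    the grid center to a corner.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    idx = np.arange(n) - n // 2
    ky, kx = np.meshgrid(idx, idx, indexing="ij")
    k2 = ky.astype(np.float64) ** 2 + kx.astype(np.float64) ** 2
    kmax2 = 2 * (n // 2) ** 2
    return (1.0 + a * k2 / kmax2) ** (b / 2.0)


def l1wav_prox(z: np.ndarray, threshold: float, wavelet: str = "db4",
               level: int | None = None) -> np.ndarray:
    """Complex soft-thresholding in an orthogonal wavelet frame.

    Detail coefficients are shrunk in magnitude (phase preserved) by the
    threshold; the approximation band is left untouched. threshold = 0 is
    the identity up to transform round-off.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    z = np.asarray(z, dtype=np.complex128)
    if level is None:
        level = min(3, pywt.dwtn_max_level(z.shape, wavelet))
    coeffs = pywt.wavedec2(z, wavelet, mode="periodization", level=level)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        shrunk = []
        for band in detail:
            mag = np.abs(band)
            factor = np.maximum(1.0 - threshold / np.maximum(mag, 1e-300), 0.0)
            shrunk.append(band * factor)
        out.append(tuple(shrunk))
    rec = pywt.waverec2(out, wavelet, mode="periodization")
    return rec[: z.shape[0], : z.shape[1]]


def _l1wav_norm(z: np.ndarray, wavelet: str = "db4") -> float:
    level = min(3, pywt.dwtn_max_level(z.shape, wavelet))
    coeffs = pywt.wavedec2(z, wavelet, mode="periodization", level=level)
    total = 0.0
    for detail in coeffs[1:]:
        for band in detail:
            total += float(np.abs(band).sum())
    return total


def _power_iteration(op, shape, n_iter: int = 10, seed: int = 0) -> float:
    """Largest eigenvalue estimate of a PSD operator by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = op(v)
        lam = float(np.real(np.vdot(v, w)))
        nw = np.linalg.norm(w)
        if nw == 0:
            return 1.0
        v = w / nw
    return max(lam, 1e-12)


def _scale_index(k: int, total: int, schedule: NoiseSchedule) -> int:
    """Map iteration k of `total` onto the schedule's 0..N scale index."""
    if total <= 1:
        return schedule.N
    return int(round(k / (total - 1) * schedule.N))


# ---------------------------------------------------------------------------
# PICS

@dataclass
class PicsConfig:
    regularizer: str = "l2"          # l2 | l1wav | prior
    alpha: float = 0.01
    iters: int = 100
    step: float | str = "auto"       # data-term step size or "auto"
    seed: int = 0
    restart: bool = True             # FISTA adaptive restart on objective rise

    def __post_init__(self) -> None:
        if self.regularizer not in ("l2", "l1wav", "prior"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.alpha < 0 or self.iters < 1:
            raise ValueError("alpha must be >= 0 and iters >= 1")


@dataclass
class PicsResults:
    """Estimates and diagnostics of a PICS fit."""

    image: ComplexImage
    objective: np.ndarray
    step: float
    scale: float
    diverged: bool
    config: PicsConfig
    n_operator_evals: int

    def summary(self) -> str:
        lines = [
            "PICS reconstruction results",
            "===========================",
            f"regularizer      : {self.config.regularizer}",
            f"alpha            : {self.config.alpha:g}",
            f"iterations       : {self.config.iters}",
            f"step size        : {self.step:.4g}",
            f"data scale       : {self.scale:.4g}",
            f"operator evals   : {self.n_operator_evals}",
            f"final objective  : {self.objective[-1]:.6g}",
            f"diverged flag    : {self.diverged}",
        ]
        return "\n".join(lines)


class PicsModel:
    """Linear compressed-sensing parallel-imaging reconstruction model.

    Parameters
    ----------
    y : KSpace
        Undersampled multi-coil measurements.
    coils : CoilSensitivities
        Pre-estimated sensitivity maps.
    config : PicsConfig
    prior, schedule :
        Required when ``config.regularizer == 'prior'``: the learned
        log-prior and the noise schedule whose scale index follows the
        FISTA iteration counter (i=0 at the first iteration, i=N at the
        last).
    """

    def __init__(
        self,
        y: KSpace,
        coils: CoilSensitivities,
        config: PicsConfig | None = None,
        prior: Optional[PriorModel] = None,
        schedule: Optional[NoiseSchedule] = None,
    ):
        self.y = y
        self.coils = coils
        self.config = config or PicsConfig()
        if self.config.regularizer == "prior":
            if prior is None:
                raise ValueError("prior regularizer requires a prior model")
            if schedule is None:
                schedule = build_schedule(N=self.config.iters)
        self.prior = prior
        self.schedule = schedule
        if coils.data.shape != y.data.shape:
            raise ValueError("coil / k-space shape mismatch")

    # forward ops on plain arrays
    def _A(self, x: np.ndarray) -> np.ndarray:
        return fft2c(x[:, :, None] * self.coils.data) * self.y.mask.data[:, :, None]

    def _At(self, r: np.ndarray) -> np.ndarray:
        return np.sum(np.conj(self.coils.data) * ifft2c(r), axis=2)

    def fit(self) -> PicsResults:
        cfg = self.config
        zf = self._At(self.y.data)
        scale = float(np.abs(zf).max())
        if scale == 0:
            raise ValueError("zero-filled image is empty")
        yn = self.y.data / scale
        x = zf / scale
        evals = 0

        if cfg.step == "auto":
            L = _power_iteration(lambda v: self._At(self._A(v)), x.shape,
                                 n_iter=10, seed=cfg.seed)
            step = 0.95 / L
        else:
            step = float(cfg.step)

        def prox(z: np.ndarray, k: int) -> np.ndarray:
            t = step * cfg.alpha
            if cfg.regularizer == "l2":
                return z / (1.0 + t)
            if cfg.regularizer == "l1wav":
                return l1wav_prox(z, t)
            # learned prior: the score at scale i has magnitude ~ 1/sigma_i^2,
            # so the stable proximal weight anneals as sigma_i^2 (t =
            # sigma_i^2 would be a full Tweedie denoising step; alpha sets
            # the fraction, independent of the data-term step size)
            i = _scale_index(k, cfg.iters, self.schedule)
            return prox_step(z, cfg.alpha * self.schedule[i] ** 2, self.prior, i)

        def objective(xv: np.ndarray) -> float:
            resid = self._A(xv) - yn
            data = 0.5 * float(np.sum(np.abs(resid) ** 2))
            if cfg.regularizer == "l2":
                return data + 0.5 * cfg.alpha * float(np.sum(np.abs(xv) ** 2))
            if cfg.regularizer == "l1wav":
                return data + cfg.alpha * _l1wav_norm(xv)
            return data

        monotone = cfg.regularizer in ("l2", "l1wav")
        v = x.copy()
        t_mom = 1.0
        obj = [objective(x)]
        bad_streak = 0
        for k in range(cfg.iters):
            grad = self._At(self._A(v) - yn)
            evals += 2
            z_new = prox(v - step * grad, k)
            ob = objective(z_new)
            if monotone and ob > obj[-1]:
                # monotone FISTA: keep the better iterate, momentum still
                # extrapolates through the prox output
                x_new, ob_new = x, obj[-1]
            else:
                x_new, ob_new = z_new, ob
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            v = x_new + (t_mom / t_new) * (z_new - x_new) \
                + ((t_mom - 1.0) / t_new) * (x_new - x)
            if cfg.restart and ob > obj[-1]:
                # adaptive restart: drop momentum when the objective rises
                t_new = 1.0
                v = x_new.copy()
            bad_streak = bad_streak + 1 if ob > obj[-1] * (1 + 1e-12) else 0
            obj.append(ob_new)
            x, t_mom = x_new, t_new
        diverged = bad_streak >= 10 or not np.all(np.isfinite(x))
        img = ComplexImage(x * scale, meta={"method": "pics",
                                            "regularizer": cfg.regularizer})
        return PicsResults(
            image=img,
            objective=np.asarray(obj),
            step=step,
            scale=scale,
            diverged=diverged,
            config=cfg,
            n_operator_evals=evals,
        )


# ---------------------------------------------------------------------------
# NLINV

@dataclass
class NlinvConfig:
    gn_steps: int = 10
    stage1_steps: int = 5
    alpha0: float = 1.0
    beta0: float = 1.0
    q: float = 0.5
    sobolev_a: float = 220.0
    sobolev_b: float = 16.0
    cg_iters: int = 30
    fista_iters: int = 50
    regularizer: str = "l2"          # stage-2 image regularizer
    prior_weight: float = 0.02       # stage-2 weight for the learned prior
    anneal_start: float = 0.7        # fraction of the noise schedule skipped
                                     # at stage-2 entry (the image is already
                                     # partially converged after stage 1)
    alpha_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.stage1_steps >= self.gn_steps:
            raise ValueError("stage1_steps must be < gn_steps")
        if self.regularizer not in ("l2", "l1wav", "prior"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


@dataclass
class NlinvResults:
    """Joint image/coil estimates and diagnostics of an NLINV fit."""

    image: ComplexImage
    coils: CoilSensitivities
    alphas: np.ndarray
    betas: np.ndarray
    residuals: np.ndarray = field(repr=False)
    scale: float = 1.0
    config: NlinvConfig | None = None

    def coil_product(self) -> np.ndarray:
        """x * c_j per coil — the identifiable quantity (the separate
        factors carry a joint scale/phase ambiguity)."""
        return self.image.data[:, :, None] * self.coils.data

    def combined_image(self) -> ComplexImage:
        """Scale-fixed image x * rss(c): the root-sum-of-squares of the
        coil product, with the phase of x. Comparable across runs because
        the joint scale ambiguity cancels."""
        rss = np.sqrt(np.sum(np.abs(self.coils.data) ** 2, axis=2))
        return ComplexImage(self.image.data * rss, meta={"method": "nlinv-combined"})

    def summary(self) -> str:
        lines = [
            "NLINV reconstruction results",
            "============================",
            f"Gauss-Newton steps : {self.config.gn_steps}"
            f" (stage 1: {self.config.stage1_steps})",
            f"stage-2 regularizer: {self.config.regularizer}",
            f"alpha_k            : {np.array2string(self.alphas, precision=4)}",
            f"beta_k             : {np.array2string(self.betas, precision=4)}",
            f"data scale         : {self.scale:.4g}",
            f"final rel residual : {self.residuals[-1]:.4g}",
        ]
        return "\n".join(lines)


class NlinvModel:
    """Joint nonlinear reconstruction model (image + coil sensitivities)."""

    def __init__(
        self,
        y: KSpace,
        config: NlinvConfig | None = None,
        prior: Optional[PriorModel] = None,
        schedule: Optional[NoiseSchedule] = None,
    ):
        self.y = y
        self.config = config or NlinvConfig()
        cfg = self.config
        if cfg.regularizer == "prior":
            if prior is None:
                raise ValueError("prior regularizer requires a prior model")
            if schedule is None:
                n_total = (cfg.gn_steps - cfg.stage1_steps) * cfg.fista_iters
                schedule = build_schedule(N=max(n_total, 1))
        self.prior = prior
        self.schedule = schedule
        n = y.data.shape[0]
        self.winv = 1.0 / sobolev_weight(n, cfg.sobolev_a, cfg.sobolev_b)
        self.mask = y.mask.data

    # -- operator pieces (coil variable in preconditioned k-space domain) --
    def _coils_from_chat(self, chat: np.ndarray) -> np.ndarray:
        return ifft2c(chat * self.winv[:, :, None])

    def _G(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        return fft2c(x[:, :, None] * c) * self.mask[:, :, None]

    def _DG(self, x0, c0, dx, dchat) -> np.ndarray:
        dc = self._coils_from_chat(dchat)
        return fft2c(dx[:, :, None] * c0 + x0[:, :, None] * dc) * self.mask[:, :, None]

    def _DGt(self, x0, c0, r) -> tuple[np.ndarray, np.ndarray]:
        t = ifft2c(r * self.mask[:, :, None])
        gx = np.sum(np.conj(c0) * t, axis=2)
        gchat = self.winv[:, :, None] * fft2c(np.conj(x0)[:, :, None] * t)
        return gx, gchat

    # -- fit ---------------------------------------------------------------
    def fit(self) -> NlinvResults:
        cfg = self.config
        n, _, nc = self.y.data.shape
        rss = np.sqrt(np.sum(np.abs(ifft2c(self.y.data)) ** 2, axis=2))
        scale = float(rss.max())
        if scale == 0:
            raise ValueError("empty k-space data")
        yn = self.y.data / scale

        x = np.ones((n, n), dtype=np.complex128)
        x_ref = x.copy()  # l2 stages regularize toward the initialization
        chat = np.zeros((n, n, nc), dtype=np.complex128)
        alphas, betas, residuals = [], [], []
        stage2_counter = 0
        n_stage2_total = (cfg.gn_steps - cfg.stage1_steps) * cfg.fista_iters

        for k in range(cfg.gn_steps):
            alpha_k = max(cfg.alpha0 * cfg.q**k, cfg.alpha_min)
            beta_k = cfg.beta0 * cfg.q**k
            alphas.append(alpha_k)
            betas.append(beta_k)
            c0 = self._coils_from_chat(chat)
            Gm = self._G(x, c0)
            b = yn - Gm
            residuals.append(float(np.linalg.norm(Gm - yn) / np.linalg.norm(yn)))

            if k < cfg.stage1_steps:
                dx, dchat = self._solve_cg(x, c0, chat, x_ref, b, alpha_k, beta_k,
                                           cfg.cg_iters)
                x = x + dx
                chat = chat + dchat
            else:
                x, chat, stage2_counter = self._solve_fista(
                    x, c0, chat, x_ref, b, alpha_k, beta_k, cfg.fista_iters,
                    stage2_counter, n_stage2_total,
                )
        c_final = self._coils_from_chat(chat)
        img = ComplexImage(x * scale, meta={"method": "nlinv"})
        return NlinvResults(
            image=img,
            coils=CoilSensitivities(c_final),
            alphas=np.asarray(alphas),
            betas=np.asarray(betas),
            residuals=np.asarray(residuals),
            scale=scale,
            config=cfg,
        )

    # stage 1: CG on the regularized normal equations of the sub-problem,
    # with the l2 terms anchored at the initialization (x_ref, 0) — the
    # standard NLINV convention that keeps the joint estimation alive while
    # the coils are still unknown
    def _solve_cg(self, x0, c0, chat0, x_ref, b, alpha, beta, iters):
        def normal(dx, dchat):
            r = self._DG(x0, c0, dx, dchat)
            gx, gchat = self._DGt(x0, c0, r)
            return gx + alpha * dx, gchat + beta * dchat

        rx0, rc0 = self._DGt(x0, c0, b)
        rx0 = rx0 - alpha * (x0 - x_ref)
        rc0 = rc0 - beta * chat0
        dx = np.zeros_like(x0)
        dchat = np.zeros_like(chat0)
        rx, rc = rx0.copy(), rc0.copy()
        px, pc = rx.copy(), rc.copy()
        rs = np.vdot(rx, rx).real + np.vdot(rc, rc).real
        for _ in range(iters):
            if rs < 1e-30:
                break
            qx, qc = normal(px, pc)
            denom = np.vdot(px, qx).real + np.vdot(pc, qc).real
            a = rs / denom
            dx += a * px
            dchat += a * pc
            rx -= a * qx
            rc -= a * qc
            rs_new = np.vdot(rx, rx).real + np.vdot(rc, rc).real
            px = rx + (rs_new / rs) * px
            pc = rc + (rs_new / rs) * pc
            rs = rs_new
        return dx, dchat

    # stage 2: FISTA on m = m_k + delta with prox on the image part
    def _solve_fista(self, x0, c0, chat0, x_ref, b, alpha, beta, iters,
                     counter, n_total):
        cfg = self.config
        rss0 = np.sqrt(np.sum(np.abs(c0) ** 2, axis=2))
        rss0_safe = np.maximum(rss0, 0.05 * rss0.max() if rss0.max() > 0 else 1.0)
        L = _power_iteration(
            lambda v: self._DGt(x0, c0, self._DG(x0, c0, v, np.zeros_like(chat0)))[0],
            x0.shape, n_iter=10, seed=cfg.seed,
        )
        Lc = _power_iteration(
            lambda v: self._DGt(x0, c0, self._DG(x0, c0, np.zeros_like(x0),
                                                 v.reshape(chat0.shape)))[1].reshape(-1),
            (chat0.size,), n_iter=10, seed=cfg.seed,
        )
        # block-diagonal preconditioning: the image and coil blocks have
        # very different curvature (|c|^2 vs |x|^2 scales); the factor 2
        # majorizes the cross terms of the joint Hessian
        step_x = 0.95 / max(2 * L, 1e-12)
        step_c = 0.95 / max(2 * Lc + beta, 1e-12)

        x, chat = x0.copy(), chat0.copy()
        vx, vc = x.copy(), chat.copy()
        t_mom = 1.0
        for _ in range(iters):
            r = self._DG(x0, c0, vx - x0, vc - chat0) - b
            gx, gchat = self._DGt(x0, c0, r)
            gchat = gchat + beta * vc
            zx = vx - step_x * gx
            zc = vc - step_c * gchat
            t_eff = step_x * alpha
            step = step_x
            if cfg.regularizer == "l2":
                x_new = (zx + t_eff * x_ref) / (1.0 + t_eff)
            elif cfg.regularizer == "l1wav":
                x_new = l1wav_prox(zx, t_eff)
            else:
                # the learned prior anneals through its own noise schedule
                # (the advancing scale index takes over the role of the
                # decaying alpha_k), weighted by sigma_i^2 for stability.
                # x carries an arbitrary joint scale in NLINV, so the prox
                # is applied in the max-1-normalized frame the prior was
                # trained on.
                i0 = int(round(cfg.anneal_start * self.schedule.N))
                i = i0 + int(round(counter / max(n_total - 1, 1)
                                   * (self.schedule.N - i0)))
                t_prior = cfg.prior_weight * self.schedule[i] ** 2
                # the (x, c) split pushes the coil shading into x, so the
                # prior is applied to the coil-combined image x * rss(c)
                # (the shading-free, max-1-normalized object it was
                # trained on) and the update is mapped back to x
                u = zx * rss0
                mnorm = float(np.abs(u).max())
                if mnorm > 0:
                    u_new = prox_step(u / mnorm, t_prior, self.prior, i) * mnorm
                    x_new = u_new / rss0_safe
                else:
                    x_new = zx
            counter += 1
            c_new = zc
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            vx = x_new + ((t_mom - 1.0) / t_new) * (x_new - x)
            vc = c_new + ((t_mom - 1.0) / t_new) * (c_new - chat)
            x, chat, t_mom = x_new, c_new, t_new
        return x, chat, counter
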