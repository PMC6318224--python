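"""Metropolis MCMC posterior estimation.

Two fitting modes share one chain engine:

* voxel-wise deconvolution — independent chains per voxel, each inferring
  ``{S0, d_m, d_std, lambda_R, tau, {f_n, v_n}}`` from a single dataset.
* fusion ("RubiX") — one chain per LR neighborhood, jointly inferring the P
  HR voxels' parameters, the LR baseline ``S0_LR``, per-dataset noise
  precisions, and the neighborhood's Watson orientation hyper-parameters
  (M modes + concentrations) that couple the LR angular information to the
  HR grid.

Positive scale-like parameters (``tau``, ``d_m``, ``d_std``, ``S0``,
Watson ``kappa``) take multiplicative log-normal random walks (the
asymmetry correction ``log x' - log x`` is included in the acceptance
ratio); ``lambda_R`` and the fractions take additive Gaussian walks with
rejection outside their support; orientations take small random rotations,
which are symmetric proposals on the sphere.  Proposal scales adapt toward
~50% acceptance during burn-in only, so the sampling phase is Markovian.

Each voxel/neighborhood draws its random stream from
``SeedSequence((master_seed, index))``: results are independent of
execution order and bit-reproducible given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .fusion import build_neighborhoods
from .priors import (
    PriorConfig,
    log_prior_dm,
    log_prior_dstd,
    log_prior_fractions,
    log_prior_lambdaR,
    watson_log_kappa_normaliser,
)
from .schemes import GradientScheme
from .tensor import dti_fit

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "metropolis_update",
    "sample_target",
    "run_voxelwise",
    "run_rubix",
    "posterior_mode",
]

logger = logging.getLogger(__name__)

_DEFAULT_SCALES = {
    "S0": 0.05,
    "d_m": 0.1,
    "d_std": 0.5,
    "lambda_R": 0.02,
    "tau": 0.3,
    "f": 0.05,
    "v": 0.15,
    "S0_LR": 0.03,
    "watson_mode": 0.1,
    "watson_kappa": 0.5,
}


@dataclass
class MCMCConfig:
    """Chain schedule.  Defaults: 5000 burn-in, 1250 sampling iterations
    thinned by 25, i.e. 50 retained draws per parameter."""

    n_burnin: int = 5000
    n_sample_iters: int = 1250
    thin: int = 25
    rng_seed: int = 0
    adapt_interval: int = 40
    proposal_scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sample_iters % self.thin != 0:
            raise ValueError("thin must divide n_sample_iters")
        scales = dict(_DEFAULT_SCALES)
        scales.update(self.proposal_scales)
        self.proposal_scales = scales

    @property
    def n_draws(self) -> int:
        return self.n_sample_iters // self.thin


# ---------------------------------------------------------------------------
# generic Metropolis machinery (also used directly for sampler validation)
# ---------------------------------------------------------------------------

def metropolis_update(state, log_posterior, proposal_scales, rng):
    """One sweep of one-parameter-at-a-time Gaussian random-walk updates.

    ``state`` maps names to scalars; ``log_posterior`` maps a state dict to
    a float.  Returns the new state and a dict of accept flags.  Proposals
    that leave the support (log-posterior -inf) are rejected.
    """
    state = dict(state)
    accepted = {}
    lp = log_posterior(state)
    for name in state:
        scale = proposal_scales[name] if not np.isscalar(proposal_scales) else proposal_scales
        cand = dict(state)
        cand[name] = state[name] + scale * rng.standard_normal()
        lp_cand = log_posterior(cand)
        if np.log(rng.uniform()) < lp_cand - lp:
            state = cand
            lp = lp_cand
            accepted[name] = True
        else:
            accepted[name] = False
    return state, accepted


def sample_target(log_posterior, init_state, config: MCMCConfig, rng=None):
    """Run the standard chain schedule against an arbitrary scalar target.

    Returns retained draws as a dict of arrays of length
    ``config.n_draws`` plus per-parameter acceptance rates.  Proposal scales
    adapt toward ~50% acceptance during burn-in only.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    state = dict(init_state)
    scales = {k: config.proposal_scales.get(k, 1.0) for k in state}
    counts = {k: 0 for k in state}
    draws = {k: [] for k in state}
    acc_total = {k: 0 for k in state}
    n_total = config.n_burnin + config.n_sample_iters
    for it in range(n_total):
        state, accepted = metropolis_update(state, log_posterior, scales, rng)
        burnin = it < config.n_burnin
        for k, ok in accepted.items():
            counts[k] += ok
            if not burnin:
                acc_total[k] += ok
        if burnin and (it + 1) % config.adapt_interval == 0:
            for k in scales:
                rate = counts[k] / config.adapt_interval
                scales[k] *= float(np.exp(rate - 0.5))
                counts[k] = 0
        if not burnin and (it - config.n_burnin + 1) % config.thin == 0:
            for k, x in state.items():
                draws[k].append(x)
    out = {k: np.asarray(v) for k, v in draws.items()}
    rates = {k: acc_total[k] / max(config.n_sample_iters, 1) for k in state}
    return out, rates


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _rng_for(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(index))))


def _random_rotation(v: np.ndarray, scale: float, rng) -> np.ndarray:
    """Rotate v by an angle ~ N(0, scale) about a uniformly random axis."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = scale * rng.standard_normal()
    c, s = np.cos(angle), np.sin(angle)
    out = v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)
    return out / np.linalg.norm(out)


def _iso_att(b, d_m, d_std):
    if d_std < 1e-7:
        return np.exp(-b * d_m)
    beta = d_m / d_std**2
    return (beta / (beta + b)) ** (d_m * beta)


def _fib_att(b, dot, d_m, lam_R):
    scale = 3.0 * d_m / (2.0 * lam_R + 1.0)
    return np.exp(-b * scale * ((1.0 - lam_R) * dot**2 + lam_R))


def _watson_logpdf_many(vs, modes, kappas):
    """(Q,) log-density of the equal-weight Watson mixture at each row of vs."""
    dots = vs @ modes.T  # (Q, M)
    comps = watson_log_kappa_normaliser(kappas)[None, :] + kappas[None, :] * dots**2
    return special.logsumexp(comps, axis=1) - np.log(modes.shape[0])


class _DataVector:
    """Per-voxel measurements with Y <= 0 entries treated as missing."""

    __slots__ = ("Y", "mask", "sum_logY", "sumY2", "n")

    def __init__(self, Y):
        Y = np.asarray(Y, dtype=float)
        self.mask = Y > 0
        self.Y = Y[self.mask]
        self.n = int(self.mask.sum())
        self.sum_logY = float(np.sum(np.log(self.Y))) if self.n else 0.0
        self.sumY2 = float(np.sum(self.Y**2)) if self.n else 0.0

    def loglik(self, S, tau):
        """Rician log-likelihood against predictions S (full-length)."""
        if self.n == 0:
            return 0.0
        Sm = S[self.mask]
        x = tau * self.Y * Sm
        log_bessel = np.log(special.i0e(x)) + x
        return (
            self.n * np.log(tau)
            + self.sum_logY
            - tau * (self.sumY2 + float(Sm @ Sm)) / 2.0
            + float(np.sum(log_bessel))
        )


class _NeighborhoodChain:
    """Joint Metropolis chain for P HR voxels (+ optional LR data/Watson prior).

    With P = 1, no LR data and no Watson prior this reduces exactly to the
    voxel-wise sampler.
    """

    def __init__(
        self,
        Y_hr,  # (P, K)
        hr_scheme: GradientScheme,
        Y_lr,  # (L,) or None
        lr_scheme: GradientScheme | None,
        weights,  # (P,)
        priors: PriorConfig,
        config: MCMCConfig,
        rng: np.random.Generator,
        N: int = 3,
        M: int = 3,
        use_watson: bool = False,
        init: list[dict] | None = None,
    ):
        self.P = len(Y_hr)
        self.N = N
        self.M = M
        self.priors = priors
        self.config = config
        self.rng = rng
        self.a = np.asarray(weights, dtype=float)
        self.b_hr = hr_scheme.bvals
        self.g_hr = hr_scheme.bvecs
        self.data_hr = [_DataVector(y) for y in Y_hr]
        self.has_lr = Y_lr is not None and np.size(Y_lr) > 0
        if self.has_lr:
            self.b_lr = lr_scheme.bvals
            self.g_lr = lr_scheme.bvecs
            self.data_lr = _DataVector(Y_lr)
        self.use_watson = use_watson

        # --- state ------------------------------------------------------
        self.S0 = np.empty(self.P)
        self.d_m = np.empty(self.P)
        self.d_std = np.empty(self.P)
        self.lam_R = np.empty(self.P)
        self.tau = np.empty(self.P)
        self.f = np.zeros((self.P, N))
        self.v = np.zeros((self.P, N, 3))
        for p in range(self.P):
            ini = init[p] if init is not None else {}
            self.S0[p] = ini.get("S0", 1.0)
            self.d_m[p] = ini.get("d_m", 1.0e-3)
            self.d_std[p] = ini.get("d_std", 1.0e-4)
            self.lam_R[p] = ini.get("lambda_R", priors.lambdaR_mu)
            self.tau[p] = ini.get("tau", 1.0)
            self.f[p] = ini.get("f", np.linspace(0.4, 0.05, N))
            v0 = ini.get("v")
            if v0 is None:
                v0 = rng.standard_normal((N, 3))
                v0 /= np.linalg.norm(v0, axis=1, keepdims=True)
            self.v[p] = v0
        if self.has_lr:
            self.S0_LR = float(np.mean(self.data_lr.Y[self.b_lr[self.data_lr.mask] == 0])) \
                if np.any(self.b_lr[self.data_lr.mask] == 0) else float(np.mean(self.S0))
            if not self.S0_LR > 0:
                self.S0_LR = float(np.mean(self.S0))
            self.tau_LR = float(init[0].get("tau_LR", 1.0)) if init else 1.0
        if use_watson:
            self.w_modes, self.w_kappa = self._init_watson()

        # --- caches -----------------------------------------------------
        self.iso_hr = [None] * self.P
        self.katt_hr = [None] * self.P
        self.sig_hr = [None] * self.P
        if self.has_lr:
            self.iso_lr = [None] * self.P
            self.katt_lr = [None] * self.P
            self.sig_lr = [None] * self.P
        for p in range(self.P):
            self._refresh_voxel(p)
        if self.has_lr:
            self.lr_num = sum(self.a[p] * self.sig_lr[p] for p in range(self.P))
            self.lr_den = float(np.sum(self.a * self.S0))
            self.ll_lr = self.data_lr.loglik(self._lr_signal(), self.tau_LR)
        self.ll_hr = np.array(
            [self.data_hr[p].loglik(self.sig_hr[p], self.tau[p]) for p in range(self.P)]
        )
        if use_watson:
            self.w_lp = self._watson_all()  # (P, N) per-orientation log prior

        # --- proposal scales / adaptation -------------------------------
        sc = config.proposal_scales
        self.scales = {
            "S0": np.full(self.P, sc["S0"]),
            "d_m": np.full(self.P, sc["d_m"]),
            "d_std": np.full(self.P, sc["d_std"]),
            "lambda_R": np.full(self.P, sc["lambda_R"]),
            "tau": np.full(self.P, sc["tau"]),
            "f": np.full((self.P, N), sc["f"]),
            "v": np.full((self.P, N), sc["v"]),
        }
        if self.has_lr:
            self.scales["S0_LR"] = np.array([sc["S0_LR"]])
            self.scales["tau_LR"] = np.array([sc["tau"]])
        if use_watson:
            self.scales["watson_mode"] = np.full(M, sc["watson_mode"])
            self.scales["watson_kappa"] = np.full(M, sc["watson_kappa"])
        self.acc = {k: np.zeros_like(s) for k, s in self.scales.items()}
        self.acc_run = {k: np.zeros_like(s) for k, s in self.scales.items()}

    # -- initialisation helpers ------------------------------------------

    def _init_watson(self):
        """Seed the Watson modes with well-separated fibre orientations."""
        cands = self.v[:, 0, :].reshape(-1, 3).copy()
        modes = [cands[0] / np.linalg.norm(cands[0])]
        while len(modes) < self.M:
            sims = np.max(
                np.abs(cands @ np.array(modes).T), axis=1
            )  # antipodal similarity
            nxt = cands[int(np.argmin(sims))]
            n = np.linalg.norm(nxt)
            modes.append(nxt / n if n > 0 else np.array([0.0, 0.0, 1.0]))
        return np.array(modes), np.full(self.M, 50.0)

    # -- model evaluation ------------------------------------------------

    def _refresh_voxel(self, p):
        self.iso_hr[p] = _iso_att(self.b_hr, self.d_m[p], self.d_std[p])
        dots = self.g_hr @ self.v[p].T  # (K, N)
        self.katt_hr[p] = _fib_att(
            self.b_hr[:, None], dots, self.d_m[p], self.lam_R[p]
        ).T  # (N, K)
        self.sig_hr[p] = self._combine(p, self.iso_hr[p], self.katt_hr[p])
        if self.has_lr:
            self.iso_lr[p] = _iso_att(self.b_lr, self.d_m[p], self.d_std[p])
            dots = self.g_lr @ self.v[p].T
            self.katt_lr[p] = _fib_att(
                self.b_lr[:, None], dots, self.d_m[p], self.lam_R[p]
            ).T
            self.sig_lr[p] = self._combine(p, self.iso_lr[p], self.katt_lr[p])

    def _combine(self, p, iso, katt, f=None, S0=None):
        f = self.f[p] if f is None else f
        S0 = self.S0[p] if S0 is None else S0
        return S0 * ((1.0 - f.sum()) * iso + f @ katt)

    def _lr_signal(self, num=None, den=None, S0_LR=None):
        num = self.lr_num if num is None else num
        den = self.lr_den if den is None else den
        S0_LR = self.S0_LR if S0_LR is None else S0_LR
        return S0_LR * num / den

    def _watson_all(self):
        vs = self.v.reshape(-1, 3)
        return _watson_logpdf_many(vs, self.w_modes, self.w_kappa).reshape(self.P, self.N)

    # -- accept/reject core ----------------------------------------------

    def _accept(self, delta):
        return np.log(self.rng.uniform()) < delta

    def _try_voxel(self, p, d_prior, new_sig_hr, new_sig_lr=None, new_S0p=None,
                   new_tau=None):
        """Evaluate a proposal touching voxel p's predictions; return
        (accepted, new_ll_hr, lr_bits)."""
        tau = self.tau[p] if new_tau is None else new_tau
        new_ll_hr = self.data_hr[p].loglik(new_sig_hr, tau)
        delta = d_prior + new_ll_hr - self.ll_hr[p]
        lr_bits = None
        if self.has_lr and new_sig_lr is not None:
            num = self.lr_num + self.a[p] * (new_sig_lr - self.sig_lr[p])
            den = self.lr_den
            if new_S0p is not None:
                den = den + self.a[p] * (new_S0p - self.S0[p])
            ll_lr = self.data_lr.loglik(self._lr_signal(num, den), self.tau_LR)
            delta += ll_lr - self.ll_lr
            lr_bits = (num, den, ll_lr)
        return self._accept(delta), new_ll_hr, lr_bits

    def _commit_lr(self, lr_bits):
        if lr_bits is not None:
            self.lr_num, self.lr_den, self.ll_lr = lr_bits

    # -- per-parameter updates -------------------------------------------

    def _update_S0(self, p):
        s = self.scales["S0"][p]
        new = self.S0[p] * np.exp(s * self.rng.standard_normal())
        ratio = new / self.S0[p]
        sig_hr = self.sig_hr[p] * ratio
        sig_lr = self.sig_lr[p] * ratio if self.has_lr else None
        corr = np.log(ratio)  # log-normal walk asymmetry; flat prior on S0
        ok, ll, lr_bits = self._try_voxel(p, corr, sig_hr, sig_lr, new_S0p=new)
        if ok:
            self.S0[p] = new
            self.sig_hr[p] = sig_hr
            self.ll_hr[p] = ll
            if self.has_lr:
                self.sig_lr[p] = sig_lr
                self._commit_lr(lr_bits)
            self.acc["S0"][p] += 1

    def _update_dm(self, p):
        s = self.scales["d_m"][p]
        new = self.d_m[p] * np.exp(s * self.rng.standard_normal())
        pr = self.priors
        d_prior = (
            log_prior_dm(new, pr.dm_gamma_shape, pr.dm_gamma_scale)
            - log_prior_dm(self.d_m[p], pr.dm_gamma_shape, pr.dm_gamma_scale)
            + np.log(new / self.d_m[p])
        )
        iso_hr = _iso_att(self.b_hr, new, self.d_std[p])
        dots = self.g_hr @ self.v[p].T
        katt_hr = _fib_att(self.b_hr[:, None], dots, new, self.lam_R[p]).T
        sig_hr = self._combine(p, iso_hr, katt_hr)
        if self.has_lr:
            iso_lr = _iso_att(self.b_lr, new, self.d_std[p])
            dots_l = self.g_lr @ self.v[p].T
            katt_lr = _fib_att(self.b_lr[:, None], dots_l, new, self.lam_R[p]).T
            sig_lr = self._combine(p, iso_lr, katt_lr)
        else:
            sig_lr = None
        ok, ll, lr_bits = self._try_voxel(p, d_prior, sig_hr, sig_lr)
        if ok:
            self.d_m[p] = new
            self.iso_hr[p], self.katt_hr[p], self.sig_hr[p] = iso_hr, katt_hr, sig_hr
            self.ll_hr[p] = ll
            if self.has_lr:
                self.iso_lr[p], self.katt_lr[p], self.sig_lr[p] = iso_lr, katt_lr, sig_lr
                self._commit_lr(lr_bits)
            self.acc["d_m"][p] += 1

    def _update_dstd(self, p):
        s = self.scales["d_std"][p]
        new = self.d_std[p] * np.exp(s * self.rng.standard_normal())
        d_prior = (
            log_prior_dstd(new, self.priors.fraction_floor)
            - log_prior_dstd(self.d_std[p], self.priors.fraction_floor)
            + np.log(new / self.d_std[p])
        )
        iso_hr = _iso_att(self.b_hr, self.d_m[p], new)
        sig_hr = self._combine(p, iso_hr, self.katt_hr[p])
        if self.has_lr:
            iso_lr = _iso_att(self.b_lr, self.d_m[p], new)
            sig_lr = self._combine(p, iso_lr, self.katt_lr[p])
        else:
            sig_lr = None
        ok, ll, lr_bits = self._try_voxel(p, d_prior, sig_hr, sig_lr)
        if ok:
            self.d_std[p] = new
            self.iso_hr[p], self.sig_hr[p] = iso_hr, sig_hr
            self.ll_hr[p] = ll
            if self.has_lr:
                self.iso_lr[p], self.sig_lr[p] = iso_lr, sig_lr
                self._commit_lr(lr_bits)
            self.acc["d_std"][p] += 1

    def _update_lamR(self, p):
        s = self.scales["lambda_R"][p]
        new = self.lam_R[p] + s * self.rng.standard_normal()
        if not (0.0 < new < 1.0):
            return
        pr = self.priors
        d_prior = log_prior_lambdaR(new, pr.lambdaR_mu, pr.lambdaR_sigma) - \
            log_prior_lambdaR(self.lam_R[p], pr.lambdaR_mu, pr.lambdaR_sigma)
        dots = self.g_hr @ self.v[p].T
        katt_hr = _fib_att(self.b_hr[:, None], dots, self.d_m[p], new).T
        sig_hr = self._combine(p, self.iso_hr[p], katt_hr)
        if self.has_lr:
            dots_l = self.g_lr @ self.v[p].T
            katt_lr = _fib_att(self.b_lr[:, None], dots_l, self.d_m[p], new).T
            sig_lr = self._combine(p, self.iso_lr[p], katt_lr)
        else:
            sig_lr = None
        ok, ll, lr_bits = self._try_voxel(p, d_prior, sig_hr, sig_lr)
        if ok:
            self.lam_R[p] = new
            self.katt_hr[p], self.sig_hr[p] = katt_hr, sig_hr
            self.ll_hr[p] = ll
            if self.has_lr:
                self.katt_lr[p], self.sig_lr[p] = katt_lr, sig_lr
                self._commit_lr(lr_bits)
            self.acc["lambda_R"][p] += 1

    def _update_tau(self, p):
        s = self.scales["tau"][p]
        new = self.tau[p] * np.exp(s * self.rng.standard_normal())
        corr = np.log(new / self.tau[p])  # flat prior on tau > 0
        new_ll = self.data_hr[p].loglik(self.sig_hr[p], new)
        if self._accept(corr + new_ll - self.ll_hr[p]):
            self.tau[p] = new
            self.ll_hr[p] = new_ll
            self.acc["tau"][p] += 1

    def _update_f(self, p, n):
        s = self.scales["f"][p, n]
        f_new = self.f[p].copy()
        f_new[n] = self.f[p, n] + s * self.rng.standard_normal()
        pr = self.priors
        lp_new = log_prior_fractions(f_new, pr.ard_weight_w, pr.fraction_floor)
        if not np.isfinite(lp_new):
            return
        lp_old = log_prior_fractions(self.f[p], pr.ard_weight_w, pr.fraction_floor)
        sig_hr = self._combine(p, self.iso_hr[p], self.katt_hr[p], f=f_new)
        sig_lr = (
            self._combine(p, self.iso_lr[p], self.katt_lr[p], f=f_new)
            if self.has_lr
            else None
        )
        ok, ll, lr_bits = self._try_voxel(p, lp_new - lp_old, sig_hr, sig_lr)
        if ok:
            self.f[p] = f_new
            self.sig_hr[p] = sig_hr
            self.ll_hr[p] = ll
            if self.has_lr:
                self.sig_lr[p] = sig_lr
                self._commit_lr(lr_bits)
            self.acc["f"][p, n] += 1

    #: fraction of orientation proposals drawn uniformly on the sphere — a
    #: symmetric independence kernel that lets a near-empty compartment hop
    #: between well-separated fODF modes that local rotations cannot reach
    GLOBAL_V_FRAC = 0.2

    def _update_v(self, p, n):
        s = self.scales["v"][p, n]
        if self.rng.uniform() < self.GLOBAL_V_FRAC:
            v_new = self.rng.standard_normal(3)
            v_new /= np.linalg.norm(v_new)
        else:
            v_new = _random_rotation(self.v[p, n], s, self.rng)
        d_prior = 0.0
        if self.use_watson:
            w_new = float(
                _watson_logpdf_many(v_new[None, :], self.w_modes, self.w_kappa)[0]
            )
            d_prior = w_new - self.w_lp[p, n]
        dots = self.g_hr @ v_new
        katt_n = _fib_att(self.b_hr, dots, self.d_m[p], self.lam_R[p])
        katt_hr = self.katt_hr[p].copy()
        katt_hr[n] = katt_n
        sig_hr = self._combine(p, self.iso_hr[p], katt_hr)
        if self.has_lr:
            dots_l = self.g_lr @ v_new
            katt_lr = self.katt_lr[p].copy()
            katt_lr[n] = _fib_att(self.b_lr, dots_l, self.d_m[p], self.lam_R[p])
            sig_lr = self._combine(p, self.iso_lr[p], katt_lr)
        else:
            sig_lr = None
        ok, ll, lr_bits = self._try_voxel(p, d_prior, sig_hr, sig_lr)
        if ok:
            self.v[p, n] = v_new
            self.katt_hr[p], self.sig_hr[p] = katt_hr, sig_hr
            self.ll_hr[p] = ll
            if self.use_watson:
                self.w_lp[p, n] = w_new
            if self.has_lr:
                self.katt_lr[p], self.sig_lr[p] = katt_lr, sig_lr
                self._commit_lr(lr_bits)
            self.acc["v"][p, n] += 1

    def _update_S0_LR(self):
        s = self.scales["S0_LR"][0]
        new = self.S0_LR * np.exp(s * self.rng.standard_normal())
        corr = np.log(new / self.S0_LR)
        ll = self.data_lr.loglik(self._lr_signal(S0_LR=new), self.tau_LR)
        if self._accept(corr + ll - self.ll_lr):
            self.S0_LR = new
            self.ll_lr = ll
            self.acc["S0_LR"][0] += 1

    def _update_tau_LR(self):
        s = self.scales["tau_LR"][0]
        new = self.tau_LR * np.exp(s * self.rng.standard_normal())
        corr = np.log(new / self.tau_LR)
        ll = self.data_lr.loglik(self._lr_signal(), new)
        if self._accept(corr + ll - self.ll_lr):
            self.tau_LR = new
            self.ll_lr = ll
            self.acc["tau_LR"][0] += 1

    def _update_watson_mode(self, j):
        s = self.scales["watson_mode"][j]
        modes = self.w_modes.copy()
        modes[j] = _random_rotation(self.w_modes[j], s, self.rng)
        w_lp = _watson_logpdf_many(self.v.reshape(-1, 3), modes, self.w_kappa)
        w_lp = w_lp.reshape(self.P, self.N)
        # uniform-on-sphere hyper-prior on the mode: no extra term
        if self._accept(float(w_lp.sum() - self.w_lp.sum())):
            self.w_modes = modes
            self.w_lp = w_lp
            self.acc["watson_mode"][j] += 1

    def _update_watson_kappa(self, j):
        s = self.scales["watson_kappa"][j]
        kappa = self.w_kappa.copy()
        kappa[j] = self.w_kappa[j] * np.exp(s * self.rng.standard_normal())
        pr = self.priors
        if not (pr.watson_kappa_min <= kappa[j] <= pr.watson_kappa_max):
            return
        # log-uniform hyper-prior (∝ 1/kappa) cancels the log-normal walk
        # asymmetry exactly; only the orientation-prior change remains.
        w_lp = _watson_logpdf_many(self.v.reshape(-1, 3), self.w_modes, kappa)
        w_lp = w_lp.reshape(self.P, self.N)
        if self._accept(float(w_lp.sum() - self.w_lp.sum())):
            self.w_kappa = kappa
            self.w_lp = w_lp
            self.acc["watson_kappa"][j] += 1

    # -- schedule ---------------------------------------------------------

    def _sweep(self):
        for p in range(self.P):
            self._update_S0(p)
            self._update_dm(p)
            self._update_dstd(p)
            self._update_lamR(p)
            for n in range(self.N):
                self._update_f(p, n)
                self._update_v(p, n)
            self._update_tau(p)
        if self.has_lr:
            self._update_S0_LR()
            self._update_tau_LR()
        if self.use_watson:
            for j in range(self.M):
                self._update_watson_mode(j)
                self._update_watson_kappa(j)

    def _adapt(self, interval):
        for k, sc in self.scales.items():
            rate = self.acc[k] / interval
            sc *= np.exp(rate - 0.5)
            np.clip(sc, 1e-4, 3.0, out=sc)
            self.acc[k][...] = 0.0

    def run(self):
        cfg = self.config
        T = cfg.n_draws
        rec = {
            "S0": np.empty((self.P, T)),
            "d_m": np.empty((self.P, T)),
            "d_std": np.empty((self.P, T)),
            "lambda_R": np.empty((self.P, T)),
            "tau": np.empty((self.P, T)),
            "f": np.empty((self.P, T, self.N)),
            "v": np.empty((self.P, T, self.N, 3)),
        }
        extras = {}
        if self.has_lr:
            extras["S0_LR"] = np.empty(T)
            extras["tau_LR"] = np.empty(T)
        if self.use_watson:
            extras["watson_modes"] = np.empty((T, self.M, 3))
            extras["watson_kappa"] = np.empty((T, self.M))
        t = 0
        for it in range(cfg.n_burnin + cfg.n_sample_iters):
            self._sweep()
            burnin = it < cfg.n_burnin
            if burnin:
                if (it + 1) % cfg.adapt_interval == 0:
                    self._adapt(cfg.adapt_interval)
                continue
            for k, arr in self.acc.items():
                self.acc_run[k] += arr
                arr[...] = 0.0
            if (it - cfg.n_burnin + 1) % cfg.thin == 0:
                rec["S0"][:, t] = self.S0
                rec["d_m"][:, t] = self.d_m
                rec["d_std"][:, t] = self.d_std
                rec["lambda_R"][:, t] = self.lam_R
                rec["tau"][:, t] = self.tau
                rec["f"][:, t] = self.f
                rec["v"][:, t] = self.v
                if self.has_lr:
                    extras["S0_LR"][t] = self.S0_LR
                    extras["tau_LR"][t] = self.tau_LR
                if self.use_watson:
                    extras["watson_modes"][t] = self.w_modes
                    extras["watson_kappa"][t] = self.w_kappa
                t += 1
        rates = {
            k: v / max(cfg.n_sample_iters, 1) for k, v in self.acc_run.items()
        }
        return rec, extras, rates


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

class PosteriorSamples:
    """Thinned MCMC draws per voxel with summary accessors.

    ``draws`` maps parameter names to arrays whose leading axes are
    (voxel, draw):  scalars (V, T); fractions (V, T, N); orientations
    (V, T, N, 3).
    """

    def __init__(self, voxel_indices, grid_shape, draws, acceptance=None,
                 in_mask=None, extras=None, config=None, variant="voxelwise"):
        self.voxel_indices = np.asarray(voxel_indices, dtype=int)
        self.grid_shape = tuple(grid_shape)
        self.draws = draws
        self.acceptance = acceptance or {}
        self.in_mask = (
            np.ones(len(self.voxel_indices), bool) if in_mask is None
            else np.asarray(in_mask, bool)
        )
        self.extras = extras or {}
        self.config = config
        self.variant = variant

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    @property
    def n_draws(self) -> int:
        return self.draws["S0"].shape[1]

    @property
    def n_fibres(self) -> int:
        return self.draws["f"].shape[2]

    def mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=1)

    @property
    def mean_fractions(self) -> np.ndarray:
        """(V, N) posterior-mean volume fractions."""
        return self.draws["f"].mean(axis=1)

    def mean_dyads(self) -> np.ndarray:
        """(V, N, 3) mean-dyad orientations (sign-invariant averages)."""
        from .metrics import mean_dyad

        V, T, N, _ = self.draws["v"].shape
        out = np.empty((V, N, 3))
        for i in range(V):
            for n in range(N):
                out[i, n] = mean_dyad(self.draws["v"][i, :, n, :])
        return out

    def cones_95(self) -> np.ndarray:
        """(V, N) 95% cones of uncertainty in degrees."""
        from .metrics import cone_of_uncertainty_95

        V, T, N, _ = self.draws["v"].shape
        out = np.empty((V, N))
        for i in range(V):
            for n in range(N):
                out[i, n] = cone_of_uncertainty_95(self.draws["v"][i, :, n, :])
        return out

    def mode(self, name: str, voxel: int = 0):
        return posterior_mode(self, name, voxel)

    def to_volume(self, values, fill=np.nan) -> np.ndarray:
        """Scatter per-voxel values (V, ...) back onto the grid."""
        values = np.asarray(values)
        vol = np.full(self.grid_shape + values.shape[1:], fill)
        idx = tuple(self.voxel_indices.T)
        vol[idx] = values
        return vol

    def parameter_maps(self) -> dict:
        """Summary maps in the sampler's output naming convention."""
        maps = {}
        mf = self.mean_fractions
        dyads = self.mean_dyads()
        for n in range(self.n_fibres):
            maps[f"mean_f{n + 1}samples"] = self.to_volume(mf[:, n])
            maps[f"dyads{n + 1}"] = self.to_volume(dyads[:, n])
        maps["mean_dsamples"] = self.to_volume(self.mean("d_m"))
        maps["mean_d_stdsamples"] = self.to_volume(self.mean("d_std"))
        maps["mean_lambdaRsamples"] = self.to_volume(self.mean("lambda_R"))
        maps["mean_S0samples"] = self.to_volume(self.mean("S0"))
        return maps


def posterior_mode(samples: PosteriorSamples | np.ndarray, name=None, voxel=0):
    """Posterior mode of one parameter.

    Scalars: mode of a Gaussian-KDE density estimate over the draws
    (constant draws return that constant).  Orientations: principal
    eigenvector of the mean dyadic tensor (handles v = -v symmetry).
    """
    if isinstance(samples, PosteriorSamples):
        draws = samples.draws[name][voxel]
    else:
        draws = np.asarray(samples)
    if draws.ndim >= 2 and draws.shape[-1] == 3:
        from .metrics import mean_dyad

        return mean_dyad(draws.reshape(-1, 3))
    draws = draws.ravel()
    if draws.size < 2 or np.ptp(draws) < 1e-14 * max(1.0, abs(draws[0])):
        return float(draws[0])
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _dti_init(Y, scheme: GradientScheme, rng, N: int):
    """Initialise a voxel chain from a tensor fit."""
    fit = dti_fit(Y, scheme)
    md = float(np.clip(fit["md"], 1e-4, 3e-3))
    fa = float(np.clip(fit["fa"], 0.0, 1.0))
    v = np.empty((N, 3))
    v[0] = fit["pdd"]
    # further compartments start on the remaining tensor eigenvectors: for a
    # crossing, the secondary eigenvector spans the crossing plane
    for n in range(1, min(N, 3)):
        v[n] = fit["evecs"][:, n]
    for n in range(3, N):
        r = rng.standard_normal(3)
        v[n] = r / np.linalg.norm(r)
    b0 = scheme.b0_mask & (np.asarray(Y) > 0)
    S0 = float(np.mean(np.asarray(Y)[b0])) if b0.any() else float(np.max(Y))
    S0 = max(S0, 1e-6)
    # noise precision from b0 scatter, floored for nearly noise-free input
    if b0.sum() >= 2:
        sig2 = float(np.var(np.asarray(Y)[b0]))
    else:
        sig2 = (0.05 * S0) ** 2
    sig2 = max(sig2, (1e-4 * S0) ** 2)
    f = np.zeros(N)
    f[0] = np.clip(fa, 0.05, 0.9)
    if N > 1:
        f[1:] = min(0.05, (1 - f[0]) / (2 * N))
    return {
        "S0": S0,
        "d_m": md,
        "d_std": 1e-4,
        "lambda_R": None,  # filled by caller from the prior mean
        "tau": 1.0 / sig2,
        "f": f,
        "v": v,
    }


def run_voxelwise(
    data_4d,
    scheme: GradientScheme,
    mask,
    priors: PriorConfig | None = None,
    mcmc_cfg: MCMCConfig | None = None,
    N: int = 3,
) -> PosteriorSamples:
    """Voxel-wise deconvolution: independent MCMC chains per in-mask voxel."""
    priors = priors or PriorConfig()
    mcmc_cfg = mcmc_cfg or MCMCConfig()
    data = np.asarray(data_4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.shape[:3] != mask.shape:
        raise ValueError("mask shape does not match data grid")
    if data.shape[3] != len(scheme):
        raise ValueError("4th data dimension does not match scheme length")

    voxels = np.argwhere(mask)
    kept, rec_all, rates_all = [], [], []
    for count, idx in enumerate(voxels):
        Y = data[tuple(idx)]
        if not np.any(Y > 0):
            logger.warning("voxel %s has all-zero signal; skipped", tuple(idx))
            continue
        rng = _rng_for(mcmc_cfg.rng_seed, count)
        ini = _dti_init(Y, scheme, rng, N)
        ini["lambda_R"] = priors.lambdaR_mu
        chain = _NeighborhoodChain(
            Y_hr=Y[None, :],
            hr_scheme=scheme,
            Y_lr=None,
            lr_scheme=None,
            weights=[1.0],
            priors=priors,
            config=mcmc_cfg,
            rng=rng,
            N=N,
            use_watson=False,
            init=[ini],
        )
        rec, _, rates = chain.run()
        kept.append(idx)
        rec_all.append(rec)
        rates_all.append(rates)

    if not kept:
        raise ValueError("no usable voxels inside the mask")
    draws = {
        k: np.concatenate([r[k] for r in rec_all], axis=0)
        for k in rec_all[0]
    }
    acceptance = {
        k: float(np.mean([np.mean(r[k]) for r in rates_all])) for k in rates_all[0]
    }
    return PosteriorSamples(
        voxel_indices=np.array(kept),
        grid_shape=mask.shape,
        draws=draws,
        acceptance=acceptance,
        config=mcmc_cfg,
        variant="voxelwise",
    )


def run_rubix(
    hr_data,
    hr_scheme: GradientScheme,
    lr_data,
    lr_scheme: GradientScheme,
    mask,
    ratio,
    priors: PriorConfig | None = None,
    mcmc_cfg: MCMCConfig | None = None,
    N: int = 3,
    M: int = 3,
) -> PosteriorSamples:
    """Fusion fit: joint chains per LR neighborhood, samples on the HR grid.

    ``mask`` lives on the HR grid; a neighborhood is fitted when at least
    one of its HR voxels is in-mask, and its out-of-mask voxels are fitted
    but flagged (``in_mask`` on the result).  Neighborhoods are independent
    given their seeds, so results do not depend on processing order.
    """
    priors = priors or PriorConfig()
    mcmc_cfg = mcmc_cfg or MCMCConfig()
    hr = np.asarray(hr_data, dtype=float)
    lr = np.asarray(lr_data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if hr.shape[:3] != mask.shape:
        raise ValueError("mask shape does not match HR grid")
    if hr.shape[3] != len(hr_scheme):
        raise ValueError("HR data volumes do not match HR scheme length")
    if lr.shape[3] != len(lr_scheme):
        raise ValueError("LR data volumes do not match LR scheme length")
    ratio = tuple(int(r) for r in ratio)
    expected_lr = tuple(s // r for s, r in zip(hr.shape[:3], ratio))
    if lr.shape[:3] != expected_lr:
        raise ValueError(
            f"LR grid {lr.shape[:3]} inconsistent with HR grid {hr.shape[:3]} "
            f"at ratio {ratio}"
        )

    maps = build_neighborhoods(hr.shape[:3], ratio)
    kept_idx, kept_flags, rec_all, extras_all, rates_all = [], [], [], [], []
    for nb_count, nb in enumerate(maps):
        flags = np.array([mask[idx] for idx in nb.hr_indices])
        if not flags.any():
            continue
        Y_hr = np.array([hr[idx] for idx in nb.hr_indices])
        Y_lr = lr[nb.lr_index]
        rng = _rng_for(mcmc_cfg.rng_seed, nb_count)
        inits = []
        for p in range(nb.P):
            if np.any(Y_hr[p] > 0):
                ini = _dti_init(Y_hr[p], hr_scheme, rng, N)
            else:
                ini = {"S0": max(float(np.mean(Y_lr[Y_lr > 0])) if np.any(Y_lr > 0) else 1.0, 1e-6)}
            ini["lambda_R"] = priors.lambdaR_mu
            inits.append(ini)
        chain = _NeighborhoodChain(
            Y_hr=Y_hr,
            hr_scheme=hr_scheme,
            Y_lr=Y_lr,
            lr_scheme=lr_scheme,
            weights=nb.weights,
            priors=priors,
            config=mcmc_cfg,
            rng=rng,
            N=N,
            M=M,
            use_watson=True,
            init=inits,
        )
        rec, extras, rates = chain.run()
        kept_idx.extend(nb.hr_indices)
        kept_flags.extend(flags.tolist())
        rec_all.append(rec)
        extras_all.append(extras)
        rates_all.append(rates)

    if not rec_all:
        raise ValueError("no neighborhoods intersect the mask")
    draws = {
        k: np.concatenate([r[k] for r in rec_all], axis=0) for k in rec_all[0]
    }
    extras = {
        k: np.stack([e[k] for e in extras_all], axis=0) for k in extras_all[0]
    }
    acceptance = {
        k: float(np.mean([np.mean(r[k]) for r in rates_all])) for k in rates_all[0]
    }
    return PosteriorSamples(
        voxel_indices=np.array(kept_idx),
        grid_shape=mask.shape,
        draws=draws,
        acceptance=acceptance,
        in_mask=np.array(kept_flags),
        extras=extras,
        config=mcmc_cfg,
        variant="rubix",
    )
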