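"""Hierarchical Poisson GLMM with CAR/convolution spatial priors, by MCMC.

The disease-mapping model is

    y_i | E_i, gamma_i ~ Poisson(lambda_i),   log lambda_i = log E_i + log gamma_i
    log gamma_i = mu + x_i beta + psi_i,      E(psi_i) = 0

with the n-vector of random effects ``psi`` given any of the spatial
priors in :mod:`carfield.gmrf`.  Posteriors are simulated with an adaptive
single-site random-walk Metropolis-within-Gibbs sampler:

* psi components (phi_s and phi_h separately for convolution models) are
  updated in conditionally independent colour blocks of the adjacency
  graph, with per-site step sizes adapted to a 0.44 acceptance rate
  during burn-in and frozen afterwards;
* the spatial parameter c moves by random walk on logit(c); for pCAR and
  LCAR the prior log-determinant is evaluated from precomputed
  eigenvalues, for the (M)BYM family c enters the likelihood only;
* scale parameters move on the log scale under Uniform(0, a) or
  half-normal priors; mu and the regression coefficients beta by Gaussian
  random walk;
* models containing an intrinsic component are recentred every sweep
  (the component mean is transferred into mu), which pins down the
  otherwise flat level of the intrinsic field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd

from . import gmrf
from .gmrf import CARSpec
from .lattice import AdjacencyGraph, structure_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseMapData",
    "GLMMConfig",
    "PosteriorDraws",
    "summarize",
    "fit",
]

_ADAPT_BATCH = 50


@dataclass(frozen=True, eq=False)
class DiseaseMapData:
    """Observed counts, expected counts and optional covariates."""

    y: np.ndarray
    E: np.ndarray
    X: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        if self.y.shape != self.E.shape or self.y.ndim != 1:
            raise ValueError("y and E must be 1-d arrays of equal length")
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("y must be non-negative integer counts")
        if np.any(self.E <= 0):
            raise ValueError("expected counts E must be positive")
        if self.X is not None:
            X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if X.shape[0] != self.y.size:
                raise ValueError("X must have one row per area")
            object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return 0 if self.X is None else self.X.shape[1]


@dataclass(frozen=True)
class GLMMConfig:
    """Priors and MCMC controls.

    ``prior_c`` is the Beta(a, b) hyper-prior for the spatial parameter
    (independent per-area copies for adaptive models); ``prior_sigma`` is
    either ``("uniform", a)`` for Uniform(0, a) or ``("half_normal", s)``;
    ``prior_mu_sd`` is the standard deviation of the zero-mean normal
    prior on mu and each beta.  ``fixed`` lists parameters held at their
    CARSpec values instead of being sampled (any of "c", "sigma",
    "sigma_s", "sigma_h").  ``prior_only`` disables the Poisson
    likelihood, so the sampler targets the prior (a correctness check).
    """

    prior_c: tuple[float, float] = (1.0, 1.0)
    prior_sigma: tuple[str, float] = ("uniform", 10.0)
    prior_mu_sd: float = 100.0
    iters: int = 15000
    burnin: int = 5000
    thin: int = 1
    chains: int = 2
    seed: int = 0
    adapt_target: float = 0.44
    fixed: tuple[str, ...] = ()
    prior_only: bool = False

    def __post_init__(self):
        if not 0 < self.burnin < self.iters:
            raise ValueError("need 0 < burnin < iters")
        a, b = self.prior_c
        if a <= 0 or b <= 0:
            raise ValueError("Beta prior parameters must be positive")
        kind, val = self.prior_sigma
        if kind not in ("uniform", "half_normal") or val <= 0:
            raise ValueError("prior_sigma must be ('uniform', a) or ('half_normal', s)")


@dataclass(frozen=True, eq=False)
class PosteriorDraws:
    """Retained MCMC draws, each array shaped (chains, draws[, ...]).

    Every stored draw satisfies ``log lambda_i = log E_i + mu + x_i beta +
    psi_i`` exactly: ``gamma`` is recomputed from the stored state at
    storage time.  For convolution models ``psi = psi_s + psi_h``
    draw-by-draw, with ``psi_s = sqrt(c) * phi_s`` and
    ``psi_h = sqrt(1-c) * phi_h``.
    """

    model: str
    mu: np.ndarray
    psi: np.ndarray
    gamma: np.ndarray
    E: np.ndarray
    beta: np.ndarray | None = None
    c: np.ndarray | None = None
    sigma: np.ndarray | None = None
    sigma_s: np.ndarray | None = None
    sigma_h: np.ndarray | None = None
    psi_s: np.ndarray | None = None
    psi_h: np.ndarray | None = None
    accept_rates: dict = field(default_factory=dict)

    @property
    def lambda_(self) -> np.ndarray:
        return self.gamma * self.E

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws of one quantity with chains stacked, shape (C*T[, ...])."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_names(self) -> list[str]:
        names = ["mu"]
        if self.c is not None and self.c.ndim == 2:
            names.append("c")
        for nm in ("sigma", "sigma_s", "sigma_h"):
            if getattr(self, nm) is not None:
                names.append(nm)
        return names


def _greedy_coloring(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Partition areas into independent sets (no two neighbours share a
    colour), so same-colour sites can be Metropolis-updated in parallel."""
    W = graph.W.tolil()
    color = -np.ones(graph.n, dtype=int)
    for i in range(graph.n):
        used = {color[k] for k in W.rows[i] if color[k] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.flatnonzero(color == c) for c in range(color.max() + 1)]


class _StepAdapter:
    """Per-site step sizes targeting a fixed acceptance rate (frozen after
    burn-in), Roberts–Rosenthal batch adaptation.  One ``update`` call per
    sweep, with one attempted move per site."""

    def __init__(self, size, target, init=0.5):
        self.log_step = np.full(size, np.log(init))
        self.target = target
        self.acc = np.zeros(size)
        self.tries = 0
        self.batch = 0
        self.frozen = False
        self.total_acc = np.zeros(size)
        self.total_tries = 0

    @property
    def step(self):
        return np.exp(self.log_step)

    @property
    def rate(self) -> float:
        """Mean post-freeze (sampling-phase) acceptance rate."""
        if self.total_tries == 0:
            return np.nan
        return float(np.mean(self.total_acc) / self.total_tries)

    def update(self, accepted):
        if self.frozen:
            self.total_acc += accepted
            self.total_tries += 1
            return
        self.acc += accepted
        self.tries += 1
        if self.tries >= _ADAPT_BATCH:
            self.batch += 1
            delta = min(0.05, self.batch**-0.5)
            rate = self.acc / self.tries
            self.log_step += np.where(rate > self.target, delta, -delta)
            np.clip(self.log_step, -8.0, 4.0, out=self.log_step)
            self.acc[:] = 0.0
            self.tries = 0


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class _Sampler:
    """One-chain state and update machinery for every supported model."""

    def __init__(self, graph, data, spec, config, rng):
        self.graph = graph
        self.data = data
        self.spec = spec
        self.cfg = config
        self.rng = rng
        self.n = graph.n
        self.model = spec.model
        self.convolution = self.model in gmrf.CONVOLUTION_MODELS
        self.adaptive = self.model in ("adaptive_mbym", "adaptive_scaled_mbym")
        self.intrinsic = self.model in gmrf.ICAR_CONTAINING

        self.W = graph.W.tocsr().astype(float)
        self.wplus = graph.wplus.astype(float)
        self.colors = _greedy_coloring(graph)

        if self.model == "pcar":
            rng_c = gmrf.valid_range(graph)
            self.cmin, self.cmax = rng_c.cmin, rng_c.cmax
            d = 1.0 / np.sqrt(self.wplus)
            M = d[:, None] * graph.W.toarray() * d[None, :]
            self.alpha = np.linalg.eigvalsh(M)
        if self.model == "lcar":
            Q1 = structure_matrix(graph, 1.0).toarray()
            self.lam_q1 = np.linalg.eigvalsh(Q1)
        self.s2 = 1.0
        if self.model in ("scaled_icar", "scaled_mbym", "adaptive_scaled_mbym"):
            self.s2 = gmrf.scaling(graph).s ** 2

        # --- state ---
        self.mu = 0.0
        self.beta = np.zeros(data.p)
        if self.model == "bym":
            self.sigma_s = spec.sigma_s
            self.sigma_h = spec.sigma_h
        else:
            self.sigma = spec.sigma
        if self.model in ("icar", "scaled_icar", "bym"):
            self.c = None
        elif self.adaptive:
            self.c = np.asarray(spec.c, dtype=float).copy()
            if self.c.shape != (self.n,):
                raise ValueError("adaptive c initial vector must have length n")
        else:
            self.c = float(spec.c)
        if self.convolution:
            self.u = np.zeros(self.n)  # phi_s (psi_s for bym)
            self.v = np.zeros(self.n)  # phi_h (psi_h for bym)
        else:
            self.u = np.zeros(self.n)  # psi itself

        self.xb = data.X @ self.beta if data.p else np.zeros(self.n)
        self.logE = np.log(data.E)
        self._refresh_eta()

        tgt = config.adapt_target
        self.ad_u = _StepAdapter(self.n, tgt, init=0.5)
        self.ad_v = _StepAdapter(self.n, tgt, init=0.5) if self.convolution else None
        self.ad_mu = _StepAdapter(1, tgt, init=0.1)
        self.ad_beta = _StepAdapter(data.p, tgt, init=0.1) if data.p else None
        csize = self.n if self.adaptive else 1
        self.ad_c = _StepAdapter(csize, tgt, init=1.0)
        self.ad_sig = _StepAdapter(2 if self.model == "bym" else 1, tgt, init=0.3)

        self.sample_c = self.c is not None and "c" not in config.fixed
        if self.model == "bym":
            self.sample_sig = tuple(
                nm for nm in ("sigma_s", "sigma_h") if nm not in config.fixed
            )
        else:
            self.sample_sig = () if "sigma" in config.fixed else ("sigma",)

    # -- convolution weights ---------------------------------------------
    def _weights(self):
        if self.model == "bym":
            return 1.0, 1.0
        a = np.sqrt(self.c)
        b = np.sqrt(1.0 - self.c)
        return a, b

    def psi(self):
        if not self.convolution:
            return self.u
        a, b = self._weights()
        return a * self.u + b * self.v

    def _refresh_eta(self):
        self.eta = self.mu + self.xb + self.psi()
        self.lam = self.data.E * np.exp(self.eta)

    # -- likelihood pieces ------------------------------------------------
    def _dloglik(self, idx, delta_psi):
        """Change in Poisson log-likelihood when psi[idx] shifts by delta."""
        if self.cfg.prior_only:
            return 0.0
        y = self.data.y[idx]
        lam = self.lam[idx]
        return y * delta_psi - lam * np.expm1(delta_psi)

    # -- field prior pieces -----------------------------------------------
    def _u_prior_prec(self):
        """(diagonal, off-diagonal coefficient) of the u-field precision."""
        m = self.model
        if m == "pcar":
            return self.wplus / self.sigma**2, self.c / self.sigma**2
        if m == "lcar":
            return (
                (self.c * self.wplus + 1.0 - self.c) / self.sigma**2,
                self.c / self.sigma**2,
            )
        if m == "bym":
            return self.wplus / self.sigma_s**2, 1.0 / self.sigma_s**2
        # icar / scaled_icar / (scaled/adaptive) mbym: intrinsic block
        coef = self.s2 / self.sigma**2
        return self.wplus * coef, coef

    def _update_field(self, x, adapter, prior_diag, prior_coef, lik_scale):
        """Colour-block random-walk update of a field with CAR prior.

        ``lik_scale`` maps a change in the field to the change in psi
        (1 for plain CARs, sqrt(c) or sqrt(1-c) for convolution parts).
        """
        Wx = self.W @ x
        scale = np.broadcast_to(np.asarray(lik_scale, dtype=float), (self.n,))
        acc_sweep = np.zeros(self.n)
        for idx in self.colors:
            step = adapter.step[idx]
            delta = step * self.rng.standard_normal(idx.size)
            xo, xn = x[idx], x[idx] + delta
            # off-diagonal part of the precision is -coef*W, so the cross
            # term in the log density is +coef * x_i * (W x)_i
            dprior = -0.5 * prior_diag[idx] * (xn**2 - xo**2) + prior_coef * delta * Wx[idx]
            dpost = dprior + self._dloglik(idx, scale[idx] * delta)
            accept = np.log(self.rng.random(idx.size)) < dpost
            if np.any(accept):
                upd = idx[accept]
                x[upd] += delta[accept]
                dpsi = scale[upd] * delta[accept]
                self.eta[upd] += dpsi
                self.lam[upd] = self.data.E[upd] * np.exp(self.eta[upd])
                Wx = self.W @ x  # neighbours' cross terms changed
            acc_sweep[idx] = accept
        adapter.update(acc_sweep)

    def _update_v(self):
        """IID component: all sites are conditionally independent."""
        if self.model == "bym":
            prec = 1.0 / self.sigma_h**2
            scale = np.ones(self.n)
        else:
            prec = 1.0 / self.sigma**2
            _, scale = self._weights()
            scale = np.broadcast_to(np.asarray(scale, dtype=float), (self.n,))
        step = self.ad_v.step
        delta = step * self.rng.standard_normal(self.n)
        vo, vn = self.v, self.v + delta
        dpost = -0.5 * prec * (vn**2 - vo**2) + self._dloglik(
            np.arange(self.n), scale * delta
        )
        accept = np.log(self.rng.random(self.n)) < dpost
        self.v[accept] += delta[accept]
        dpsi = scale[accept] * delta[accept]
        self.eta[accept] += dpsi
        self.lam[accept] = self.data.E[accept] * np.exp(self.eta[accept])
        self.ad_v.update(accept.astype(float))

    def _recenter(self):
        """Transfer the mean of the intrinsic component into mu."""
        if not self.intrinsic:
            return
        m = self.u.mean()
        if m == 0.0:
            return
        if self.adaptive:
            # level not exactly transferable (weights vary by area):
            # Metropolis translation move along the intrinsic flat direction
            delta = 0.5 * self.rng.standard_normal()
            a, _ = self._weights()
            dll = (
                0.0
                if self.cfg.prior_only
                else float(
                    np.sum(self.data.y * a * delta)
                    - np.sum(self.lam * np.expm1(a * delta))
                )
            )
            if np.log(self.rng.random()) < dll:
                self.u += delta
                self._refresh_eta()
            return
        self.u -= m
        if self.convolution and self.model != "bym":
            m = np.sqrt(self.c) * m
        self.mu += m
        # eta and lam are unchanged by construction

    def _update_mu(self):
        step = self.ad_mu.step[0]
        delta = step * self.rng.standard_normal()
        if self.cfg.prior_only:
            dll = 0.0
        else:
            dll = float(
                delta * self.data.y.sum() - np.expm1(delta) * self.lam.sum()
            )
        sd = self.cfg.prior_mu_sd
        dprior = -((self.mu + delta) ** 2 - self.mu**2) / (2 * sd**2)
        acc = np.log(self.rng.random()) < dll + dprior
        if acc:
            self.mu += delta
            self.eta += delta
            self.lam *= np.exp(delta)
        self.ad_mu.update(np.array([float(acc)]))

    def _update_beta(self):
        X = self.data.X
        sd = self.cfg.prior_mu_sd
        accs = np.zeros(self.data.p)
        for j in range(self.data.p):
            step = self.ad_beta.step[j]
            delta = step * self.rng.standard_normal()
            xj = X[:, j]
            if self.cfg.prior_only:
                dll = 0.0
            else:
                dll = float(
                    delta * np.dot(self.data.y, xj)
                    - np.dot(self.lam, np.expm1(delta * xj))
                )
            b = self.beta[j]
            dprior = -((b + delta) ** 2 - b**2) / (2 * sd**2)
            if np.log(self.rng.random()) < dll + dprior:
                self.beta[j] = b + delta
                self.eta += delta * xj
                self.lam = self.data.E * np.exp(self.eta)
                self.xb += delta * xj
                accs[j] = 1.0
        self.ad_beta.update(accs)

    # -- c updates ---------------------------------------------------------
    def _log_beta_prior(self, c):
        a, b = self.cfg.prior_c
        return (a - 1.0) * np.log(c) + (b - 1.0) * np.log1p(-c)

    def _car_c_logdens(self, c):
        """log prior density of u under pCAR/LCAR at parameter c
        (0.5 log|K(c)| - u'K(c)u / (2 sigma^2)), constants dropped."""
        if self.model == "pcar":
            logdet = np.sum(np.log1p(-c * self.alpha))
            quad = self.quad_D - c * self.quad_W
        else:
            logdet = np.sum(np.log(c * self.lam_q1 + (1.0 - c)))
            quad = c * self.quad_Q1 + (1.0 - c) * self.quad_I
        return 0.5 * logdet - quad / (2.0 * self.sigma**2)

    def _update_c_car(self):
        u = self.u
        Wu = self.W @ u
        self.quad_D = float(np.dot(self.wplus * u, u))
        self.quad_W = float(np.dot(u, Wu))
        self.quad_Q1 = self.quad_D - self.quad_W
        self.quad_I = float(np.dot(u, u))
        step = self.ad_c.step[0]
        z = _logit(self.c) + step * self.rng.standard_normal()
        cnew = _expit(z)
        if self.model == "pcar" and not (self.cmin < cnew < self.cmax):
            self.ad_c.update(np.zeros(1))
            return
        dpost = (
            self._car_c_logdens(cnew)
            - self._car_c_logdens(self.c)
            + self._log_beta_prior(cnew)
            - self._log_beta_prior(self.c)
            # Jacobian of the logit transform
            + np.log(cnew) + np.log1p(-cnew)
            - np.log(self.c) - np.log1p(-self.c)
        )
        acc = np.log(self.rng.random()) < dpost
        if acc:
            self.c = float(cnew)
        self.ad_c.update(np.array([float(acc)]))

    def _update_c_conv(self):
        """(M)BYM weight: c enters only through psi = sqrt(c) u + sqrt(1-c) v."""
        if self.adaptive:
            step = self.ad_c.step
            z = _logit(self.c) + step * self.rng.standard_normal(self.n)
            cnew = _expit(z)
            dpsi = (
                np.sqrt(cnew) * self.u + np.sqrt(1 - cnew) * self.v
            ) - self.psi()
            dll = (
                np.zeros(self.n)
                if self.cfg.prior_only
                else self.data.y * dpsi - self.lam * np.expm1(dpsi)
            )
            dpost = (
                dll
                + self._log_beta_prior(cnew) - self._log_beta_prior(self.c)
                + np.log(cnew) + np.log1p(-cnew)
                - np.log(self.c) - np.log1p(-self.c)
            )
            accept = np.log(self.rng.random(self.n)) < dpost
            self.c = np.where(accept, cnew, self.c)
            self._refresh_eta()
            self.ad_c.update(accept.astype(float))
            return
        step = self.ad_c.step[0]
        z = _logit(self.c) + step * self.rng.standard_normal()
        cnew = float(_expit(z))
        dpsi = (np.sqrt(cnew) * self.u + np.sqrt(1 - cnew) * self.v) - self.psi()
        if self.cfg.prior_only:
            dll = 0.0
        else:
            dll = float(np.sum(self.data.y * dpsi - self.lam * np.expm1(dpsi)))
        dpost = (
            dll
            + self._log_beta_prior(cnew) - self._log_beta_prior(self.c)
            + np.log(cnew) + np.log1p(-cnew)
            - np.log(self.c) - np.log1p(-self.c)
        )
        acc = np.log(self.rng.random()) < dpost
        if acc:
            self.c = cnew
            self._refresh_eta()
        self.ad_c.update(np.array([float(acc)]))

    # -- scale updates ------------------------------------------------------
    def _log_sigma_prior(self, sigma):
        kind, val = self.cfg.prior_sigma
        if kind == "uniform":
            return 0.0 if sigma < val else -np.inf
        return -(sigma**2) / (2.0 * val**2)

    def _sigma_quad_rank(self, which):
        """Quadratic form and rank governing one scale parameter."""
        u, v = self.u, self.v if self.convolution else None
        n = self.n
        if self.model == "pcar":
            Wu = self.W @ u
            return float(np.dot(self.wplus * u, u) - self.c * np.dot(u, Wu)), n
        if self.model == "lcar":
            Wu = self.W @ u
            q1 = np.dot(self.wplus * u, u) - np.dot(u, Wu)
            return float(self.c * q1 + (1 - self.c) * np.dot(u, u)), n
        quad_u = float(
            self.s2 * (np.dot(self.wplus * u, u) - np.dot(u, self.W @ u))
        )
        if self.model in ("icar", "scaled_icar"):
            return quad_u, n - 1
        if self.model == "bym":
            if which == "sigma_s":
                return quad_u, n - 1
            return float(np.dot(v, v)), n
        # mbym family: one sigma for both components
        return quad_u + float(np.dot(v, v)), 2 * n - 1

    def _update_sigma(self):
        accs = np.zeros(self.ad_sig.log_step.size)
        for slot, name in enumerate(self.sample_sig):
            sigma = getattr(self, name)
            step = self.ad_sig.step[slot]
            snew = float(sigma * np.exp(step * self.rng.standard_normal()))
            lp_new = self._log_sigma_prior(snew)
            if not np.isfinite(lp_new):
                continue
            quad, rank = self._sigma_quad_rank(name)
            dpost = (
                -rank * (np.log(snew) - np.log(sigma))
                - quad / 2.0 * (snew**-2 - sigma**-2)
                + lp_new - self._log_sigma_prior(sigma)
                + np.log(snew) - np.log(sigma)  # log-scale Jacobian
            )
            if np.log(self.rng.random()) < dpost:
                setattr(self, name, snew)
                accs[slot] = 1.0
        self.ad_sig.update(accs)

    # -- one sweep -----------------------------------------------------------
    def sweep(self):
        diag, coef = self._u_prior_prec()
        if self.convolution:
            a, _ = self._weights()
            self._update_field(self.u, self.ad_u, diag, coef, a)
            self._update_v()
        else:
            self._update_field(self.u, self.ad_u, diag, coef, 1.0)
        self._recenter()
        self._update_mu()
        if self.data.p:
            self._update_beta()
        if self.sample_c:
            if self.convolution:
                self._update_c_conv()
            else:
                self._update_c_car()
        if self.sample_sig:
            self._update_sigma()
        if not np.all(np.isfinite(self.lam)):
            raise FloatingPointError(
                f"non-finite Poisson mean encountered; state: mu={self.mu}, "
                f"sigma={getattr(self, 'sigma', None)}, c={self.c}"
            )

    def freeze_adaptation(self):
        for ad in (self.ad_u, self.ad_v, self.ad_mu, self.ad_beta, self.ad_c, self.ad_sig):
            if ad is not None:
                ad.frozen = True


def fit(
    graph: AdjacencyGraph,
    data: DiseaseMapData,
    spec: CARSpec,
    config: GLMMConfig | None = None,
) -> PosteriorDraws:
    """Fit the Poisson GLMM with the spatial prior given by ``spec``.

    ``spec`` supplies the model and initial values for its parameters
    (which are sampled unless listed in ``config.fixed``).  Runs
    ``config.chains`` independent chains sequentially; with the same seed
    and configuration the output is bit-for-bit reproducible.
    """
    config = config or GLMMConfig()
    if data.n != graph.n:
        raise ValueError(f"data has {data.n} areas but graph has {graph.n}")
    if spec.model in gmrf.ICAR_CONTAINING and graph.has_islands:
        raise ValueError("intrinsic-CAR component undefined for island areas")

    n_keep = (config.iters - config.burnin) // config.thin
    C = config.chains
    model = spec.model
    conv = model in gmrf.CONVOLUTION_MODELS
    adaptive = model in ("adaptive_mbym", "adaptive_scaled_mbym")

    mu = np.empty((C, n_keep))
    psi = np.empty((C, n_keep, graph.n))
    gamma = np.empty((C, n_keep, graph.n))
    beta = np.empty((C, n_keep, data.p)) if data.p else None
    c_store = None
    if model not in ("icar", "scaled_icar", "bym"):
        c_store = np.empty((C, n_keep, graph.n) if adaptive else (C, n_keep))
    sig = sig_s = sig_h = None
    if model == "bym":
        sig_s = np.empty((C, n_keep))
        sig_h = np.empty((C, n_keep))
    else:
        sig = np.empty((C, n_keep))
    psi_s = np.empty((C, n_keep, graph.n)) if conv else None
    psi_h = np.empty((C, n_keep, graph.n)) if conv else None

    seeds = np.random.SeedSequence(config.seed).spawn(C)
    acc_rates = {}
    for ch in range(C):
        rng = np.random.default_rng(seeds[ch])
        smp = _Sampler(graph, data, spec, config, rng)
        kept = 0
        for it in range(config.iters):
            if it == config.burnin:
                smp.freeze_adaptation()
            smp.sweep()
            if it >= config.burnin and (it - config.burnin) % config.thin == 0:
                mu[ch, kept] = smp.mu
                cur_psi = smp.psi()
                psi[ch, kept] = cur_psi
                gamma[ch, kept] = np.exp(smp.mu + smp.xb + cur_psi)
                if data.p:
                    beta[ch, kept] = smp.beta
                if c_store is not None:
                    c_store[ch, kept] = smp.c
                if model == "bym":
                    sig_s[ch, kept] = smp.sigma_s
                    sig_h[ch, kept] = smp.sigma_h
                    psi_s[ch, kept] = smp.u
                    psi_h[ch, kept] = smp.v
                elif conv:
                    sig[ch, kept] = smp.sigma
                    a, b = smp._weights()
                    psi_s[ch, kept] = a * smp.u
                    psi_h[ch, kept] = b * smp.v
                else:
                    sig[ch, kept] = smp.sigma
                kept += 1
        rates = {"psi": smp.ad_u.rate, "mu": smp.ad_mu.rate}
        if smp.ad_v is not None:
            rates["psi_h"] = smp.ad_v.rate
        if smp.sample_c:
            rates["c"] = smp.ad_c.rate
        if smp.sample_sig:
            rates["sigma"] = smp.ad_sig.rate
        acc_rates[f"chain{ch}"] = rates

    return PosteriorDraws(
        model=model,
        mu=mu,
        psi=psi,
        gamma=gamma,
        E=data.E.copy(),
        beta=beta,
        c=c_store,
        sigma=sig,
        sigma_s=sig_s,
        sigma_h=sig_h,
        psi_s=psi_s,
        psi_h=psi_h,
        accept_rates=acc_rates,
    )


def _ess_rhat(arr: np.ndarray) -> tuple[float, float]:
    """Bulk effective sample size and split-Rhat for (chains, draws)."""
    import arviz as az

    if arr.std() == 0:
        return float(arr.size), np.nan
    return float(az.ess(arr)), float(az.rhat(arr)) if arr.shape[0] > 1 else np.nan


def summarize(
    draws: PosteriorDraws, quantities: list[str] | None = None, diagnostics: bool = True
) -> pd.DataFrame:
    """Posterior summary table: median, sd, equal-tailed 95% interval,
    effective sample size and split-Rhat per quantity (per area for
    vector quantities)."""
    if draws.n_draws < 2:
        raise ValueError("need at least 2 retained draws to summarize")
    if quantities is None:
        quantities = draws.scalar_names() + ["psi", "gamma"]
        if draws.beta is not None:
            quantities.insert(1, "beta")
        if draws.psi_s is not None:
            quantities += ["psi_s", "psi_h"]
        if draws.c is not None and draws.c.ndim == 3:
            quantities.append("c")
    rows = []
    for name in quantities:
        arr = getattr(draws, name)
        if arr is None:
            continue
        comps = [None] if arr.ndim == 2 else range(arr.shape[2])
        for j in comps:
            x = arr if j is None else arr[:, :, j]
            flatx = x.reshape(-1)
            lo, med, hi = np.percentile(flatx, [2.5, 50.0, 97.5])
            row = {
                "quantity": name,
                "area": j,
                "median": med,
                "sd": float(flatx.std(ddof=1)),
                "q2.5": lo,
                "q97.5": hi,
            }
            if diagnostics:
                ess, rhat = _ess_rhat(x)
                row["ess"] = ess
                row["rhat"] = rhat
            rows.append(row)
    return pd.DataFrame(rows)


def poisson_log_pmf(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Pointwise Poisson log pmf including the log(y!) constant."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("Poisson means must be positive")
    lgam = np.vectorize(lgamma)(y + 1.0)
    return y * np.log(lam) - lam - lgam
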