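"""Gaussian (Markov) random fields for areal disease mapping.

Implements the family of conditionally specified spatial priors used as
random-effect distributions in Bayesian disease mapping:

* ``icar``   — intrinsic CAR, singular precision :math:`\\sigma^{-2} Q(1)`
  with :math:`Q(c) = D_w - cW`; rank ``n - 1``, used with a sum-to-zero
  constraint.
* ``pcar``   — proper CAR, precision :math:`\\sigma^{-2} Q(c)` with the
  spatial dependence parameter ``c`` inside a spectral validity interval.
* ``lcar``   — Leroux et al. CAR, precision
  :math:`\\sigma^{-2}(c\\,Q(1) + (1-c) I)`, a precision-weighted mix of the
  intrinsic CAR and independent Gaussian noise.
* ``bym``    — Besag–York–Mollié convolution :math:`\\psi = \\psi_s + \\psi_h`
  with :math:`\\psi_s \\sim \\mathrm{iCAR}(\\sigma_s^2)` and IID
  :math:`\\psi_h \\sim N(0, \\sigma_h^2)`.
* ``mbym``   — the reparameterized BYM
  :math:`\\psi = \\sqrt{c}\\,\\phi_s + \\sqrt{1-c}\\,\\phi_h` with a single
  scale; its covariance is :math:`\\sigma^2(c\\,Q(1)^- + (1-c) I)`.
* ``scaled_icar`` / ``scaled_mbym`` — the same fields with the intrinsic
  block rescaled by the reference standard deviation ``s`` so that the
  geometric mean of its marginal variances is ``1/tau`` (the BYM2
  convention).
* ``adaptive_mbym`` / ``adaptive_scaled_mbym`` — per-area weights
  :math:`c_i \\in (0,1)`, covariance
  :math:`\\sigma^2(C^{1/2} Q(1)^- C^{1/2} + (I - C))`.

The generalized inverse :math:`Q(1)^-` is the Moore–Penrose pseudo-inverse,
which equals the intrinsic-CAR covariance under the sum-to-zero constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import scipy.linalg as sla

from .lattice import AdjacencyGraph, structure_matrix

__all__ = [
    "CAR_MODELS",
    "CONVOLUTION_MODELS",
    "ICAR_CONTAINING",
    "CARSpec",
    "FieldLaw",
    "ScalingInfo",
    "SpectralRange",
    "precision",
    "covariance",
    "valid_range",
    "scaling",
    "sample_field",
    "DENSE_CAP",
]

CAR_MODELS = ("icar", "pcar", "lcar", "scaled_icar")
CONVOLUTION_MODELS = (
    "bym",
    "mbym",
    "scaled_mbym",
    "adaptive_mbym",
    "adaptive_scaled_mbym",
)
ALL_MODELS = CAR_MODELS + CONVOLUTION_MODELS
#: models whose spatial block is the (possibly scaled) intrinsic CAR
ICAR_CONTAINING = ("icar", "scaled_icar") + CONVOLUTION_MODELS
ADAPTIVE_MODELS = ("adaptive_mbym", "adaptive_scaled_mbym")

#: dense covariance computations refuse to run beyond this many areas
DENSE_CAP = 3000


@dataclass(frozen=True)
class CARSpec:
    """Parameterization of one spatial prior.

    Exactly the parameters the chosen model uses must be given: ``sigma``
    for every model, ``c`` for all but ``icar``/``scaled_icar`` and ``bym``
    (scalar, or a length-n vector in ``(0,1)`` for adaptive models), and
    ``sigma_s``/``sigma_h`` instead of ``sigma`` for ``bym``.
    """

    model: str
    c: float | np.ndarray | None = None
    sigma: float | None = None
    sigma_s: float | None = None
    sigma_h: float | None = None

    def __post_init__(self):
        if self.model not in ALL_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "bym":
            if self.sigma is not None or self.c is not None:
                raise ValueError("bym takes sigma_s and sigma_h, not sigma/c")
            if self.sigma_s is None or self.sigma_h is None:
                raise ValueError("bym requires sigma_s and sigma_h")
            if self.sigma_s <= 0 or self.sigma_h <= 0:
                raise ValueError("bym scales must be positive")
            return
        if self.sigma_s is not None or self.sigma_h is not None:
            raise ValueError(f"{self.model} does not take sigma_s/sigma_h")
        if self.sigma is None or self.sigma <= 0:
            raise ValueError(f"{self.model} requires sigma > 0")
        if self.model in ("icar", "scaled_icar"):
            if self.c is not None:
                raise ValueError(f"{self.model} takes no spatial parameter c")
            return
        if self.c is None:
            raise ValueError(f"{self.model} requires a spatial parameter c")
        c = np.asarray(self.c, dtype=float)
        if self.model in ADAPTIVE_MODELS:
            if c.ndim != 1:
                raise ValueError(f"{self.model} requires a per-area c vector")
            if np.any(c <= 0) or np.any(c >= 1):
                raise ValueError("adaptive weights must all lie in (0, 1)")
        else:
            if c.ndim != 0:
                raise ValueError(f"{self.model} takes a scalar c")
            if self.model in ("lcar", "mbym", "scaled_mbym") and not 0 <= c <= 1:
                # c = 0 and c = 1 are admitted as the IID and iCAR limits
                raise ValueError(f"{self.model} requires c in [0, 1]")

    def with_c(self, c) -> "CARSpec":
        return replace(self, c=c)


@dataclass(frozen=True)
class FieldLaw:
    """A fully materialized Gaussian field: precision and/or covariance.

    ``Omega`` is absent for convolution models, whose closed form is the
    covariance; ``Sigma`` is absent when only the (possibly singular)
    precision was requested.  ``B`` is the spatial dependence matrix of the
    CAR conditionals (``B_ik`` is the coefficient of influence of area k on
    area i); ``rank`` the matrix rank of ``Omega``; ``constraint`` is
    ``"sum_to_zero"`` for intrinsic fields.
    """

    model: str
    Omega: np.ndarray | None = field(default=None, repr=False)
    Sigma: np.ndarray | None = field(default=None, repr=False)
    B: np.ndarray | None = field(default=None, repr=False)
    rank: int | None = None
    constraint: str = "none"


@dataclass(frozen=True)
class SpectralRange:
    """Validity interval for the proper-CAR dependence parameter.

    Bounds are the reciprocals of the extreme eigenvalues of the
    symmetrized adjacency ``D_w^{-1/2} W D_w^{-1/2}``; for a connected
    graph ``cmax = 1`` and ``cmin < 0``.
    """

    cmin: float
    cmax: float

    def contains(self, c: float) -> bool:
        return self.cmin < c < self.cmax


@dataclass(frozen=True)
class ScalingInfo:
    """Reference standard deviation and scaled intrinsic-CAR quantities.

    ``s = exp((1/2n) sum_i log Sigma*_ii)`` where ``Sigma*`` is the
    pseudo-inverse of ``D_w - W``; the scaled precision is
    ``tau_s = s^2 tau``, chosen so that the geometric mean of the marginal
    variances of ``(tau_s (D_w - W))^-`` equals ``1/tau``.
    """

    s: float
    tau: float
    tau_s: float
    Sigma_star: np.ndarray = field(repr=False)
    Sigma_scaled: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"s": self.s, "tau": self.tau, "tau_s": self.tau_s}


def _check_cap(n: int) -> None:
    if n > DENSE_CAP:
        raise ValueError(
            f"dense field computation for n={n} exceeds the cap of {DENSE_CAP} areas"
        )


@lru_cache(maxsize=8)
def _laplacian_eigh(graph: AdjacencyGraph):
    """Eigen-decomposition of Q(1); cached per graph object (identity hash)."""
    Q1 = structure_matrix(graph, 1.0).toarray().astype(float)
    lam, V = np.linalg.eigh(Q1)
    return lam, V


def q1_pinv(graph: AdjacencyGraph) -> np.ndarray:
    """Moore–Penrose pseudo-inverse of ``Q(1) = D_w - W`` (``Sigma*``)."""
    _check_cap(graph.n)
    lam, V = _laplacian_eigh(graph)
    inv = np.where(lam > 1e-10 * lam.max(), 1.0 / np.where(lam > 0, lam, 1.0), 0.0)
    return (V * inv) @ V.T


def valid_range(graph: AdjacencyGraph) -> SpectralRange:
    """Spectral validity interval for the proper-CAR parameter ``c``."""
    if graph.has_islands:
        raise ValueError("valid_range undefined for graphs with island areas")
    _check_cap(graph.n)
    d = 1.0 / np.sqrt(graph.wplus.astype(float))
    M = d[:, None] * graph.W.toarray() * d[None, :]
    ev = np.linalg.eigvalsh(M)
    return SpectralRange(cmin=float(1.0 / ev[0]), cmax=float(1.0 / ev[-1]))


def scaling(graph: AdjacencyGraph, tau: float = 1.0) -> ScalingInfo:
    """Reference standard deviation ``s`` and scaled-iCAR covariance."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not graph.is_connected:
        raise ValueError(
            "scaling requires a connected graph: the pseudo-inverse would mix components"
        )
    Sigma_star = q1_pinv(graph)
    d = np.diag(Sigma_star)
    s = float(np.exp(np.mean(np.log(d)) / 2.0))
    tau_s = s * s * tau
    return ScalingInfo(
        s=s, tau=tau, tau_s=tau_s, Sigma_star=Sigma_star,
        Sigma_scaled=Sigma_star / tau_s,
    )


def _check_pcar_c(graph: AdjacencyGraph, c: float) -> None:
    rng = valid_range(graph)
    if not (rng.contains(c) or c == 0.0):
        raise ValueError(
            f"pCAR parameter c={c} outside validity range ({rng.cmin:.4f}, {rng.cmax:.4f})"
        )


def precision(graph: AdjacencyGraph, spec: CARSpec) -> FieldLaw:
    """Precision matrix (and dependence matrix B) of a CAR field.

    Only the Markov models have a sparse closed-form precision; the
    convolution models are specified through :func:`covariance`.
    """
    if spec.model not in CAR_MODELS:
        raise ValueError(f"precision is defined for {CAR_MODELS}, not {spec.model!r}")
    _check_cap(graph.n)
    n = graph.n
    sig2 = spec.sigma**2
    W = graph.W.toarray().astype(float)
    Dw = np.diag(graph.wplus.astype(float))
    if spec.model == "pcar":
        _check_pcar_c(graph, spec.c)
        if graph.has_islands:
            raise ValueError("pCAR conditional variance undefined for island areas")
        Omega = (Dw - spec.c * W) / sig2
        rank, constraint = (n - 1, "sum_to_zero") if spec.c == 1.0 else (n, "none")
    elif spec.model == "lcar":
        Omega = (spec.c * (Dw - W) + (1.0 - spec.c) * np.eye(n)) / sig2
        rank, constraint = (n - 1, "sum_to_zero") if spec.c == 1.0 else (n, "none")
    elif spec.model == "icar":
        if graph.has_islands:
            raise ValueError("iCAR undefined for island areas (w_i+ = 0)")
        Omega = (Dw - W) / sig2
        rank, constraint = n - 1, "sum_to_zero"
    else:  # scaled_icar
        if graph.has_islands:
            raise ValueError("iCAR undefined for island areas (w_i+ = 0)")
        info = scaling(graph, tau=1.0 / sig2)
        Omega = info.tau_s * (Dw - W)
        rank, constraint = n - 1, "sum_to_zero"
    diag = np.diag(Omega).copy()
    B = np.eye(n) - Omega / diag[:, None]
    return FieldLaw(
        model=spec.model, Omega=Omega, B=B, rank=rank, constraint=constraint
    )


def covariance(graph: AdjacencyGraph, spec: CARSpec) -> FieldLaw:
    """Dense covariance matrix of any supported field.

    For intrinsic fields this is the covariance under the sum-to-zero
    constraint (the pseudo-inverse of the precision); for convolution
    models it is the closed-form weighted sum of the intrinsic and IID
    blocks.
    """
    _check_cap(graph.n)
    n = graph.n
    model = spec.model
    if model in ("pcar", "lcar"):
        law = precision(graph, spec)
        if (model == "pcar" and spec.c == 1.0) or (model == "lcar" and spec.c == 1.0):
            Sigma = sla.pinvh(law.Omega)
        else:
            Sigma = sla.inv(law.Omega)
        return replace(law, Sigma=Sigma)
    if model in ("icar", "scaled_icar"):
        law = precision(graph, spec)
        Sstar = q1_pinv(graph)
        if model == "icar":
            Sigma = spec.sigma**2 * Sstar
        else:
            info = scaling(graph, tau=1.0 / spec.sigma**2)
            Sigma = Sstar / info.tau_s
        return replace(law, Sigma=Sigma)

    # convolution models: closed form is the covariance
    Sstar = q1_pinv(graph)
    I = np.eye(n)
    if model == "bym":
        Sigma = spec.sigma_s**2 * Sstar + spec.sigma_h**2 * I
    elif model == "mbym":
        Sigma = spec.sigma**2 * (spec.c * Sstar + (1.0 - spec.c) * I)
    elif model == "scaled_mbym":
        s2 = scaling(graph).s ** 2
        Sigma = spec.sigma**2 * (spec.c * Sstar / s2 + (1.0 - spec.c) * I)
    else:
        cvec = np.asarray(spec.c, dtype=float)
        if cvec.shape != (n,):
            raise ValueError(f"adaptive c must have length n={n}")
        root = np.sqrt(cvec)
        block = Sstar if model == "adaptive_mbym" else Sstar / scaling(graph).s ** 2
        Sigma = spec.sigma**2 * (
            root[:, None] * block * root[None, :] + np.diag(1.0 - cvec)
        )
    return FieldLaw(model=model, Sigma=Sigma, rank=n, constraint="none")


def _icar_sampler(graph: AdjacencyGraph, scale: float):
    """Return a function drawing exact intrinsic-CAR fields of given scale.

    Sampling happens in the eigenbasis of Q(1) with the null eigenvector
    excluded, which enforces the sum-to-zero constraint exactly.
    """
    lam, V = _laplacian_eigh(graph)
    keep = lam > 1e-10 * lam.max()
    Vk = V[:, keep]
    sd = scale / np.sqrt(lam[keep])

    def draw(rng, ndraws):
        z = rng.standard_normal((ndraws, int(keep.sum())))
        return (z * sd) @ Vk.T

    return draw


def sample_field(
    graph: AdjacencyGraph, spec: CARSpec, ndraws: int, seed=None
) -> np.ndarray:
    """Exact multivariate-normal draws from the field, shape (ndraws, n).

    ``seed`` may be an int or a ``numpy.random.Generator``.  Intrinsic
    draws satisfy the sum-to-zero constraint to machine precision;
    convolution draws are assembled componentwise as
    ``sqrt(c) * phi_s + sqrt(1-c) * phi_h``.
    """
    if ndraws < 1:
        raise ValueError("ndraws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = graph.n
    model = spec.model

    if model in ("icar", "scaled_icar"):
        scale = spec.sigma
        if model == "scaled_icar":
            scale = spec.sigma / scaling(graph).s
        return _icar_sampler(graph, scale)(rng, ndraws)

    if model in ("pcar", "lcar"):
        law = precision(graph, spec)
        if law.rank < n:  # c == 1 limit: intrinsic
            return _icar_sampler(graph, spec.sigma)(rng, ndraws)
        L = np.linalg.cholesky(law.Omega)
        z = rng.standard_normal((ndraws, n))
        return sla.solve_triangular(L.T, z.T, lower=False).T

    # convolution models
    icar_scale = spec.sigma_s if model == "bym" else spec.sigma
    if model in ("scaled_mbym", "adaptive_scaled_mbym"):
        icar_scale = spec.sigma / scaling(graph).s
    phi_s = _icar_sampler(graph, icar_scale)(rng, ndraws)
    iid_scale = spec.sigma_h if model == "bym" else spec.sigma
    phi_h = rng.standard_normal((ndraws, n)) * iid_scale
    if model == "bym":
        return phi_s + phi_h
    c = np.asarray(spec.c, dtype=float)
    return np.sqrt(c) * phi_s + np.sqrt(1.0 - c) * phi_h
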