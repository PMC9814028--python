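"""Dependence diagnostics: influence, conditional variance, correlations.

The CAR conditionals expose two local quantities with direct
epidemiological reading: the *coefficient of influence* ``B_ik`` of a
neighbouring area k on area i (how much a neighbour's risk pulls the
conditional mean) and the conditional (predictive) variance of an area
given the rest of the map.  The field's covariance matrix in turn defines
marginal correlation/covariance functions, which this module organizes by
neighbour order (graph distance from a chosen source area), and the
precision matrix defines partial correlations
``-Omega_ik / sqrt(Omega_ii Omega_kk)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from . import gmrf
from .lattice import AdjacencyGraph, neighbor_orders

__all__ = [
    "CorrelationProfile",
    "influence",
    "conditional_variance",
    "correlation_profile",
    "partial_correlation_profile",
]


@dataclass(frozen=True, eq=False)
class CorrelationProfile:
    """Per-area values of a (partial) correlation or covariance function
    with respect to one source area, grouped by neighbour order."""

    source: int
    kind: str  # correlation | covariance | partial_correlation
    values: np.ndarray = field(repr=False)
    order: np.ndarray = field(repr=False)
    constrained: bool = False  # intrinsic precision: defined up to constraint

    def by_order(self) -> pd.DataFrame:
        """Mean, min and max of the profile per neighbour order m >= 1."""
        df = self.to_frame()
        df = df[df["order"] > 0]
        out = df.groupby("order")["value"].agg(["mean", "min", "max", "count"])
        return out.reset_index()

    def to_frame(self) -> pd.DataFrame:
        """Tidy (area, order, value) table, 0-based areas."""
        return pd.DataFrame(
            {
                "area": np.arange(self.values.size),
                "order": self.order,
                "value": self.values,
            }
        )


def influence(model: str, c: float, wplus: int) -> float:
    """Coefficient of influence of a neighbour on an area with ``wplus``
    neighbours: ``c / w_i+`` for the proper CAR and
    ``c / (1 - c + c w_i+)`` for the Leroux CAR.

    The proper-CAR influence is linear in ``c``; the Leroux form is larger
    on ``0 < c < 1`` (the two coincide at ``c = 0`` and ``c = 1``).
    """
    if wplus < 1:
        raise ValueError("wplus must be >= 1")
    if not 0 < c <= 1:
        raise ValueError("influence is defined for c in (0, 1]")
    if model == "pcar":
        return c / wplus
    if model == "lcar":
        return c / (1.0 - c + c * wplus)
    raise ValueError(f"influence defined for pcar/lcar, not {model!r}")


def conditional_variance(model: str, c: float, sigma: float, wplus: int) -> float:
    """Conditional (predictive) variance of one area given the rest.

    ``sigma^2 / w_i+`` for the proper and intrinsic CARs (independent of
    c) and ``sigma^2 / (1 - c + c w_i+)`` for the Leroux CAR.
    """
    if wplus < 1:
        raise ValueError("wplus must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if model in ("pcar", "icar"):
        return sigma**2 / wplus
    if model == "lcar":
        if not 0 <= c <= 1:
            raise ValueError("lcar requires c in [0, 1]")
        return sigma**2 / (1.0 - c + c * wplus)
    raise ValueError(f"conditional_variance defined for pcar/lcar/icar, not {model!r}")


def correlation_profile(
    graph: AdjacencyGraph,
    spec: gmrf.CARSpec,
    k: int,
    mode: str = "correlation",
) -> CorrelationProfile:
    """Marginal correlation (or covariance) of every area with area ``k``."""
    if not 0 <= k < graph.n:
        raise ValueError(f"source area {k} outside 0..{graph.n - 1}")
    if mode not in ("correlation", "covariance"):
        raise ValueError(f"unknown mode {mode!r}")
    Sigma = gmrf.covariance(graph, spec).Sigma
    col = Sigma[:, k].copy()
    if mode == "correlation":
        col = col / np.sqrt(np.diag(Sigma) * Sigma[k, k])
    orders = neighbor_orders(graph, k).order
    return CorrelationProfile(source=k, kind=mode, values=col, order=orders)


def partial_correlation_profile(
    graph: AdjacencyGraph, spec: gmrf.CARSpec, k: int
) -> CorrelationProfile:
    """Partial correlation of every area with area ``k``:
    ``-Omega_ik / sqrt(Omega_ii Omega_kk)`` (1 at the source itself).

    For full-rank models the precision is obtained directly or by
    inverting the dense covariance.  For the singular intrinsic CAR the
    profile is computed from ``Q(1)/sigma^2`` itself and flagged
    ``constrained``: the precision is well defined even though the
    covariance is not full rank.
    """
    if not 0 <= k < graph.n:
        raise ValueError(f"source area {k} outside 0..{graph.n - 1}")
    constrained = False
    if spec.model in gmrf.CAR_MODELS:
        law = gmrf.precision(graph, spec)
        Omega = law.Omega
        constrained = law.constraint == "sum_to_zero"
    else:
        Sigma = gmrf.covariance(graph, spec).Sigma
        Omega = sla.inv(Sigma)
    vals = -Omega[:, k] / np.sqrt(np.diag(Omega) * Omega[k, k])
    vals[k] = 1.0
    orders = neighbor_orders(graph, k).order
    return CorrelationProfile(
        source=k,
        kind="partial_correlation",
        values=vals,
        order=orders,
        constrained=constrained,
    )
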