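"""Deviance-based model comparison: DIC and WAIC for the Poisson GLMM.

Both criteria are computed from the *conditional* Poisson likelihood
``p(y_i | lambda_i)``, so they focus on the fitted means and are invariant
to how the random effects are parameterized (BYM and MBYM chains that
encode the same lambda draws score identically).

* DIC = Dbar + pD, with Dbar the posterior mean deviance and the
  effective number of parameters pD = Dbar - D(lambda-bar), the plug-in
  deviance evaluated at the posterior mean of lambda (the
  reparameterization-invariant "number of free parameters" variant).
  An alternative plug-in at the posterior mean of log(lambda) is exposed
  through ``plugin="log_mean"``.
* WAIC = -2 lppd + 2 pWAIC2, with lppd the log pointwise predictive
  density and pWAIC2 the summed posterior variances of the pointwise
  log predictive density (sample variance, divisor T - 1).

The deviance includes the full ``log(y_i!)`` constant, so absolute scores
are well defined; constants cancel in pD and in model differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import DiseaseMapData, PosteriorDraws, poisson_log_pmf

logger = logging.getLogger(__name__)

__all__ = ["ComparisonScores", "deviance", "dic", "waic", "score", "preference_rate"]


@dataclass(frozen=True)
class ComparisonScores:
    """DIC and WAIC components for one fitted model."""

    Dbar: float
    pD: float
    DIC: float
    lppd: float
    pWAIC2: float
    WAIC: float

    def to_dict(self) -> dict:
        return {
            "Dbar": self.Dbar,
            "pD": self.pD,
            "DIC": self.DIC,
            "lppd": self.lppd,
            "pWAIC2": self.pWAIC2,
            "WAIC": self.WAIC,
        }


def deviance(y: np.ndarray, lam: np.ndarray) -> float:
    """Poisson deviance ``-2 sum_i [y_i log(lambda_i) - lambda_i - log(y_i!)]``."""
    return float(-2.0 * np.sum(poisson_log_pmf(y, lam)))


def _lambda_draws(draws: PosteriorDraws) -> np.ndarray:
    lam = draws.lambda_
    return lam.reshape(-1, lam.shape[-1])


def dic(
    draws: PosteriorDraws, data: DiseaseMapData, plugin: str = "mean"
) -> tuple[float, float, float]:
    """(Dbar, pD, DIC) from the lambda chains.

    ``plugin`` chooses the plug-in point for the effective-parameter
    count: the posterior mean of lambda (default) or of log(lambda).
    """
    lam = _lambda_draws(draws)
    if lam.shape[0] == 0:
        raise ValueError("no retained draws")
    devs = -2.0 * np.sum(poisson_log_pmf(data.y[None, :], lam), axis=1)
    Dbar = float(devs.mean())
    if plugin == "mean":
        lam_hat = lam.mean(axis=0)
    elif plugin == "log_mean":
        lam_hat = np.exp(np.log(lam).mean(axis=0))
    else:
        raise ValueError(f"unknown plugin {plugin!r}")
    pD = Dbar - deviance(data.y, lam_hat)
    return Dbar, float(pD), float(Dbar + pD)


def waic(draws: PosteriorDraws, data: DiseaseMapData) -> tuple[float, float, float]:
    """(lppd, pWAIC2, WAIC) from the lambda chains."""
    lam = _lambda_draws(draws)
    T = lam.shape[0]
    if T < 2:
        raise ValueError("pWAIC2 needs at least 2 draws (variance undefined)")
    logp = poisson_log_pmf(data.y[None, :], lam)  # (T, n)
    # lppd_i = log mean_t p(y_i | lam_i^t), computed stably
    m = logp.max(axis=0)
    lppd = float(np.sum(m + np.log(np.mean(np.exp(logp - m), axis=0))))
    pwaic2 = float(np.sum(logp.var(axis=0, ddof=1)))
    return lppd, pwaic2, float(-2.0 * lppd + 2.0 * pwaic2)


def score(draws: PosteriorDraws, data: DiseaseMapData) -> ComparisonScores:
    """All comparison scores for one fitted model."""
    Dbar, pD, DIC = dic(draws, data)
    lppd, pwaic2, WAIC = waic(draws, data)
    return ComparisonScores(Dbar=Dbar, pD=pD, DIC=DIC, lppd=lppd, pWAIC2=pwaic2, WAIC=WAIC)


def preference_rate(
    score_table: pd.DataFrame, true_model: str, criterion: str = "dic"
) -> pd.DataFrame:
    """Fraction of replicates in which the true model beats each rival.

    ``score_table`` is a tidy table with columns ``replicate``, ``model``
    and the score columns (``DIC``, ``WAIC``).  Preference is a strictly
    lower score for the true model; ties count as non-preference (and are
    logged).
    """
    col = {"dic": "DIC", "waic": "WAIC"}.get(criterion.lower())
    if col is None:
        raise ValueError(f"criterion must be 'dic' or 'waic', not {criterion!r}")
    if score_table.empty:
        raise ValueError("empty score table")
    wide = score_table.pivot(index="replicate", columns="model", values=col)
    if true_model not in wide.columns:
        raise ValueError(f"true model {true_model!r} missing from scores")
    if wide.isna().any().any():
        raise ValueError("missing scores for some (replicate, model) pairs")
    rows = []
    for rival in wide.columns:
        if rival == true_model:
            continue
        ties = int((wide[true_model] == wide[rival]).sum())
        if ties:
            logger.info(
                "%d tie(s) between %s and %s counted as non-preference",
                ties, true_model, rival,
            )
        rate = float((wide[true_model] < wide[rival]).mean())
        rows.append(
            {"true_model": true_model, "fitted_model": rival,
             "criterion": col, "rate": rate, "n_replicates": len(wide)}
        )
    return pd.DataFrame(rows)
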