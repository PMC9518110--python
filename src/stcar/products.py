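"""Posterior products: relative risks, exceedance probabilities, DIC, WAIC.

All functions take retained MCMC draws and the panel *the draws were fitted
on* (same covariate scaling) and reduce them to the quantities a disease-
mapping analysis reports: fixed-effect relative risks exp(beta) with
equal-tailed credible intervals, the area-time relative-risk surface
lambda_it, the exceedance probability P(lambda_it > T | data), and the
DIC/WAIC model-comparison criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .data import PanelData
from .sampler import PosteriorSamples

__all__ = [
    "fixed_effect_rr",
    "lambda_draws",
    "rr_surface",
    "exceedance_probability",
    "compute_dic",
    "compute_waic",
    "FitSummary",
    "compare_models",
]


def _ci(draws: np.ndarray, level: float = 0.95, axis: int = 0):
    a = (1.0 - level) / 2.0
    return (np.quantile(draws, a, axis=axis), np.quantile(draws, 1.0 - a, axis=axis))


def fixed_effect_rr(samples: PosteriorSamples, scale_means=None, scale_sds=None,
                    ci_level: float = 0.95) -> pd.DataFrame:
    """Relative risks exp(beta) per covariate, on the original covariate scale.

    If the model was fitted on standardized covariates, pass the means/sds
    used so coefficients are back-transformed (beta_orig = beta_std / sd)
    before exponentiation.
    """
    beta = samples.stacked("beta")
    m = beta.shape[1]
    sds = np.ones(m) if scale_sds is None else np.asarray(scale_sds, dtype=float)
    beta_orig = beta / sds[None, :]
    rr = np.exp(beta_orig)
    lo, hi = _ci(rr, ci_level)
    names = samples.covariate_names or tuple(f"x{k}" for k in range(m))
    return pd.DataFrame({
        "covariate": list(names),
        "rr_mean": rr.mean(axis=0),
        "rr_lower": lo,
        "rr_upper": hi,
        "beta_mean": beta_orig.mean(axis=0),
    })


def lambda_draws(samples: PosteriorSamples, data: PanelData) -> np.ndarray:
    """Per-draw relative-risk surface lambda_it = exp(eta_it), shape (S, n, Z)."""
    alpha = samples.stacked("alpha")
    beta = samples.stacked("beta")
    u = samples.stacked("u")
    v = samples.stacked("v")
    gamma = samples.stacked("gamma")
    psi = samples.stacked("psi")
    eta = (
        alpha[:, None, None]
        + (np.einsum("nzm,sm->snz", data.X, beta) if data.m else 0.0)
        + u[:, :, None] + v[:, :, None] + gamma[:, None, :] + psi
    )
    return np.exp(eta)


def rr_surface(samples: PosteriorSamples, data: PanelData, ci_level: float = 0.95,
               threshold: float | None = None) -> pd.DataFrame:
    """Long-format per-(region, time) relative-risk summary for mapping.

    Columns: region, time, rr_mean, rr_lower, rr_upper and, when a threshold
    is given, exceedance_prob = P(lambda_it > T | data).
    """
    lam = lambda_draws(samples, data)
    lo, hi = _ci(lam, ci_level)
    n, Z = data.n, data.Z
    out = pd.DataFrame({
        "region": np.repeat(data.graph.region_ids, Z),
        "time": np.tile(data.time_labels, n),
        "rr_mean": lam.mean(axis=0).ravel(),
        "rr_lower": lo.ravel(),
        "rr_upper": hi.ravel(),
    })
    if threshold is not None:
        out["exceedance_prob"] = exceedance_probability(samples, data, threshold).ravel()
    return out


def exceedance_probability(samples: PosteriorSamples, data: PanelData,
                           threshold: float = 1.0) -> np.ndarray:
    """P(lambda_it > T | data) per cell: the fraction of draws above T."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    lam = lambda_draws(samples, data)
    return (lam > threshold).mean(axis=0)


def _pointwise_loglik(samples: PosteriorSamples, data: PanelData) -> np.ndarray:
    """Per-draw, per-cell Poisson log p(Y_it | mu_it^(s)); shape (S, n, Z)."""
    lam = lambda_draws(samples, data)
    mu = lam * data.E[None, :, :]
    Y = data.Y[None, :, :]
    return Y * np.log(mu) - mu - gammaln(data.Y + 1.0)[None, :, :]


def compute_dic(samples: PosteriorSamples, data: PanelData):
    """Deviance information criterion.

    D(s) = -2 log p(Y | mu^(s)); pD = mean deviance minus the deviance of
    the cellwise posterior-mean linear predictor (plug-in at mean eta, the
    convention INLA reports); DIC = mean deviance + pD.  Returns
    ``(dic, p_d, mean_deviance)``.
    """
    ll = _pointwise_loglik(samples, data)
    dev = -2.0 * ll.sum(axis=(1, 2))
    dbar = float(dev.mean())
    lam = lambda_draws(samples, data)
    eta_bar = np.log(lam).mean(axis=0)
    mu_hat = data.E * np.exp(eta_bar)
    dhat = float(-2.0 * np.sum(data.Y * np.log(mu_hat) - mu_hat - gammaln(data.Y + 1.0)))
    pd_ = dbar - dhat
    return dbar + pd_, pd_, dbar


def compute_waic(samples: PosteriorSamples, data: PanelData):
    """Watanabe-Akaike criterion with the variance penalty; returns (waic, p_waic)."""
    ll = _pointwise_loglik(samples, data)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1))) if S > 1 else 0.0
    if not np.isfinite(lppd):
        raise FloatingPointError("WAIC computation underflowed")
    return -2.0 * (lppd - p_waic), p_waic


@dataclass
class FitSummary:
    """Portable summary of one fitted model, sufficient for comparison."""

    label: str
    fixed_effects: pd.DataFrame = field(repr=False)
    surface: pd.DataFrame = field(repr=False)
    dic: float = np.nan
    waic: float = np.nan
    p_d: float = np.nan
    p_waic: float = np.nan
    mean_deviance: float = np.nan
    data_hash: str = ""

    def criteria(self) -> dict:
        return {"dic": self.dic, "waic": self.waic, "pd": self.p_d,
                "p_waic": self.p_waic, "dbar": self.mean_deviance}


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted models by DIC (ascending), with delta columns.

    Ties are broken by WAIC, then by fewer effective parameters pD; the
    ranking is invariant to input order.  Fits must be of the same data —
    differing data hashes are an error.
    """
    rows = []
    for f in fits:
        if isinstance(f, FitSummary):
            rows.append({"model": f.label, "dic": f.dic, "waic": f.waic,
                         "pd": f.p_d, "dbar": f.mean_deviance, "data_hash": f.data_hash})
        else:  # fitted results object
            crit = f.criteria()
            rows.append({"model": getattr(f, "label", f.model.spec.interaction_type),
                         "dic": crit["dic"], "waic": crit["waic"], "pd": crit["pd"],
                         "dbar": crit["dbar"], "data_hash": f.model.data.data_hash()})
    if len(rows) < 2:
        raise ValueError("need >= 2 fits to compare")
    hashes = {r["data_hash"] for r in rows}
    if len(hashes) > 1:
        raise ValueError("fits were made on differing data; comparison refused")
    df = pd.DataFrame(rows).drop(columns="data_hash")
    df = df.sort_values(["dic", "waic", "pd", "model"], kind="mergesort").reset_index(drop=True)
    df["delta_dic"] = df["dic"] - df["dic"].iloc[0]
    df["delta_waic"] = df["waic"] - df["waic"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    df["best"] = df["rank"] == 1
    return df
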