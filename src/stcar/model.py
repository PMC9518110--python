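"""Model and Results objects for Bayesian spatio-temporal disease mapping.

`SpatioTemporalPoissonModel` bundles an areal count panel with a model
specification (which random-effect blocks are active, prior settings);
``fit()`` runs the Metropolis-within-Gibbs sampler and returns a
`SpatioTemporalPoissonResults` carrying the posterior draws, fixed-effect
relative risks, area-time risk surfaces, exceedance probabilities, model
criteria and convergence diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import replace

import numpy as np
import pandas as pd

from . import products
from .data import PanelData
from .graphs import RegionGraph
from .priors import ModelSpec, ModelStructures, ParameterState, linear_predictor, log_posterior
from .sampler import MCMCConfig, PosteriorSamples, diagnostics, run_chain

__all__ = ["SpatioTemporalPoissonModel", "SpatioTemporalPoissonResults"]


class SpatioTemporalPoissonModel:
    """Hierarchical Poisson model with BYM spatial, RW1 temporal and
    Knorr-Held interaction random effects.

    Parameters
    ----------
    data
        The observed panel (counts, at-risk totals, expected counts,
        covariates) on its original covariate scale.
    spec
        Model specification; defaults to the BYM + RW1 model without
        interaction.
    standardize
        Centre and scale covariates internally before sampling (improves
        MCMC conditioning); reported coefficients are always on the
        original scale.
    """

    def __init__(self, data: PanelData, spec: ModelSpec | None = None,
                 standardize: bool = True):
        self.data = data
        self.spec = spec if spec is not None else ModelSpec()
        if data.m:
            means = data.X.reshape(-1, data.m).mean(axis=0)
            sds = data.X.reshape(-1, data.m).std(axis=0)
            if np.any(sds == 0):
                flat = [data.covariate_names[k] for k in np.flatnonzero(sds == 0)]
                raise ValueError(f"constant covariates cannot be standardized: {flat}")
        else:
            means, sds = np.zeros(0), np.ones(0)
        self.standardize = bool(standardize)
        self.x_means = means if self.standardize else np.zeros(data.m)
        self.x_sds = sds if self.standardize else np.ones(data.m)
        X_fit = (data.X - self.x_means) / self.x_sds if data.m else data.X
        self._fit_data = PanelData(
            data.graph, data.Y, data.N, data.E, X_fit,
            data.covariate_names, data.time_labels,
        )
        self.structures = ModelStructures(data.graph, data.Z, self.spec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, graph: RegionGraph,
                       covariates=None, interaction: str = "none",
                       spec: ModelSpec | None = None, **kwargs) -> "SpatioTemporalPoissonModel":
        """Build from a long-format dataframe (columns region, time, Y, N, ...)."""
        data = PanelData.from_long_dataframe(df, graph, covariates)
        if spec is None:
            spec = ModelSpec(interaction_type=interaction)
        return cls(data, spec, **kwargs)

    def fit(self, seed: int, n_iter: int = 15_000, n_burnin: int = 5_000,
            thin: int = 5, n_chains: int = 4,
            config: MCMCConfig | None = None) -> "SpatioTemporalPoissonResults":
        """Sample the posterior and return a results object."""
        if config is None:
            config = MCMCConfig(n_iter=n_iter, n_burnin=n_burnin, thin=thin,
                                seed=seed, n_chains=n_chains)
        samples = run_chain(self._fit_data, self.spec, config, self.structures)
        return SpatioTemporalPoissonResults(self, samples)

    def log_posterior(self, state: ParameterState) -> float:
        """Unnormalized log-posterior at a state (standardized covariate scale)."""
        return log_posterior(state, self.spec, self._fit_data, self.structures)

    def linear_predictor(self, state: ParameterState):
        return linear_predictor(self._fit_data, state)

    @property
    def label(self) -> str:
        it = self.spec.interaction_type
        if not self.spec.include_temporal:
            return "spatial"
        return "spatio-temporal" if it == "none" else f"interaction {it}"


class SpatioTemporalPoissonResults:
    """Posterior draws plus every reported product of the fitted model."""

    def __init__(self, model: SpatioTemporalPoissonModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self._criteria = None
        self._diag = None

    # -- fixed effects --------------------------------------------------------

    def fixed_effect_rr(self, ci_level: float = 0.95) -> pd.DataFrame:
        """exp(beta) per covariate on the original scale, with equal-tailed CIs."""
        return products.fixed_effect_rr(
            self.samples, self.model.x_means, self.model.x_sds, ci_level)

    @property
    def params(self) -> pd.Series:
        """Posterior means: intercept (original scale) and covariate coefficients."""
        beta_std = self.samples.stacked("beta")
        beta = beta_std / self.model.x_sds[None, :] if self.model.data.m else beta_std
        alpha = self.samples.stacked("alpha")
        if self.model.data.m:
            alpha = alpha - beta_std @ (self.model.x_means / self.model.x_sds)
        vals = {"alpha": alpha.mean()}
        for k, nm in enumerate(self.model.data.covariate_names):
            vals[nm] = beta[:, k].mean()
        return pd.Series(vals)

    # -- surfaces -------------------------------------------------------------

    def rr_surface(self, ci_level: float = 0.95) -> pd.DataFrame:
        """Per-(region, time) relative-risk summary plus exceedance at the model's T."""
        return products.rr_surface(self.samples, self.model._fit_data,
                                   ci_level, self.model.spec.threshold)

    def exceedance_probability(self, threshold: float | None = None) -> np.ndarray:
        T = self.model.spec.threshold if threshold is None else threshold
        return products.exceedance_probability(self.samples, self.model._fit_data, T)

    # -- criteria -------------------------------------------------------------

    def criteria(self) -> dict:
        if self._criteria is None:
            dic, p_d, dbar = products.compute_dic(self.samples, self.model._fit_data)
            waic, p_waic = products.compute_waic(self.samples, self.model._fit_data)
            self._criteria = {"dic": dic, "pd": p_d, "dbar": dbar,
                              "waic": waic, "p_waic": p_waic}
        return dict(self._criteria)

    def dic(self) -> float:
        return self.criteria()["dic"]

    def waic(self) -> float:
        return self.criteria()["waic"]

    # -- diagnostics ----------------------------------------------------------

    def diagnostics(self) -> pd.DataFrame:
        if self._diag is None:
            self._diag = diagnostics(self.samples)
        return self._diag

    @property
    def converged(self) -> bool:
        d = self.diagnostics()
        return not bool(d["flagged"].any())

    @property
    def label(self) -> str:
        return self.model.label

    def to_fit_summary(self) -> products.FitSummary:
        crit = self.criteria()
        return products.FitSummary(
            label=self.label,
            fixed_effects=self.fixed_effect_rr(),
            surface=self.rr_surface(),
            dic=crit["dic"], waic=crit["waic"], p_d=crit["pd"],
            p_waic=crit["p_waic"], mean_deviance=crit["dbar"],
            data_hash=self.model.data.data_hash(),
        )

    # -- presentation ---------------------------------------------------------

    def summary(self, ci_level: float = 0.95) -> str:
        crit = self.criteria()
        fe = self.fixed_effect_rr(ci_level)
        diag = self.diagnostics()
        lines = [
            "Spatio-temporal Poisson disease-mapping model",
            "=" * 60,
            f"model:             {self.label}",
            f"regions x periods: {self.model.data.n} x {self.model.data.Z}",
            f"retained draws:    {self.samples.n_retained} "
            f"({self.samples.n_chains} chains)",
            f"converged:         {'yes' if self.converged else 'NO (R-hat > 1.05)'}",
            "",
            "Fixed effects (relative risk, original covariate scale)",
            "-" * 60,
        ]
        if len(fe):
            for _, r in fe.iterrows():
                lines.append(
                    f"  {r['covariate']:<24s} RR {r['rr_mean']:6.3f} "
                    f"({r['rr_lower']:.3f}-{r['rr_upper']:.3f})"
                )
        else:
            lines.append("  (no covariates)")
        lines += [
            "",
            "Model criteria",
            "-" * 60,
            f"  DIC  {crit['dic']:10.2f}   pD      {crit['pd']:8.2f}   "
            f"Dbar {crit['dbar']:10.2f}",
            f"  WAIC {crit['waic']:10.2f}   p_waic  {crit['p_waic']:8.2f}",
            "",
            f"Acceptance rates: "
            + ", ".join(f"{b}={r:.2f}" for b, r in self.samples.acceptance.items()),
            f"Worst R-hat: {np.nanmax(diag['rhat']):.4f}"
            if np.isfinite(diag["rhat"]).any() else "R-hat unavailable (single chain)",
        ]
        return "\n".join(lines)

    def save_artifacts(self, outdir, save_samples: bool = True):
        """Write summary CSVs, criteria JSON, diagnostics and sample archive."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fixed_effect_rr().to_csv(out / "fixed_effects.csv", index=False)
        self.rr_surface().to_csv(out / "rr_surface.csv", index=False)
        self.diagnostics().to_csv(out / "diagnostics.csv", index=False)
        crit = self.criteria() | {"converged": self.converged}
        (out / "criteria.json").write_text(json.dumps(crit, indent=2))
        (out / "summary.txt").write_text(self.summary() + "\n")
        if save_samples:
            self.samples.save(out / "samples.npz")
        provenance = {
            "config": self.samples.config,
            "model": self.model.spec.to_dict(),
            "data_hash": self.model.data.data_hash(),
            "label": self.label,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        return out
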