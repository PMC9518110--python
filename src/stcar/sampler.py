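"""Metropolis-within-Gibbs sampler for the spatio-temporal Poisson model.

Latent blocks (alpha, u, v, gamma, psi) are updated by adaptive random-walk
Metropolis, one site at a time; beta is updated as a joint block.  Site-wise
updates are vectorized over colour classes: sites of the same colour have no
structure-matrix cross terms and touch disjoint likelihood cells, so
accepting them simultaneously is identical to a sequential scan within the
class.  Precisions get exact conjugate Gamma updates using the structure
rank (not the dimension — essential for the intrinsic blocks).  Proposal
scales adapt by Robbins-Monro on the log scale during burn-in and are
frozen afterwards, preserving the stationary target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .data import PanelData
from .priors import (
    ModelSpec,
    ModelStructures,
    ParameterState,
    apply_constraints,
)
from .structures import StructureMatrix, quadratic_form

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "gibbs_update_precision",
    "mh_update_block",
    "run_chain",
    "diagnostics",
]

logger = logging.getLogger("stcar")

LATENT_BLOCKS = ("alpha", "beta", "u", "v", "gamma", "psi")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler run lengths and targets.  A seed is mandatory."""

    n_iter: int = 15_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int | None = None
    n_chains: int = 4
    target_accept_scalar: float = 0.44
    target_accept_block: float = 0.234
    adapt_until: int | None = None
    log_every: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("an explicit seed is required (no silent default)")
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")
        if self.adapt_until is None:
            object.__setattr__(self, "adapt_until", self.n_burnin)

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter, "n_burnin": self.n_burnin, "thin": self.thin,
            "seed": self.seed, "n_chains": self.n_chains,
            "target_accept_scalar": self.target_accept_scalar,
            "target_accept_block": self.target_accept_block,
            "adapt_until": self.adapt_until,
        }


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, dimensioned (chain, draw, ...)."""

    alpha: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    tau_u: np.ndarray
    tau_v: np.ndarray
    tau_gamma: np.ndarray
    tau_psi: np.ndarray
    log_post: np.ndarray
    acceptance: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    covariate_names: tuple = ()
    region_ids: tuple = ()
    time_labels: tuple = ()

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_retained(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened into the first axis."""
        arr = getattr(self, name)
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])

    def state_at(self, chain: int, draw: int) -> ParameterState:
        return ParameterState(
            float(self.alpha[chain, draw]), self.beta[chain, draw].copy(),
            self.u[chain, draw].copy(), self.v[chain, draw].copy(),
            self.gamma[chain, draw].copy(), self.psi[chain, draw].copy(),
            float(self.tau_u[chain, draw]), float(self.tau_v[chain, draw]),
            float(self.tau_gamma[chain, draw]), float(self.tau_psi[chain, draw]),
        )

    def save(self, path):
        """Checkpoint all draws plus config provenance to one .npz archive."""
        import json

        np.savez_compressed(
            path,
            alpha=self.alpha, beta=self.beta, u=self.u, v=self.v,
            gamma=self.gamma, psi=self.psi, tau_u=self.tau_u, tau_v=self.tau_v,
            tau_gamma=self.tau_gamma, tau_psi=self.tau_psi, log_post=self.log_post,
            meta=np.frombuffer(json.dumps({
                "acceptance": self.acceptance, "config": self.config,
                "covariate_names": list(self.covariate_names),
                "region_ids": list(self.region_ids),
                "time_labels": [str(t) for t in self.time_labels],
            }).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            return cls(
                alpha=z["alpha"], beta=z["beta"], u=z["u"], v=z["v"],
                gamma=z["gamma"], psi=z["psi"], tau_u=z["tau_u"], tau_v=z["tau_v"],
                tau_gamma=z["tau_gamma"], tau_psi=z["tau_psi"], log_post=z["log_post"],
                acceptance=meta["acceptance"], config=meta["config"],
                covariate_names=tuple(meta["covariate_names"]),
                region_ids=tuple(meta["region_ids"]),
                time_labels=tuple(meta["time_labels"]),
            )


def gibbs_update_precision(fieldv: np.ndarray, R: StructureMatrix, a: float, b: float,
                           rng: np.random.Generator) -> float:
    """Exact conjugate draw tau | field ~ Gamma(a + rank/2, b + field'R field / 2)."""
    if a <= 0 or b <= 0:
        raise ValueError("Gamma hyperparameters must be positive")
    qf = quadratic_form(R, np.asarray(fieldv, dtype=float).ravel())
    return float(rng.gamma(shape=a + 0.5 * R.rank, scale=1.0 / (b + 0.5 * qf)))


def _graph_colours(graph) -> list[np.ndarray]:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n))
    for i, nbrs in enumerate(graph.neighbours):
        g.add_edges_from((i, j) for j in nbrs)
    colouring = nx.greedy_color(g, strategy="largest_first")
    k = max(colouring.values()) + 1 if colouring else 0
    return [np.array(sorted(i for i, c in colouring.items() if c == col), dtype=int)
            for col in range(k)]


class _Engine:
    """Precomputed update machinery for one (data, spec) pair."""

    def __init__(self, data: PanelData, spec: ModelSpec, structures: ModelStructures):
        self.data = data
        self.spec = spec
        self.structures = structures
        n, Z = data.n, data.Z
        self.n, self.Z, self.m = n, Z, data.m
        self.Yrow = data.Y.sum(axis=1).astype(float)
        self.Ycol = data.Y.sum(axis=0).astype(float)
        self.Yflat = data.Y.ravel().astype(float)
        self.Ytot = float(data.Y.sum())
        # sparse matrices + diagonals for local quadratic-form deltas
        self.Rmat, self.Rdiag = {}, {}
        for b, R in structures.R.items():
            self.Rmat[b] = R.matrix
            self.Rdiag[b] = R.matrix.diagonal()
        # colour classes of conditionally independent sites
        region_cols = _graph_colours(data.graph)
        self.colours = {"u": region_cols, "v": [np.arange(n)]}
        if "gamma" in structures.R:
            self.colours["gamma"] = [np.arange(0, Z, 2), np.arange(1, Z, 2)]
        it = spec.interaction_type
        if it == "I":
            self.colours["psi"] = [np.arange(n * Z)]
        elif it == "II":
            base = np.arange(n)[:, None] * Z
            self.colours["psi"] = [
                (base + np.arange(0, Z, 2)[None, :]).ravel(),
                (base + np.arange(1, Z, 2)[None, :]).ravel(),
            ]
        elif it == "III":
            self.colours["psi"] = [
                (cls[:, None] * Z + np.arange(Z)[None, :]).ravel() for cls in region_cols
            ]
        # caches for the interweaving (aliased-direction Gibbs) moves and the
        # collapsed precision update
        self._Ru_dense = structures["u"].dense() if "u" in structures.R else None
        self._eig = {}
        self._eig_full = None
        for b in ("u", "gamma"):
            if b in structures.R:
                w, V = np.linalg.eigh(structures[b].dense())
                keep = w > 1e-8 * max(1.0, w.max())
                self._eig[b] = (w[keep], V[:, keep])
                if b == "u":
                    self._eig_full = (np.where(keep, w, 0.0), V)
        # per-covariate caches for the beta <-> psi aliased direction
        self._beta_psi = None
        if "psi" in structures.R and self.m:
            Rpsi = structures["psi"].matrix
            xs = [data.X[:, :, k].ravel() for k in range(self.m)]
            self._beta_psi = [(x, Rpsi @ x, float(x @ (Rpsi @ x))) for x in xs]

    def init_arrays(self, state: ParameterState) -> dict:
        from .priors import linear_predictor

        fieldv = linear_predictor(self.data, state)
        return {
            "alpha": float(state.alpha), "beta": state.beta.astype(float).copy(),
            "u": state.u.astype(float).copy(), "v": state.v.astype(float).copy(),
            "gamma": state.gamma.astype(float).copy(),
            "psi": state.psi.astype(float).reshape(-1).copy(),
            "tau": {b: state.tau(b) for b in ("u", "v", "gamma", "psi")},
            "eta": fieldv.eta.copy(), "mu": fieldv.mu.copy(),
        }

    def to_state(self, arr: dict) -> ParameterState:
        return ParameterState(
            arr["alpha"], arr["beta"].copy(), arr["u"].copy(), arr["v"].copy(),
            arr["gamma"].copy(), arr["psi"].reshape(self.n, self.Z).copy(),
            arr["tau"]["u"], arr["tau"]["v"], arr["tau"]["gamma"], arr["tau"]["psi"],
        )

    def refresh_mu(self, arr: dict):
        """Rebuild eta and mu from the component fields (kills float drift)."""
        eta = (
            arr["alpha"]
            + (self.data.X @ arr["beta"] if self.m else 0.0)
            + arr["u"][:, None] + arr["v"][:, None]
            + arr["gamma"][None, :] + arr["psi"].reshape(self.n, self.Z)
        )
        arr["eta"] = np.asarray(eta, dtype=float)
        arr["mu"] = self.data.E * np.exp(arr["eta"])

    # ---- local delta pieces -------------------------------------------------

    def _dqf(self, block: str, x: np.ndarray, idx: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Change in x'Rx when sites idx move by d (no cross terms within idx)."""
        R, Rd = self.Rmat[block], self.Rdiag[block]
        rx = R @ x
        off = rx[idx] - Rd[idx] * x[idx]
        return Rd[idx] * (2.0 * x[idx] * d + d * d) + 2.0 * d * off

    # ---- updates ------------------------------------------------------------

    def update_alpha(self, arr, rng, log_scale: float) -> bool:
        d = rng.normal() * np.exp(log_scale)
        mutot = arr["mu"].sum()
        with np.errstate(over="ignore", invalid="ignore"):
            dll = d * self.Ytot - mutot * np.expm1(d)
        if np.isfinite(dll) and np.log(rng.uniform()) < dll:
            arr["alpha"] += d
            arr["eta"] += d
            arr["mu"] *= np.exp(d)
            return True
        return False

    def update_beta(self, arr, rng, log_scale: float) -> bool:
        if self.m == 0:
            return False
        delta = rng.normal(size=self.m) * np.exp(log_scale)
        deta = self.data.X @ delta
        with np.errstate(over="ignore"):
            dll = float((self.data.Y * deta).sum() - (arr["mu"] * np.expm1(deta)).sum())
        tb = self.spec.beta_prior_precision
        dev = arr["beta"] - self.spec.beta_prior_mean
        dprior = -0.5 * tb * float(2.0 * dev @ delta + delta @ delta)
        logacc = dll + dprior
        if np.isfinite(logacc) and np.log(rng.uniform()) < logacc:
            arr["beta"] += delta
            arr["eta"] += deta
            arr["mu"] *= np.exp(deta)
            return True
        return False

    def _site_sweep(self, arr, block, rng, log_scales, accept_target=None):
        """One vectorized scan over all colour classes of a latent field."""
        x = arr[block] if block != "psi" else arr["psi"]
        tau = arr["tau"][block]
        mu = arr["mu"]
        acc_total = 0
        acc_masks = []
        for idx in self.colours[block]:
            if idx.size == 0:
                acc_masks.append((idx, np.zeros(0, bool)))
                continue
            d = rng.normal(size=idx.size) * np.exp(log_scales[idx])
            with np.errstate(over="ignore", invalid="ignore"):
                if block in ("u", "v"):
                    mrow = mu[idx, :].sum(axis=1)
                    dll = self.Yrow[idx] * d - mrow * np.expm1(d)
                elif block == "gamma":
                    mcol = mu[:, idx].sum(axis=0)
                    dll = self.Ycol[idx] * d - mcol * np.expm1(d)
                else:
                    muf = mu.ravel()
                    dll = self.Yflat[idx] * d - muf[idx] * np.expm1(d)
                dqf = self._dqf(block, x, idx, d)
                logacc = dll - 0.5 * tau * dqf
            ok = np.isfinite(logacc)
            acc = ok & (np.log(rng.uniform(size=idx.size)) < logacc)
            if acc.any():
                hit = idx[acc]
                dacc = d[acc]
                x[hit] += dacc
                if block in ("u", "v"):
                    arr["eta"][hit, :] += dacc[:, None]
                    mu[hit, :] *= np.exp(dacc)[:, None]
                elif block == "gamma":
                    arr["eta"][:, hit] += dacc[None, :]
                    mu[:, hit] *= np.exp(dacc)[None, :]
                else:
                    i2, t2 = np.divmod(hit, self.Z)
                    arr["eta"][i2, t2] += dacc
                    mu[i2, t2] *= np.exp(dacc)
            acc_total += int(acc.sum())
            acc_masks.append((idx, acc))
        return acc_total, acc_masks

    # ---- collapsed spatial-precision update ---------------------------------

    def _split_marginal(self, s_tilde: np.ndarray, tu: float, tv: float) -> float:
        """log p(u + v | tau_u, tau_v) with the BYM split integrated out.

        In the eigenbasis of R_u the components of s = u + v are independent
        with variance 1/(tau_u * lambda_k) + 1/tau_v on the rowspace and
        1/tau_v on the null directions (u's null components are pinned to
        zero by the constraint convention).
        """
        lam, _ = self._eig_full
        var = np.where(lam > 0, 1.0 / (tu * np.maximum(lam, 1e-300)) + 1.0 / tv,
                       1.0 / tv)
        return float(-0.5 * np.sum(np.log(var) + s_tilde**2 / var))

    def update_tau_uv_collapsed(self, arr, rng, log_scale: float) -> bool:
        """Joint MH update of (log tau_u, log tau_v) given s = u + v only.

        Marginalizing the split removes the ridge that makes the conjugate
        updates mix slowly; the split itself is redrawn exactly afterwards
        by :meth:`interweave`.
        """
        if self._eig_full is None or self.n < 2:
            return False
        tu, tv = arr["tau"]["u"], arr["tau"]["v"]
        _, V = self._eig_full
        s_tilde = V.T @ (arr["u"] + arr["v"])
        d = rng.normal(size=2) * np.exp(log_scale)
        tu_new, tv_new = tu * np.exp(d[0]), tv * np.exp(d[1])
        sh, rt = self.spec.hyper_shape, self.spec.hyper_rate
        # Gamma prior + log-scale Jacobian: a*log(tau) - b*tau (+ const)
        def logp(tau_u, tau_v):
            return (self._split_marginal(s_tilde, tau_u, tau_v)
                    + sh["u"] * np.log(tau_u) - rt["u"] * tau_u
                    + sh["v"] * np.log(tau_v) - rt["v"] * tau_v)
        logacc = logp(tu_new, tv_new) - logp(tu, tv)
        if np.isfinite(logacc) and np.log(rng.uniform()) < logacc:
            arr["tau"]["u"], arr["tau"]["v"] = float(tu_new), float(tv_new)
            return True
        return False

    # ---- aliased-direction Gibbs moves --------------------------------------

    def interweave(self, arr, rng):
        """Exact conditional draws along prior-aliased directions.

        The likelihood identifies u + v (per region), and under type II /
        type III interactions a common temporal / spatial curve trades off
        between the main effect and the interaction.  Site-wise Metropolis
        explores these ridges slowly; drawing the split from its exact
        Gaussian full conditional (likelihood-invariant, prior-Gaussian)
        restores mixing without changing the target.
        """
        spec = self.spec
        if spec.include_spatial and self._Ru_dense is not None and self.n > 1:
            tu, tv = arr["tau"]["u"], arr["tau"]["v"]
            # w: shift u -> u + w, v -> v - w; full conditional N(w*, Q^-1)
            Q = tu * self._Ru_dense + tv * np.eye(self.n)
            rhs = tv * arr["v"] - tu * (self._Ru_dense @ arr["u"])
            L = np.linalg.cholesky(Q)
            w_star = np.linalg.solve(Q, rhs)
            w = w_star + np.linalg.solve(L.T, rng.normal(size=self.n))
            arr["u"] += w
            arr["v"] -= w
        it = spec.interaction_type
        if it == "II" and "gamma" in self._eig:
            tg, tp = arr["tau"]["gamma"], arr["tau"]["psi"]
            psi = arr["psi"].reshape(self.n, self.Z)
            m = psi.mean(axis=0)
            wv, V = self._eig["gamma"]
            raw = (tp * self.n * m - tg * arr["gamma"]) / (tg + self.n * tp)
            d = V @ (V.T @ raw) + V @ (rng.normal(size=wv.size)
                                       / np.sqrt((tg + self.n * tp) * wv))
            arr["gamma"] += d
            psi -= d[None, :]
        elif it == "III" and "u" in self._eig:
            tu, tp = arr["tau"]["u"], arr["tau"]["psi"]
            psi = arr["psi"].reshape(self.n, self.Z)
            ms = psi.mean(axis=1)
            wv, V = self._eig["u"]
            raw = (tp * self.Z * ms - tu * arr["u"]) / (tu + self.Z * tp)
            d = V @ (V.T @ raw) + V @ (rng.normal(size=wv.size)
                                       / np.sqrt((tu + self.Z * tp) * wv))
            arr["u"] += d
            psi -= d[:, None]
        if self._beta_psi is not None:
            # beta_k -> beta_k - d, psi -> psi + d * x_k leaves eta unchanged;
            # d has a Gaussian full conditional from the two priors
            tp = arr["tau"]["psi"]
            tb = self.spec.beta_prior_precision
            mb = self.spec.beta_prior_mean
            for k, (x, Rx, xRx) in enumerate(self._beta_psi):
                prec = tp * xRx + tb
                d_star = (tb * (arr["beta"][k] - mb) - tp * float(Rx @ arr["psi"])) / prec
                d = d_star + rng.normal() / np.sqrt(prec)
                arr["beta"][k] -= d
                arr["psi"] += d * x

    # ---- constraints on raw arrays -----------------------------------------

    def recentre(self, arr):
        """In-place recentring with compensation; eta and mu are untouched."""
        spec, graph = self.spec, self.data.graph
        n, Z = self.n, self.Z
        psi = arr["psi"].reshape(n, Z)
        if spec.interaction_type == "II":
            rm = psi.mean(axis=1)
            psi -= rm[:, None]
            arr["u"] += rm
        elif spec.interaction_type == "III":
            cm = psi.mean(axis=0)
            psi -= cm[None, :]
            arr["gamma"] += cm
        if spec.include_temporal and Z >= 2:
            g = arr["gamma"].mean()
            arr["gamma"] -= g
            arr["alpha"] += g
        if spec.include_spatial:
            overall = arr["u"].mean()
            arr["u"] -= overall
            arr["alpha"] += overall
            if graph.n_components > 1:
                labels = graph.component_labels
                for c in range(graph.n_components):
                    mask = labels == c
                    mc = arr["u"][mask].mean()
                    arr["u"][mask] -= mc
                    arr["v"][mask] += mc


def mh_update_block(state: ParameterState, block: str, scale: float, data: PanelData,
                    spec: ModelSpec, structures: ModelStructures,
                    rng: np.random.Generator):
    """One Metropolis pass over a named block with a fixed proposal scale.

    Site-wise symmetric Gaussian proposals for the latent fields (joint for
    beta, scalar for alpha), acceptance min(1, exp(delta log-posterior));
    constraints are re-applied after updates of u, gamma or psi.  Returns
    ``(new_state, accepted_any)``.
    """
    if block not in LATENT_BLOCKS:
        raise ValueError(f"unknown block {block!r}")
    eng = _Engine(data, spec, structures)
    arr = eng.init_arrays(state)
    ls = np.log(max(scale, 1e-300))
    if block == "alpha":
        accepted = eng.update_alpha(arr, rng, ls)
    elif block == "beta":
        accepted = eng.update_beta(arr, rng, ls)
    else:
        if block == "psi" and spec.interaction_type == "none":
            raise ValueError("psi is inactive when interaction_type is 'none'")
        if block == "gamma" and not spec.include_temporal:
            raise ValueError("gamma is inactive in this model")
        size = {"u": eng.n, "v": eng.n, "gamma": eng.Z, "psi": eng.n * eng.Z}[block]
        if scale == 0.0:
            accepted = True  # null proposal: delta = 0, always accepted
        else:
            n_acc, _ = eng._site_sweep(arr, block, rng, np.full(size, ls))
            accepted = n_acc > 0
        if block in ("u", "gamma", "psi"):
            eng.recentre(arr)
    return eng.to_state(arr), bool(accepted)


def _initial_state(data: PanelData, spec: ModelSpec, rng) -> ParameterState:
    st = ParameterState.zeros(data.n, data.Z, data.m)
    ytot = max(float(data.Y.sum()), 0.5)
    st.alpha = float(np.log(ytot / data.E.sum()) + 0.2 * rng.normal())
    st.beta = 0.05 * rng.normal(size=data.m)
    for b in ("u", "v", "gamma", "psi"):
        setattr(st, "tau_gamma" if b == "gamma" else f"tau_{b}",
                float(np.exp(np.log(10.0) + 0.3 * rng.normal())))
    return st


def run_chain(data: PanelData, spec: ModelSpec, config: MCMCConfig,
              structures: ModelStructures | None = None) -> PosteriorSamples:
    """Run ``config.n_chains`` independent chains and collect retained draws.

    Chains are seeded from independent streams spawned from ``config.seed``;
    the whole run is bit-reproducible for a fixed config.
    """
    if structures is None:
        structures = ModelStructures(data.graph, data.Z, spec)
    if data.Y.sum() == 0:
        warnings.warn("panel has all-zero counts; posterior driven by priors alone")
    eng = _Engine(data, spec, structures)
    n, Z, m = data.n, data.Z, data.m
    C, S = config.n_chains, config.n_retained_per_chain
    out = {
        "alpha": np.empty((C, S)), "beta": np.empty((C, S, m)),
        "u": np.empty((C, S, n)), "v": np.empty((C, S, n)),
        "gamma": np.empty((C, S, Z)), "psi": np.empty((C, S, n, Z)),
        "tau_u": np.empty((C, S)), "tau_v": np.empty((C, S)),
        "tau_gamma": np.empty((C, S)), "tau_psi": np.empty((C, S)),
        "log_post": np.empty((C, S)),
    }
    acc_rates: dict[str, list] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(C)
    active = set(spec.active_blocks)
    from .priors import log_posterior

    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        state0 = _initial_state(data, spec, rng)
        arr = eng.init_arrays(state0)
        ls = {
            "alpha": np.log(0.1), "beta": np.log(0.05),
            "u": np.full(n, np.log(0.2)), "v": np.full(n, np.log(0.2)),
            "gamma": np.full(Z, np.log(0.2)), "psi": np.full(n * Z, np.log(0.2)),
            "tau_uv": np.log(0.5),
        }
        beta_target = (config.target_accept_block if m > 1
                       else config.target_accept_scalar)
        acc_ct = {b: 0 for b in LATENT_BLOCKS}
        prop_ct = {b: 0 for b in LATENT_BLOCKS}
        kept = 0
        for it in range(config.n_iter):
            adapting = it < config.adapt_until
            step = 2.0 / (1.0 + it) ** 0.6 if adapting else 0.0
            a = eng.update_alpha(arr, rng, ls["alpha"])
            if adapting:
                ls["alpha"] += step * (float(a) - config.target_accept_scalar)
            acc_ct["alpha"] += a
            prop_ct["alpha"] += 1
            if m:
                a = eng.update_beta(arr, rng, ls["beta"])
                if adapting:
                    ls["beta"] += step * (float(a) - beta_target)
                acc_ct["beta"] += a
                prop_ct["beta"] += 1
            for b in ("u", "v", "gamma", "psi"):
                if b not in active:
                    continue
                n_acc, masks = eng._site_sweep(arr, b, rng, ls[b])
                if adapting:
                    for idx, accm in masks:
                        if idx.size:
                            ls[b][idx] += step * (accm.astype(float)
                                                  - config.target_accept_scalar)
                acc_ct[b] += n_acc
                prop_ct[b] += len(ls[b])
            if "u" in active and "v" in active:
                a = eng.update_tau_uv_collapsed(arr, rng, ls["tau_uv"])
                if adapting:
                    ls["tau_uv"] += step * (float(a) - config.target_accept_block)
            eng.interweave(arr, rng)
            eng.recentre(arr)
            for b in active:
                fieldv = arr[b] if b != "psi" else arr["psi"]
                arr["tau"][b] = gibbs_update_precision(
                    fieldv, structures[b], spec.hyper_shape[b], spec.hyper_rate[b], rng)
            if (it + 1) % 500 == 0:
                eng.refresh_mu(arr)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0 and kept < S:
                st = eng.to_state(arr)
                out["alpha"][c, kept] = st.alpha
                out["beta"][c, kept] = st.beta
                out["u"][c, kept] = st.u
                out["v"][c, kept] = st.v
                out["gamma"][c, kept] = st.gamma
                out["psi"][c, kept] = st.psi
                for b in ("u", "v", "gamma", "psi"):
                    out[f"tau_{b}"][c, kept] = arr["tau"][b]
                lp = log_posterior(st, spec, data, structures)
                out["log_post"][c, kept] = lp
                if not np.isfinite(lp):
                    raise RuntimeError(
                        f"non-finite log-posterior in retained draw {kept} of chain {c}; "
                        f"state alpha={st.alpha}, taus={arr['tau']}"
                    )
                kept += 1
            if config.log_every and (it + 1) % config.log_every == 0:
                logger.info("chain %d iter %d/%d", c, it + 1, config.n_iter)
        for b in LATENT_BLOCKS:
            if prop_ct[b]:
                acc_rates.setdefault(b, []).append(acc_ct[b] / prop_ct[b])
    return PosteriorSamples(
        **out,
        acceptance={b: float(np.mean(r)) for b, r in acc_rates.items()},
        config=config.to_dict(),
        covariate_names=data.covariate_names,
        region_ids=data.graph.region_ids,
        time_labels=data.time_labels,
    )


def diagnostics(samples: PosteriorSamples) -> "pd.DataFrame":
    """Split-R-hat and effective sample size per scalar parameter.

    With a single chain R-hat is unavailable and reported as NaN; parameters
    with R-hat > 1.05 are flagged.
    """
    import arviz as az
    import pandas as pd

    data = {
        "alpha": samples.alpha, "beta": samples.beta, "u": samples.u,
        "v": samples.v, "gamma": samples.gamma,
        "tau_u": samples.tau_u, "tau_v": samples.tau_v,
        "tau_gamma": samples.tau_gamma, "tau_psi": samples.tau_psi,
    }
    idata = az.from_dict(posterior=data)
    rows = []
    multi = samples.n_chains >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata, method="bulk")
        rhat = az.rhat(idata) if multi else None
    for name in data:
        e = np.atleast_1d(np.asarray(ess[name]))
        r = np.atleast_1d(np.asarray(rhat[name])) if multi else np.full(e.shape, np.nan)
        for k in range(e.size):
            label = name if e.size == 1 else f"{name}[{k}]"
            rows.append({"parameter": label, "rhat": float(r.flat[k]),
                         "ess_bulk": float(e.flat[k])})
    df = pd.DataFrame(rows)
    df["flagged"] = df["rhat"] > 1.05
    return df
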