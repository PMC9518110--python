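"""Model specification, parameter states and the unnormalized log-posterior.

The model, for counts Y_it over n regions and Z periods:

    Y_it ~ Poisson(mu_it),   mu_it = E_it * lambda_it,
    log lambda_it = eta_it = alpha + x_it' beta + u_i + v_i + gamma_t + psi_it,

with a flat prior on alpha, wide Gaussian priors on beta, an intrinsic CAR
(BYM structured) prior on u, iid Gaussian on v, a first-order random walk on
gamma, and a Knorr-Held type I/II/III GMRF prior on the interaction psi.
Each precision tau gets a Gamma(a, b) hyperprior.

The intrinsic blocks are improper; identifiability is restored by
sum-to-zero constraints (u per connected component, gamma overall, psi over
the null directions of its type) enforced by recentring with compensation so
that the linear predictor is left unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .data import PanelData
from .graphs import RegionGraph
from .structures import (
    StructureMatrix,
    icar_structure,
    iid_structure,
    interaction_structure,
    quadratic_form,
    rw1_structure,
)

__all__ = [
    "ModelSpec",
    "ParameterState",
    "ModelStructures",
    "gmrf_logkernel",
    "linear_predictor",
    "poisson_loglik",
    "log_prior",
    "log_posterior",
    "apply_constraints",
]

PRECISION_BLOCKS = ("u", "v", "gamma", "psi")
_CONSTRAINT_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Which effects are active and their prior hyper-parameters.

    interaction_type: "none", "I", "II" or "III".
    beta prior: iid Gaussian with mean ``beta_prior_mean`` and precision
    ``beta_prior_precision`` (wide by default).
    Each active precision tau_b ~ Gamma(shape a_b, rate b_b); defaults
    (1, 5e-4) are diffuse.
    ``threshold`` is the relative-risk exceedance threshold T.
    """

    interaction_type: str = "none"
    include_spatial: bool = True
    include_temporal: bool = True
    beta_prior_mean: float = 0.0
    beta_prior_precision: float = 1e-3
    hyper_shape: dict = field(default_factory=dict)
    hyper_rate: dict = field(default_factory=dict)
    threshold: float = 1.0

    def __post_init__(self):
        if self.interaction_type not in ("none", "I", "II", "III"):
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if self.interaction_type != "none" and not (
            self.include_spatial and self.include_temporal
        ):
            raise ValueError("interaction terms require spatial and temporal effects")
        if self.beta_prior_precision <= 0:
            raise ValueError("beta prior precision must be positive")
        if self.threshold <= 0:
            raise ValueError("exceedance threshold must be positive")
        shape = {b: 1.0 for b in PRECISION_BLOCKS} | dict(self.hyper_shape)
        rate = {b: 5e-4 for b in PRECISION_BLOCKS} | dict(self.hyper_rate)
        for b in PRECISION_BLOCKS:
            if shape[b] <= 0 or rate[b] <= 0:
                raise ValueError(f"Gamma hyperprior for tau_{b} must have positive shape/rate")
        object.__setattr__(self, "hyper_shape", shape)
        object.__setattr__(self, "hyper_rate", rate)

    @property
    def active_blocks(self) -> tuple:
        blocks = []
        if self.include_spatial:
            blocks += ["u", "v"]
        if self.include_temporal:
            blocks.append("gamma")
        if self.interaction_type != "none":
            blocks.append("psi")
        return tuple(blocks)

    def to_dict(self) -> dict:
        return {
            "interaction": self.interaction_type,
            "include_spatial": self.include_spatial,
            "include_temporal": self.include_temporal,
            "beta_prior": {"mean": self.beta_prior_mean, "precision": self.beta_prior_precision},
            "hyperpriors": {b: {"shape": self.hyper_shape[b], "rate": self.hyper_rate[b]}
                            for b in PRECISION_BLOCKS},
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        hyp = d.get("hyperpriors", {})
        return cls(
            interaction_type=d.get("interaction", "none"),
            include_spatial=d.get("include_spatial", True),
            include_temporal=d.get("include_temporal", True),
            beta_prior_mean=d.get("beta_prior", {}).get("mean", 0.0),
            beta_prior_precision=d.get("beta_prior", {}).get("precision", 1e-3),
            hyper_shape={b: hyp[b]["shape"] for b in hyp},
            hyper_rate={b: hyp[b]["rate"] for b in hyp},
            threshold=d.get("threshold", 1.0),
        )


@dataclass
class ParameterState:
    """One point in parameter space: all effects plus the four precisions."""

    alpha: float
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray  # (n, Z)
    tau_u: float = 1.0
    tau_v: float = 1.0
    tau_gamma: float = 1.0
    tau_psi: float = 1.0

    @classmethod
    def zeros(cls, n: int, Z: int, m: int) -> "ParameterState":
        return cls(0.0, np.zeros(m), np.zeros(n), np.zeros(n), np.zeros(Z), np.zeros((n, Z)))

    def copy(self) -> "ParameterState":
        return ParameterState(
            float(self.alpha), self.beta.copy(), self.u.copy(), self.v.copy(),
            self.gamma.copy(), self.psi.copy(),
            float(self.tau_u), float(self.tau_v), float(self.tau_gamma), float(self.tau_psi),
        )

    def tau(self, block: str) -> float:
        return float(getattr(self, "tau_gamma" if block == "gamma" else f"tau_{block}"))

    def check_dims(self, data: PanelData):
        n, Z, m = data.n, data.Z, data.m
        for name, arr, shape in (
            ("beta", self.beta, (m,)), ("u", self.u, (n,)), ("v", self.v, (n,)),
            ("gamma", self.gamma, (Z,)), ("psi", self.psi, (n, Z)),
        ):
            if np.shape(arr) != shape:
                raise ValueError(f"block '{name}' has shape {np.shape(arr)}, expected {shape}")


class ModelStructures:
    """Structure matrices for every active block of one (graph, Z, spec)."""

    def __init__(self, graph: RegionGraph, Z: int, spec: ModelSpec):
        self.graph = graph
        self.Z = Z
        self.spec = spec
        self.R: dict[str, StructureMatrix] = {
            "u": icar_structure(graph),
            "v": iid_structure(graph.n),
        }
        if spec.include_temporal:
            if Z < 2:
                raise ValueError("temporal effects require at least 2 periods")
            self.R["gamma"] = rw1_structure(Z)
        if spec.interaction_type != "none":
            self.R["psi"] = interaction_structure(spec.interaction_type, graph, Z)

    def __getitem__(self, block: str) -> StructureMatrix:
        return self.R[block]


def gmrf_logkernel(x: np.ndarray, R: StructureMatrix, tau: float) -> float:
    """Log-kernel of the (possibly intrinsic) GMRF N(0, (tau R)^-).

    (rank/2) log tau - (tau/2) x' R x.  The omitted normalizing constant
    does not depend on x and depends on tau only through the rank term, so
    this is sufficient both for Metropolis ratios and for the conjugate
    Gamma update of tau.
    """
    if tau <= 0:
        raise ValueError("precision must be positive")
    return 0.5 * R.rank * np.log(tau) - 0.5 * tau * quadratic_form(R, x)


def linear_predictor(data: PanelData, state: ParameterState):
    """Assemble eta_it and log mu_it = log E_it + eta_it.

    Returns an object with ``eta``, ``log_mu`` and ``mu`` (n, Z) arrays.
    """
    state.check_dims(data)
    eta = (
        state.alpha
        + (data.X @ state.beta if data.m else 0.0)
        + state.u[:, None]
        + state.v[:, None]
        + state.gamma[None, :]
        + state.psi
    )
    return LinearPredictorField(eta=np.asarray(eta, dtype=float), log_E=np.log(data.E))


@dataclass(frozen=True)
class LinearPredictorField:
    eta: np.ndarray
    log_E: np.ndarray = field(repr=False)

    @property
    def log_mu(self) -> np.ndarray:
        return self.log_E + self.eta

    @property
    def mu(self) -> np.ndarray:
        return np.exp(self.log_mu)


def poisson_loglik(data: PanelData, fieldv: LinearPredictorField) -> float:
    """Full Poisson log-likelihood sum_it [Y log mu - mu - log Y!]."""
    log_mu = fieldv.log_mu
    mu = np.exp(log_mu)
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite Poisson mean in linear predictor")
    return float(np.sum(data.Y * log_mu - mu - gammaln(data.Y + 1.0)))


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def _check_constraints(state: ParameterState, spec: ModelSpec, graph: RegionGraph):
    labels = graph.component_labels
    if spec.include_spatial:
        for c in range(graph.n_components):
            if abs(state.u[labels == c].sum()) > _CONSTRAINT_TOL * max(1, (labels == c).sum()):
                raise ValueError("u violates the per-component sum-to-zero constraint")
    if spec.include_temporal and abs(state.gamma.sum()) > _CONSTRAINT_TOL * len(state.gamma):
        raise ValueError("gamma violates the sum-to-zero constraint")
    if spec.interaction_type == "II":
        if np.max(np.abs(state.psi.sum(axis=1))) > _CONSTRAINT_TOL * state.psi.shape[1]:
            raise ValueError("type II psi violates per-region time sum-to-zero")
    elif spec.interaction_type == "III":
        if np.max(np.abs(state.psi.sum(axis=0))) > _CONSTRAINT_TOL * state.psi.shape[0]:
            raise ValueError("type III psi violates per-time region sum-to-zero")


def log_prior(state: ParameterState, spec: ModelSpec, structures: ModelStructures) -> float:
    """Unnormalized log prior density at a constrained state.

    alpha is flat (contributes 0); beta iid Gaussian; u/v/gamma/psi through
    their GMRF log-kernels; each active tau through its Gamma hyperprior.
    Raises if the state violates the model's identifiability constraints.
    """
    _check_constraints(state, spec, structures.graph)
    lp = 0.0
    m = len(state.beta)
    if m:
        tb = spec.beta_prior_precision
        dev = state.beta - spec.beta_prior_mean
        lp += 0.5 * m * np.log(tb) - 0.5 * tb * float(dev @ dev)
    fields = {"u": state.u, "v": state.v, "gamma": state.gamma, "psi": state.psi.ravel()}
    for block in spec.active_blocks:
        tau = state.tau(block)
        if tau <= 0:
            raise ValueError(f"tau_{block} must be positive")
        lp += gmrf_logkernel(fields[block], structures[block], tau)
        lp += _gamma_logpdf(tau, spec.hyper_shape[block], spec.hyper_rate[block])
    return float(lp)


def log_posterior(state: ParameterState, spec: ModelSpec, data: PanelData,
                  structures: ModelStructures) -> float:
    """Poisson log-likelihood plus log prior (unnormalized posterior)."""
    return poisson_loglik(data, linear_predictor(data, state)) + log_prior(state, spec, structures)


def apply_constraints(state: ParameterState, spec: ModelSpec, graph: RegionGraph) -> ParameterState:
    """Recentre the intrinsic blocks, compensating so eta is unchanged.

    Order of operations: the interaction's null-direction means move into u
    (type II, per-region time means) or gamma (type III, per-time region
    means); then gamma's mean moves into alpha; then u is centred — its
    global mean moves into alpha and, on disconnected graphs, the residual
    per-component offsets move into v so the predictor stays exactly
    invariant.
    """
    s = state.copy()
    if spec.interaction_type == "II":
        row_means = s.psi.mean(axis=1)
        s.psi -= row_means[:, None]
        s.u += row_means
    elif spec.interaction_type == "III":
        col_means = s.psi.mean(axis=0)
        s.psi -= col_means[None, :]
        s.gamma += col_means
    if spec.include_temporal and len(s.gamma):
        g = s.gamma.mean()
        s.gamma -= g
        s.alpha += g
    if spec.include_spatial:
        overall = s.u.mean()
        s.u -= overall
        s.alpha += overall
        labels = graph.component_labels
        if graph.n_components > 1:
            for c in range(graph.n_components):
                mask = labels == c
                mc = s.u[mask].mean()
                s.u[mask] -= mc
                s.v[mask] += mc
        else:
            s.u -= s.u.mean()  # kill rounding drift
    return s
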