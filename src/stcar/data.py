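"""Areal count panels: observed events, populations at risk, expected counts.

The observed data are event counts Y_it and at-risk totals N_it over n
regions and Z periods, plus region-time covariates.  Expected counts E_it
are formed by internal standardization: the overall event rate of the panel
itself is applied to every cell's at-risk total, so that sum(E) = sum(Y)
exactly and the relative risk lambda_it = mu_it / E_it is centred at 1
under spatial and temporal homogeneity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .graphs import RegionGraph

__all__ = ["PanelData", "compute_expected_counts", "observed_rates", "read_panel_csv"]


def compute_expected_counts(N: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Expected counts by internal standardization: E = N * (sum Y / sum N)."""
    N = np.asarray(N, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if N.shape != Y.shape:
        raise ValueError("N and Y must have matching shapes")
    if np.any(N <= 0):
        raise ValueError("all at-risk totals N must be positive")
    total_y = Y.sum()
    if total_y <= 0:
        raise ValueError("degenerate panel: total event count is zero")
    return N * (total_y / N.sum())


@dataclass(frozen=True)
class PanelData:
    """Complete n x Z areal count panel.

    Y, N, E are (n, Z) arrays aligned with ``graph.region_ids`` (rows) and
    time order (columns); X is (n, Z, m) for m named covariates.
    """

    graph: RegionGraph
    Y: np.ndarray = field(repr=False)
    N: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    covariate_names: tuple = ()
    time_labels: tuple = ()

    def __post_init__(self):
        n = self.graph.n
        Y = np.asarray(self.Y)
        N = np.asarray(self.N, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != n:
            raise ValueError(f"Y must be (n={n}, Z); got {Y.shape}")
        Z = Y.shape[1]
        if N.shape != (n, Z) or E.shape != (n, Z):
            raise ValueError("Y, N, E must share the (n, Z) shape")
        if np.any(~np.isfinite(Y)) or np.any(Y < 0) or np.any(Y != np.floor(Y)):
            raise ValueError("Y must contain non-negative integers")
        if np.any(N <= 0):
            raise ValueError("all N_it must be positive")
        if np.any(E <= 0):
            raise ValueError("all E_it must be positive")
        names = tuple(str(c) for c in self.covariate_names)
        X = np.asarray(self.X, dtype=float)
        if X.size == 0:
            X = np.zeros((n, Z, 0))
        if X.shape != (n, Z, len(names)):
            raise ValueError(f"X must be (n, Z, m={len(names)}); got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
        tl = tuple(self.time_labels) if self.time_labels else tuple(range(Z))
        if len(tl) != Z:
            raise ValueError("time_labels length must equal Z")
        object.__setattr__(self, "Y", Y.astype(np.int64))
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "covariate_names", names)
        object.__setattr__(self, "time_labels", tl)

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def Z(self) -> int:
        return self.Y.shape[1]

    @property
    def m(self) -> int:
        return len(self.covariate_names)

    def data_hash(self) -> str:
        """Content hash of (Y, N, E, X); used to refuse cross-dataset model comparison."""
        h = hashlib.sha256()
        for arr in (self.Y, self.N, self.E, self.X):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(self.graph.region_ids).encode())
        return h.hexdigest()

    def to_long_dataframe(self) -> pd.DataFrame:
        n, Z = self.n, self.Z
        rec = {
            "region": np.repeat(self.graph.region_ids, Z),
            "time": np.tile(self.time_labels, n),
            "Y": self.Y.ravel(),
            "N": self.N.ravel(),
            "E": self.E.ravel(),
        }
        for k, name in enumerate(self.covariate_names):
            rec[name] = self.X[:, :, k].ravel()
        return pd.DataFrame(rec)

    @classmethod
    def from_long_dataframe(
        cls,
        df: pd.DataFrame,
        graph: RegionGraph,
        covariates=None,
        expected_col: str | None = None,
    ) -> "PanelData":
        """Assemble a panel from long-format records (region, time, Y, N, ...).

        Time codes (years or consecutive integers) are mapped to 0..Z-1
        preserving sorted order.  Every (region, time) cell must be present
        exactly once.  E comes from ``expected_col`` if given, else internal
        standardization.
        """
        required = {"region", "time", "Y", "N"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel is missing required columns: {sorted(missing)}")
        if covariates is None:
            reserved = required | {"E"}
            covariates = [c for c in df.columns if c not in reserved]
        regions = df["region"].astype(str)
        unknown = set(regions) - set(graph.region_ids)
        if unknown:
            raise ValueError(f"panel regions absent from adjacency: {sorted(unknown)}")
        times = sorted(df["time"].unique())
        t_index = {t: k for k, t in enumerate(times)}
        n, Z = graph.n, len(times)
        if len(df) != n * Z or df.duplicated(subset=["region", "time"]).any():
            raise ValueError("panel must cover every (region, time) cell exactly once")
        if set(regions) != set(graph.region_ids):
            absent = set(graph.region_ids) - set(regions)
            raise ValueError(f"panel has no rows for regions: {sorted(absent)}")
        ii = regions.map(graph.index_of).to_numpy()
        tt = df["time"].map(t_index).to_numpy()
        Y = np.zeros((n, Z))
        N = np.zeros((n, Z))
        X = np.zeros((n, Z, len(covariates)))
        Y[ii, tt] = df["Y"].to_numpy()
        N[ii, tt] = df["N"].to_numpy()
        for k, c in enumerate(covariates):
            X[ii, tt, k] = df[c].to_numpy()
        if expected_col is not None:
            E = np.zeros((n, Z))
            E[ii, tt] = df[expected_col].to_numpy()
        else:
            E = compute_expected_counts(N, Y)
        return cls(graph, Y, N, E, X, tuple(covariates), tuple(times))


def read_panel_csv(path, graph: RegionGraph, covariates=None) -> PanelData:
    """Read a long-format panel CSV (columns region, time, Y, N, covariates...)."""
    return PanelData.from_long_dataframe(pd.read_csv(path), graph, covariates)


def observed_rates(data: PanelData, by: str = "overall") -> pd.DataFrame:
    """Crude event rates sum(Y)/sum(N) with exact (Clopper-Pearson) 95% CIs.

    ``by`` is one of ``overall``, ``region``, ``region_time``.  Cells with no
    population are reported as NaN, never as zero.
    """
    if by == "overall":
        groups = [("overall", data.Y.sum(), data.N.sum())]
        index = ["overall"]
        cols = {}
    elif by == "region":
        groups = [
            (r, data.Y[i].sum(), data.N[i].sum())
            for i, r in enumerate(data.graph.region_ids)
        ]
        cols = {"region": [g[0] for g in groups]}
    elif by == "region_time":
        groups = []
        for i, r in enumerate(data.graph.region_ids):
            for t, lab in enumerate(data.time_labels):
                groups.append(((r, lab), data.Y[i, t], data.N[i, t]))
        cols = {
            "region": [g[0][0] for g in groups],
            "time": [g[0][1] for g in groups],
        }
    else:
        raise ValueError(f"unknown aggregation {by!r}")
    ys = np.array([g[1] for g in groups], dtype=float)
    ns = np.array([g[2] for g in groups], dtype=float)
    rate = np.where(ns > 0, ys / np.where(ns > 0, ns, 1.0), np.nan)
    lo = np.full_like(rate, np.nan)
    hi = np.full_like(rate, np.nan)
    ok = ns > 0
    if ok.any():
        lo[ok], hi[ok] = proportion_confint(ys[ok], ns[ok], alpha=0.05, method="beta")
    out = pd.DataFrame({**cols, "events": ys, "at_risk": ns, "rate": rate,
                        "ci_lower": lo, "ci_upper": hi})
    return out
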