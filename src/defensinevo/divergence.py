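"""Type-I functional-divergence distances and per-cluster branch lengths.

After gene duplication, the site-specific evolutionary rate of a duplicate
cluster may shift (type-I functional divergence). The pairwise coefficient
θ_ij in [0, 1) quantifies the probability of such a rate shift between
clusters i and j; it is estimated upstream (e.g. by the bootstrapped Gu99
probabilistic model) and consumed here as a plain table.

The distance transform d_F = -ln(1 - θ_ij) makes the coefficients additive
on a star topology: d_F(A,B) = b_F(A) + b_F(B), where the functional branch
length b_F of a cluster measures how much of the rate shifting is
attributable to that cluster. With k >= 3 clusters the b_F vector is the
least-squares solution of the pairwise additivity system (exact for k = 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

ArrayLike = Union[float, Sequence[float], np.ndarray]


def functional_distance(theta: ArrayLike) -> Union[float, np.ndarray]:
    """d_F = -ln(1 - θ); strictly increasing on [0, 1).

    θ >= 1 would give an infinite distance and raises; θ < 0 is invalid.
    """
    arr = np.asarray(theta, dtype=float)
    if np.any(arr < 0):
        raise ValueError("θ must be non-negative")
    if np.any(arr >= 1):
        raise ValueError("θ >= 1: functional distance is infinite")
    out = -np.log1p(-arr)
    return float(out) if np.isscalar(theta) or arr.ndim == 0 else out


def theta_from_distance(dF: ArrayLike) -> Union[float, np.ndarray]:
    """Inverse transform θ = 1 - exp(-d_F)."""
    arr = np.asarray(dF, dtype=float)
    out = -np.expm1(-arr)
    return float(out) if np.isscalar(dF) or arr.ndim == 0 else out


@dataclass
class ThetaTable:
    """Pairwise type-I divergence coefficients between ordered clusters."""

    clusters: list[str]
    theta: np.ndarray  # symmetric, diagonal ignored
    se: Optional[np.ndarray] = None
    lrt: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        k = len(self.clusters)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (k, k):
            raise ValueError("theta matrix shape does not match cluster count")
        off = ~np.eye(k, dtype=bool)
        vals = self.theta[off]
        if np.any(vals < 0) or np.any(vals >= 1):
            raise ValueError("off-diagonal θ entries must lie in [0, 1)")
        if not np.allclose(self.theta, self.theta.T, equal_nan=True):
            raise ValueError("theta matrix must be symmetric")

    @classmethod
    def from_pairs(
        cls,
        pairs: pd.DataFrame,
    ) -> "ThetaTable":
        """Build from a long table with columns cluster_i, cluster_j, theta,
        se[, lrt] (one row per unordered pair)."""
        required = {"cluster_i", "cluster_j", "theta"}
        missing = required - set(pairs.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        clusters: list[str] = []
        for col in ("cluster_i", "cluster_j"):
            for name in pairs[col]:
                if name not in clusters:
                    clusters.append(str(name))
        k = len(clusters)
        idx = {c: i for i, c in enumerate(clusters)}
        theta = np.zeros((k, k))
        se = np.full((k, k), np.nan)
        lrt = np.full((k, k), np.nan)
        for _, row in pairs.iterrows():
            i, j = idx[str(row["cluster_i"])], idx[str(row["cluster_j"])]
            theta[i, j] = theta[j, i] = float(row["theta"])
            if "se" in pairs.columns:
                se[i, j] = se[j, i] = float(row["se"])
            if "lrt" in pairs.columns:
                lrt[i, j] = lrt[j, i] = float(row["lrt"])
        return cls(clusters, theta, se if "se" in pairs.columns else None,
                   lrt if "lrt" in pairs.columns else None)

    def distances(self) -> np.ndarray:
        """Symmetric d_F matrix with a zero diagonal."""
        k = len(self.clusters)
        dF = np.zeros((k, k))
        off = ~np.eye(k, dtype=bool)
        dF[off] = functional_distance(self.theta[off])
        return dF


@dataclass
class DivergenceResult:
    """d_F matrix, solved b_F branch lengths and additivity residuals."""

    clusters: list[str]
    dF: np.ndarray
    bF: np.ndarray
    residuals: np.ndarray  # dF_ij - (bF_i + bF_j), diagonal zeroed
    max_abs_residual: float

    def as_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(pairwise d_F long table, per-cluster b_F table) for reporting."""
        rows = []
        k = len(self.clusters)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "cluster_i": self.clusters[i],
                        "cluster_j": self.clusters[j],
                        "dF": self.dF[i, j],
                        "residual": self.residuals[i, j],
                    }
                )
        pair_df = pd.DataFrame(rows)
        bf_df = pd.DataFrame(
            {"cluster": self.clusters, "bF": self.bF,
             "negative_flag": self.bF < 0}
        )
        return pair_df, bf_df


def star_branch_lengths(
    dF: np.ndarray, clusters: Optional[Sequence[str]] = None
) -> DivergenceResult:
    """Least-squares functional branch lengths on a star topology.

    Minimizes Σ_{i<j} (dF_ij - bF_i - bF_j)² over the k branch lengths; for
    k = 3 this is the exact additive solution
    bF_i = (dF_ij + dF_ik - dF_jk) / 2. Negative solutions are permitted but
    emitted with a warning.
    """
    dF = np.asarray(dF, dtype=float)
    k = dF.shape[0]
    if dF.shape != (k, k):
        raise ValueError("dF must be square")
    if k < 3:
        raise ValueError("branch lengths are underdetermined for fewer than 3 clusters")
    iu, ju = np.triu_indices(k, 1)
    if not np.all(np.isfinite(dF[iu, ju])):
        raise ValueError("all off-diagonal d_F entries must be finite")
    names = list(clusters) if clusters is not None else [f"C{i+1}" for i in range(k)]

    A = np.zeros((len(iu), k))
    A[np.arange(len(iu)), iu] = 1.0
    A[np.arange(len(ju)), ju] = 1.0
    b = dF[iu, ju]
    bF, *_ = np.linalg.lstsq(A, b, rcond=None)

    fitted = bF[:, None] + bF[None, :]
    residuals = dF - fitted
    np.fill_diagonal(residuals, 0.0)
    max_abs = float(np.max(np.abs(residuals[iu, ju]))) if len(iu) else 0.0
    if np.any(bF < 0):
        neg = [names[i] for i in np.flatnonzero(bF < 0)]
        warnings.warn(
            f"negative functional branch length(s) for {neg}; reported unconstrained",
            stacklevel=2,
        )
    return DivergenceResult(names, dF, bF, residuals, max_abs)


def distances_from_branch_lengths(bF: Sequence[float]) -> np.ndarray:
    """Additive pairwise d_F matrix dF_ij = bF_i + bF_j (zero diagonal)."""
    b = np.asarray(bF, dtype=float)
    dF = b[:, None] + b[None, :]
    np.fill_diagonal(dF, 0.0)
    return dF


def distance_range(dF: np.ndarray) -> tuple[float, float]:
    """(min, max) over the strict upper triangle of a d_F matrix."""
    dF = np.asarray(dF, dtype=float)
    k = dF.shape[0]
    if k < 2:
        raise ValueError("need at least one pair")
    iu, ju = np.triu_indices(k, 1)
    vals = dF[iu, ju]
    return float(np.min(vals)), float(np.max(vals))


def divergence_analysis(table: ThetaTable) -> DivergenceResult:
    """θ table -> d_F matrix -> least-squares b_F, in one call."""
    return star_branch_lengths(table.distances(), table.clusters)
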