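"""Co-structure between paired community tables.

Co-inertia analysis (COIA) finds axes maximizing the squared cross-covariance
between two sample-matched tables; the global association is summarized by
the RV coefficient

    RV = trace(X Xt Y Yt) / sqrt(trace((X Xt)^2) * trace((Y Yt)^2))

with X, Y column-centered, and tested by Monte-Carlo row permutation of one
table.  Abundance tables are Hellinger-transformed (square root of relative
abundances) before entering the ordination by default.  A Mantel
distance-decay test against geographic distance is included for dispersal
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix, mantel

__all__ = ["CoinertiaResult", "hellinger", "rv_coefficient", "coinertia", "mantel_distance_decay"]


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Square root of row-wise relative abundances."""
    sums = table.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("all-zero sample row")
    return np.sqrt(table.div(sums, axis=0))


def _prepare(table: pd.DataFrame, transform: str | None) -> np.ndarray:
    if transform == "hellinger":
        table = hellinger(table)
    elif transform == "log1p":
        table = np.log1p(table)
    elif transform is not None:
        raise ValueError(f"unknown transform: {transform}")
    x = table.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValueError("constant table: no variance to relate")
    return xc


def rv_coefficient(xc: np.ndarray, yc: np.ndarray) -> float:
    """RV between two column-centered configurations (trace formula)."""
    sxy = xc.T @ yc
    sxx = xc.T @ xc
    syy = yc.T @ yc
    num = np.sum(sxy * sxy)
    den = np.sqrt(np.sum(sxx * sxx) * np.sum(syy * syy))
    return float(num / den)


@dataclass
class CoinertiaResult:
    rv: float
    eigenvalues: np.ndarray
    x_scores: pd.DataFrame
    y_scores: pd.DataFrame
    axis_correlations: np.ndarray
    perm_p: float
    n_perm: int


def coinertia(
    x: pd.DataFrame,
    y: pd.DataFrame,
    n_perm: int = 999,
    seed=None,
    transform: str | None = "hellinger",
    n_axes: int = 2,
) -> CoinertiaResult:
    """Co-inertia analysis of two sample-matched tables.

    Rows must be the same samples in the same order; features may differ.
    Eigenvalues are the squared singular values of the cross-covariance
    matrix (the co-inertia of each axis); sample scores are the projections
    of each centered table on its co-inertia axes, and
    ``axis_correlations`` the per-axis Pearson correlation between the two
    score sets.  ``perm_p = (#(RV_perm >= RV_obs) + 1) / (n_perm + 1)`` from
    random row permutations of ``y``.
    """
    if list(x.index) != list(y.index):
        raise ValueError("tables must share identical sample order")
    if len(x) < 3:
        raise ValueError("need at least three samples")
    xc = _prepare(x, transform)
    yc = _prepare(y, transform)
    n = len(x)

    cross = xc.T @ yc / n
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    k = min(n_axes, len(s))
    eig = s**2
    x_scores = xc @ u[:, :k]
    y_scores = yc @ vt.T[:, :k]
    with np.errstate(invalid="ignore"):
        axis_corr = np.array(
            [np.corrcoef(x_scores[:, a], y_scores[:, a])[0, 1] for a in range(k)]
        )

    rv_obs = rv_coefficient(xc, yc)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if rv_coefficient(xc, yc[perm]) >= rv_obs - 1e-12:
            hits += 1
    perm_p = (hits + 1) / (n_perm + 1)

    return CoinertiaResult(
        rv=rv_obs,
        eigenvalues=eig,
        x_scores=pd.DataFrame(x_scores, index=x.index, columns=[f"axis{a+1}" for a in range(k)]),
        y_scores=pd.DataFrame(y_scores, index=y.index, columns=[f"axis{a+1}" for a in range(k)]),
        axis_correlations=axis_corr,
        perm_p=perm_p,
        n_perm=n_perm,
    )


def mantel_distance_decay(
    community_d: pd.DataFrame,
    geo_d: pd.DataFrame,
    permutations: int = 999,
    seed=None,
) -> tuple[float, float]:
    """Mantel r and permutation p between community and geographic distances."""
    if set(community_d.index) != set(geo_d.index):
        raise ValueError("sample sets differ")
    ids = list(community_d.index)
    rng = np.random.default_rng(seed)
    cd = DistanceMatrix(community_d.loc[ids, ids].to_numpy(dtype=float), ids)
    gd = DistanceMatrix(geo_d.loc[ids, ids].to_numpy(dtype=float), ids)
    r, p, _ = mantel(cd, gd, method="pearson", permutations=permutations, seed=rng)
    return float(r), float(p)
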