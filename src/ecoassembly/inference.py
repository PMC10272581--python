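"""Phylogenetic-signal testing and five-way assembly-process attribution.

The Mantel correlogram here relates between-OTU Bray-Curtis distances (how
differently two OTUs are distributed across samples) to between-OTU
phylogenetic distances, class by class.  A significant positive statistic at
short phylogenetic distances means close relatives are distributed more
similarly than distant ones — the phylogenetic signal that licenses reading
nearest-taxon turnover (betaNTI) as evidence of selection.

Process attribution follows the standard two-stage decision rule on each
community pair: selection first (betaNTI beyond +/-2, variable vs
homogeneous), then dispersal (RC_bray beyond +/-0.95, limitation vs
homogenization), else undominated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import bray_curtis_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PROCESS_CLASSES",
    "CorrelogramResult",
    "NoPhylogeneticSignalError",
    "otu_profile_distances",
    "mantel_correlogram",
    "require_phylogenetic_signal",
    "classify_pair",
    "process_fractions",
    "nti_summary",
]

PROCESS_CLASSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


class NoPhylogeneticSignalError(RuntimeError):
    """Raised when the signal gate finds no significant short-distance class."""


def otu_profile_distances(table: pd.DataFrame) -> pd.DataFrame:
    """Between-OTU Bray-Curtis distances over abundance profiles.

    Each OTU's profile is its abundance vector across the samples of
    ``table`` (samples x OTUs); the result is OTU x OTU.
    """
    zero = table.columns[table.sum(axis=0) == 0]
    if len(zero):
        raise ValueError(f"all-zero OTU column(s): {list(zero)[:5]}")
    return bray_curtis_matrix(table.T)


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel statistics.

    ``table`` columns: class_min, class_max, n_pairs, r, p, p_adj,
    significant.  ``r`` uses the distance-matrix sign convention (statistic
    negated), so a positive value at a class means pairs in that
    phylogenetic-distance class are ecologically *more similar* than
    average — positive autocorrelation at that scale.  ``p`` is the raw
    two-sided permutation p-value; ``p_adj`` applies progressive Holm
    correction along increasing distance (the first class is uncorrected).
    """

    table: pd.DataFrame
    permutations: int
    alpha: float = 0.05

    def short_range_signal(self) -> bool:
        """True if any class in the shorter half is significantly positive."""
        half = self.table.iloc[: max(1, len(self.table) // 2)]
        ok = (half["r"] > 0) & half["significant"]
        return bool(ok.any())


def _condensed(square: pd.DataFrame) -> np.ndarray:
    a = square.to_numpy(dtype=float)
    iu = np.triu_indices(len(a), k=1)
    return a[iu]


def _progressive_holm(p: np.ndarray) -> np.ndarray:
    """Progressive Holm correction along the class sequence."""
    out = np.full_like(p, np.nan, dtype=float)
    for i in range(len(p)):
        window = p[: i + 1]
        mask = ~np.isnan(window)
        if np.isnan(p[i]):
            continue
        k = int(mask.sum())
        order = np.argsort(window[mask])
        ranked = window[mask][order]
        adj = np.minimum(1.0, np.maximum.accumulate(ranked * (k - np.arange(k))))
        pos = int(np.searchsorted(np.flatnonzero(mask), i))
        out[i] = adj[np.argsort(order)][pos]
    return out


def mantel_correlogram(
    eco_d: pd.DataFrame,
    phy_d: pd.DataFrame,
    n_classes: int = 10,
    permutations: int = 999,
    seed=None,
    alpha: float = 0.05,
) -> CorrelogramResult:
    """Mantel correlogram of ecological vs phylogenetic between-OTU distances.

    Distance classes are equal-frequency (quantile) bins of the pairwise
    phylogenetic distances.  For each class the Mantel statistic is the
    (negated) Pearson correlation between the ecological distances and the
    class-membership indicator; p-values come from simultaneous row/column
    permutations of the ecological matrix.  Classes with fewer than three
    pairs are flagged and not tested.
    """
    if n_classes < 2:
        raise ValueError("need at least two distance classes")
    order = eco_d.index
    if set(order) != set(phy_d.index):
        raise ValueError("OTU sets of the two matrices differ")
    phy_d = phy_d.loc[order, order]
    n = len(order)
    E = eco_d.to_numpy(dtype=float)
    iu = np.triu_indices(n, k=1)
    x = E[iu]
    ph = _condensed(phy_d)
    N = len(x)

    qs = np.quantile(ph, np.linspace(0, 1, n_classes + 1))
    edges = np.unique(qs)
    if len(edges) - 1 < n_classes:
        logger.warning("tied distances reduce %d classes to %d", n_classes, len(edges) - 1)
    k = len(edges) - 1
    cls = np.clip(np.searchsorted(edges, ph, side="right") - 1, 0, k - 1)
    M = np.zeros((k, N))
    M[cls, np.arange(N)] = 1.0
    n_pairs = M.sum(axis=1)
    m = n_pairs / N
    sd_I = np.sqrt(m * (1 - m))

    def class_r(vec: np.ndarray) -> np.ndarray:
        mu, sd = vec.mean(), vec.std()
        cov = M @ vec / N - mu * m
        with np.errstate(invalid="ignore", divide="ignore"):
            return -cov / (sd * sd_I)

    r_obs = class_r(x)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k)
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp = E[np.ix_(perm, perm)][iu]
        exceed += np.abs(class_r(xp)) >= np.abs(r_obs) - 1e-12
    p = (exceed + 1) / (permutations + 1)

    testable = n_pairs >= 3
    r_obs = np.where(testable, r_obs, np.nan)
    p = np.where(testable, p, np.nan)
    p_adj = _progressive_holm(p)
    table = pd.DataFrame(
        {
            "class_min": edges[:-1],
            "class_max": edges[1:],
            "n_pairs": n_pairs.astype(int),
            "r": r_obs,
            "p": p,
            "p_adj": p_adj,
            "significant": (p_adj <= alpha) & testable,
        }
    )
    return CorrelogramResult(table, permutations, alpha)


def require_phylogenetic_signal(
    table: pd.DataFrame,
    phy_d: pd.DataFrame,
    n_classes: int = 10,
    permutations: int = 999,
    seed=None,
) -> CorrelogramResult:
    """Gate for betaNTI-based inference: demand short-range phylogenetic signal.

    Runs the correlogram on between-OTU profile distances and raises
    :class:`NoPhylogeneticSignalError` if no significantly positive class
    exists in the shorter half of the phylogenetic-distance range.  Note the
    profile-based test is conservative: a negative outcome does not prove
    absence of signal, so callers may override it deliberately.
    """
    eco_d = otu_profile_distances(table)
    res = mantel_correlogram(eco_d, phy_d.loc[eco_d.index, eco_d.index], n_classes, permutations, seed)
    if not res.short_range_signal():
        raise NoPhylogeneticSignalError(
            "no significant positive short-distance class in the Mantel "
            "correlogram; nearest-taxon turnover is not interpretable as "
            "selection here (override to proceed anyway)"
        )
    return res


def classify_pair(bnti_value: float, rc_value: float | None = None) -> str:
    """Assign one community pair to an assembly process.

    betaNTI > +2: variable selection; betaNTI < -2: homogeneous selection;
    otherwise RC_bray > +0.95: dispersal limitation; RC_bray < -0.95:
    homogenizing dispersal; else undominated.  Comparisons are strict, so a
    value exactly at a threshold falls into the less-extreme category.
    A missing betaNTI yields "unclassified".
    """
    if bnti_value is None or math.isnan(bnti_value):
        return "unclassified"
    if bnti_value > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value is None or math.isnan(rc_value):
        return "unclassified"
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def process_fractions(turnover: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Relative influence of the five processes from a pairwise table.

    ``by="group"``: one row over all classified pairs.  ``by="community"``:
    one row per community over its n-1 comparisons.  Fractions are class
    counts over classified comparisons and sum to 1; unclassified pairs are
    excluded from denominators with a logged warning.
    """
    t = turnover[turnover["process_class"] != "unclassified"]
    dropped = len(turnover) - len(t)
    if dropped:
        logger.warning("excluding %d unclassified pair(s) from fractions", dropped)

    def frac(rows: pd.DataFrame) -> dict:
        n = len(rows)
        counts = rows["process_class"].value_counts()
        out = {c: counts.get(c, 0) / n for c in PROCESS_CLASSES}
        out["n_comparisons"] = n
        return out

    if by == "group":
        if len(t) == 0:
            raise ValueError("no classified pairs")
        return pd.DataFrame({"all": frac(t)}).T
    if by == "community":
        units = sorted(set(t["sample_a"]) | set(t["sample_b"]))
        rows = {}
        for u in units:
            sub = t[(t["sample_a"] == u) | (t["sample_b"] == u)]
            if len(sub):
                rows[u] = frac(sub)
        return pd.DataFrame(rows).T
    raise ValueError("by must be 'group' or 'community'")


def nti_summary(values) -> dict:
    """Descriptive summary of per-community NTI values.

    Reports mean, median, sd, the clustering fraction (NTI > +2), the
    two-sided significant fraction (|NTI| > 2), and a one-sample t-test of
    the mean against zero (convenience statistic).
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(v) == 0:
        raise ValueError("no non-missing NTI values")
    if len(v) > 1 and np.std(v) > 0:
        tt = stats.ttest_1samp(v, 0.0)
        t_stat, t_p = float(tt.statistic), float(tt.pvalue)
    else:
        t_stat, t_p = float("nan"), float("nan")
    return {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
        "frac_clustered": float((v > 2).mean()),
        "frac_significant": float((np.abs(v) > 2).mean()),
        "t_statistic": t_stat,
        "t_pvalue": t_p,
    }
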