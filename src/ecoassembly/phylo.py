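"""Deterministic phylogenetic and compositional distance computations.

Patristic (tip-to-tip path) distances, Bray-Curtis dissimilarity, the
abundance-weighted mean nearest taxon distance (MNTD) within a community and
its between-community analogue (betaMNTD).  These are the raw observables the
null models in :mod:`ecoassembly.nullmodels` standardize.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "patristic_distances",
    "bray_curtis",
    "bray_curtis_matrix",
    "mntd",
    "bmntd",
    "SingletonCommunityError",
]


class SingletonCommunityError(ValueError):
    """MNTD is undefined for a community with fewer than two members."""


def patristic_distances(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip path-length matrix of a rooted tree with branch lengths.

    Parameters
    ----------
    tree : skbio.TreeNode
        Rooted tree; every edge must carry a non-negative length.

    Returns
    -------
    pandas.DataFrame
        Square symmetric matrix, zero diagonal, indexed by tip name; entry
        (i, j) is the sum of branch lengths on the unique path between tips
        i and j.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("patristic distances require a tree with >= 2 tips")
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis between rows of a samples x features table."""
    m = table.to_numpy(dtype=float)
    sums = m.sum(axis=1)
    if (sums == 0).any():
        bad = table.index[sums == 0].tolist()
        raise ValueError(f"all-zero rows: {bad}")
    diff = np.abs(m[:, None, :] - m[None, :, :]).sum(axis=2)
    tot = sums[:, None] + sums[None, :]
    out = diff / tot
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.index, columns=table.index)


def _weights(community: pd.Series, abundance_weighted: bool) -> pd.Series:
    comm = community[community > 0].astype(float)
    if abundance_weighted:
        return comm / comm.sum()
    return pd.Series(1.0 / len(comm), index=comm.index)


def mntd(
    community: pd.Series,
    dist: pd.DataFrame,
    abundance_weighted: bool = True,
) -> float:
    """Mean nearest taxon distance of one community.

    ``sum_i f_i * min_{j != i} d(i, j)`` over members i with positive
    abundance; ``f_i`` is the relative abundance (or 1/n unweighted).

    Raises
    ------
    SingletonCommunityError
        If fewer than two members have positive abundance.  Returning 0
        would fake maximal phylogenetic clustering, so the caller has to
        handle this case explicitly.
    """
    w = _weights(community, abundance_weighted)
    if len(w) < 2:
        raise SingletonCommunityError(
            f"MNTD undefined for community with {len(w)} member(s)"
        )
    missing = w.index.difference(dist.index)
    if len(missing):
        raise KeyError(f"OTUs absent from distance matrix: {list(missing)[:5]}")
    sub = dist.loc[w.index, w.index].to_numpy(dtype=float).copy()
    np.fill_diagonal(sub, np.inf)
    return float(w.to_numpy() @ sub.min(axis=1))


def bmntd(
    comm_k: pd.Series,
    comm_m: pd.Series,
    dist: pd.DataFrame,
    abundance_weighted: bool = True,
) -> float:
    """Between-community mean nearest taxon distance (betaMNTD).

    ``0.5 * [ sum_{i in k} f_ik min_{j in m} d(i,j)
            + sum_{i in m} f_im min_{j in k} d(i,j) ]``

    An OTU shared by both communities has a cross-community nearest neighbour
    at distance 0 (itself), matching ``picante::comdistnt`` semantics.
    Symmetric in its community arguments.
    """
    wk = _weights(comm_k, abundance_weighted)
    wm = _weights(comm_m, abundance_weighted)
    if len(wk) == 0 or len(wm) == 0:
        raise ValueError("betaMNTD requires two non-empty communities")
    cross = dist.loc[wk.index, wm.index].to_numpy(dtype=float)
    return float(
        0.5 * (wk.to_numpy() @ cross.min(axis=1) + wm.to_numpy() @ cross.min(axis=0))
    )
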