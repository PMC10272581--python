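"""Randomization engines and standardized effect sizes.

NTI (nearest taxon index) and betaNTI standardize observed MNTD / betaMNTD
against a tip-label-shuffling null: OTU names are permuted across the tips of
the phylogeny (equivalently, rows and columns of the patristic matrix are
relabelled simultaneously) while community composition and abundances stay
fixed.  RC_bray reassembles each community of a pair probabilistically from
its regional pool — membership proportional to occupancy, abundance
proportional to regional relative abundance — and ranks the observed
Bray-Curtis within the resulting null distribution, rescaled to [-1, +1].

Every pair gets an independent null; per-pair seeds are derived
deterministically from one master seed so results do not depend on
evaluation order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import classify_pair
from .phylo import bray_curtis, bmntd, mntd

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "shuffle_tip_labels",
    "nti",
    "bnti",
    "rc_bray",
    "nti_table",
    "pairwise_turnover",
]

_PERM_CHUNK = 250  # permutations held in memory at once for the big 3-d gathers


@dataclass
class NullDistribution:
    """Observed metric, its null sample, and the standardized effect size.

    ``standardized`` is the z-score (or RC rescaling) and is NaN, with a
    logged warning, when the null has zero spread — never +/- infinity.
    """

    observed: float
    null_values: np.ndarray
    standardized: float
    seed: object = None
    exhaustive: bool = False

    @property
    def reps(self) -> int:
        return len(self.null_values)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _sample_perms(rng: np.random.Generator, reps: int, n: int) -> np.ndarray:
    """reps x n matrix of independent uniform permutations of range(n)."""
    return rng.random((reps, n)).argsort(axis=1)


def shuffle_tip_labels(dist: pd.DataFrame, seed) -> pd.DataFrame:
    """Randomly reassign OTU labels across the tips of a patristic matrix.

    Rows and columns are permuted simultaneously and the original labels are
    kept in place, so the multiset of off-diagonal distances is untouched
    while the identity of the tip carrying each label changes.
    """
    rng = _rng(seed)
    perm = rng.permutation(len(dist))
    vals = dist.to_numpy()[np.ix_(perm, perm)]
    return pd.DataFrame(vals, index=dist.index, columns=dist.columns)


def _null_mntd(D: np.ndarray, idx: np.ndarray, w: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """MNTD of one community under each tip-label permutation (vectorized)."""
    out = np.empty(len(perms))
    k = len(idx)
    for lo in range(0, len(perms), _PERM_CHUNK):
        P = perms[lo : lo + _PERM_CHUNK, :][:, idx]  # chunk x k
        sub = D[P[:, :, None], P[:, None, :]]
        sub[:, np.arange(k), np.arange(k)] = np.inf
        out[lo : lo + len(P)] = sub.min(axis=2) @ w
    return out


def _null_bmntd(
    D: np.ndarray,
    idx_k: np.ndarray,
    idx_m: np.ndarray,
    wk: np.ndarray,
    wm: np.ndarray,
    perms: np.ndarray,
) -> np.ndarray:
    out = np.empty(len(perms))
    for lo in range(0, len(perms), _PERM_CHUNK):
        P = perms[lo : lo + _PERM_CHUNK, :]
        Pk, Pm = P[:, idx_k], P[:, idx_m]
        cross = D[Pk[:, :, None], Pm[:, None, :]]
        out[lo : lo + len(P)] = 0.5 * (cross.min(axis=2) @ wk + cross.min(axis=1) @ wm)
    return out


def _standardize(obs: float, null: np.ndarray, negate: bool, ddof: int) -> float:
    mu = float(null.mean())
    sd = float(np.std(null, ddof=ddof))
    if sd == 0:
        # degenerate null: identical communities give betaMNTD = 0 in every
        # replicate.  Zero deviation from a point null is 0, not undefined;
        # only a nonzero deviation over zero spread is flagged missing.
        if abs(obs - mu) <= 1e-12:
            return 0.0
        logger.warning("null distribution has zero spread; standardized value is NaN")
        return float("nan")
    z = (obs - mu) / sd
    return -z if negate else z


def _members(community: pd.Series, dist: pd.DataFrame, abundance_weighted: bool):
    comm = community[community > 0].astype(float)
    idx = dist.index.get_indexer(comm.index)
    if (idx < 0).any():
        raise KeyError("community contains OTUs absent from the distance matrix")
    if abundance_weighted:
        w = (comm / comm.sum()).to_numpy()
    else:
        w = np.full(len(comm), 1.0 / len(comm))
    return idx, w


def _exhaustive_arrangements(n: int, idx_union: np.ndarray) -> np.ndarray:
    """All ordered placements of the occupied positions across n tips."""
    u = len(idx_union)
    arrangements = np.array(list(itertools.permutations(range(n), u)), dtype=np.intp)
    perms = np.tile(np.arange(n, dtype=np.intp), (len(arrangements), 1))
    perms[:, idx_union] = arrangements
    return perms


def nti(
    community: pd.Series,
    dist: pd.DataFrame,
    reps: int = 999,
    seed=None,
    abundance_weighted: bool = True,
    method: str = "sample",
) -> NullDistribution:
    """Nearest taxon index: negative z-score of observed MNTD vs tip-shuffle null.

    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null); positive values mean
    coexisting taxa are more closely related than chance (clustering, flagged
    at NTI > +2), negative values overdispersion (NTI < -2).

    ``method="exhaustive"`` enumerates every distinct tip relabelling instead
    of sampling ``reps`` of them (population sd); only sensible on tiny trees.
    """
    obs = mntd(community, dist, abundance_weighted)
    idx, w = _members(community, dist, abundance_weighted)
    D = dist.to_numpy(dtype=float)
    if method == "exhaustive":
        perms = _exhaustive_arrangements(len(dist), idx)
        null = _null_mntd(D, idx, w, perms)
        return NullDistribution(obs, null, _standardize(obs, null, True, 0), seed, True)
    perms = _sample_perms(_rng(seed), reps, len(dist))
    null = _null_mntd(D, idx, w, perms)
    return NullDistribution(obs, null, _standardize(obs, null, True, 1), seed)


def bnti(
    comm_k: pd.Series,
    comm_m: pd.Series,
    dist: pd.DataFrame,
    reps: int = 999,
    seed=None,
    abundance_weighted: bool = True,
    method: str = "sample",
) -> NullDistribution:
    """betaNTI: z-score of observed betaMNTD against a per-pair tip-shuffle null.

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null).
    |betaNTI| < 2 excludes selection as the dominant process for the pair;
    > +2 indicates variable selection, < -2 homogeneous selection.
    """
    obs = bmntd(comm_k, comm_m, dist, abundance_weighted)
    idx_k, wk = _members(comm_k, dist, abundance_weighted)
    idx_m, wm = _members(comm_m, dist, abundance_weighted)
    D = dist.to_numpy(dtype=float)
    if method == "exhaustive":
        union = np.unique(np.concatenate([idx_k, idx_m]))
        perms = _exhaustive_arrangements(len(dist), union)
        null = _null_bmntd(D, idx_k, idx_m, wk, wm, perms)
        return NullDistribution(obs, null, _standardize(obs, null, False, 0), seed, True)
    perms = _sample_perms(_rng(seed), reps, len(dist))
    null = _null_bmntd(D, idx_k, idx_m, wk, wm, perms)
    return NullDistribution(obs, null, _standardize(obs, null, False, 1), seed)


def _rc_draw_community(
    rng: np.random.Generator,
    reps: int,
    log_occ: np.ndarray,
    pool_p: np.ndarray,
    richness: int,
    total: int,
) -> np.ndarray:
    """Null-assemble one community ``reps`` times (reps x n_taxa counts).

    Membership: ``richness`` taxa drawn without replacement with probability
    proportional to occupancy (Gumbel top-k = sequential weighted sampling).
    Abundance: one founding read per member, the remaining reads multinomial
    with probability proportional to regional relative abundance.
    """
    S = len(log_occ)
    keys = rng.gumbel(size=(reps, S)) + log_occ
    members = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    counts = np.zeros((reps, S))
    rows = np.arange(reps)[:, None]
    counts[rows, members] = 1.0
    extra = total - richness
    if extra > 0:
        pm = pool_p[members]
        pm /= pm.sum(axis=1, keepdims=True)
        for r in range(reps):
            counts[r, members[r]] += rng.multinomial(extra, pm[r])
    return counts


def rc_bray(
    comm_k: pd.Series,
    comm_m: pd.Series,
    pool: pd.DataFrame,
    reps: int = 999,
    seed=None,
) -> NullDistribution:
    """Abundance-weighted Raup-Crick on Bray-Curtis, rescaled to [-1, +1].

    Each replicate reassembles both communities from the regional pool (all
    communities of the group): observed richness drawn occupancy-weighted,
    observed read total allocated abundance-weighted.  The observed
    Bray-Curtis is then ranked within the null sample:

        RC = 2 * [ (#(null < obs) + 0.5 * #(null == obs)) / reps - 0.5 ]

    +1 means the pair is more dissimilar than chance (dispersal limitation
    when |betaNTI| < 2), -1 more similar (homogenizing dispersal).
    """
    if len(pool) < 2:
        raise ValueError("regional pool must contain at least two communities")
    occ = (pool > 0).sum(axis=0).to_numpy(dtype=float)
    taxa = pool.columns[occ > 0]
    if len(taxa) == 0:
        raise ValueError("empty regional pool")
    occ = occ[occ > 0]
    pool_p = pool[taxa].sum(axis=0).to_numpy(dtype=float)
    pool_p /= pool_p.sum()

    ck = comm_k.reindex(taxa, fill_value=0).to_numpy(dtype=float)
    cm = comm_m.reindex(taxa, fill_value=0).to_numpy(dtype=float)
    n_k, n_m = int((ck > 0).sum()), int((cm > 0).sum())
    N_k, N_m = int(ck.sum()), int(cm.sum())
    if n_k == 0 or n_m == 0:
        raise ValueError("RC_bray requires two non-empty communities")
    if max(n_k, n_m) > len(taxa):
        raise ValueError("observed richness exceeds pool richness")
    obs = bray_curtis(ck, cm)

    rng = _rng(seed)
    a = _rc_draw_community(rng, reps, np.log(occ), pool_p, n_k, N_k)
    b = _rc_draw_community(rng, reps, np.log(occ), pool_p, n_m, N_m)
    null = np.abs(a - b).sum(axis=1) / (a + b).sum(axis=1)

    less = int((null < obs - 1e-12).sum())
    equal = int((np.abs(null - obs) <= 1e-12).sum())
    rc = 2.0 * ((less + 0.5 * equal) / reps - 0.5)
    return NullDistribution(obs, null, rc, seed)


def _pair_seed(master, *tags) -> np.random.SeedSequence:
    entropy = 0 if master is None else master
    return np.random.SeedSequence(entropy=entropy, spawn_key=tuple(tags))


def nti_table(
    table: pd.DataFrame,
    dist: pd.DataFrame,
    reps: int = 999,
    seed=None,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """NTI for every sample of a group table (one null per community).

    Samples whose NTI is undefined (singletons, zero-spread nulls) get NaN
    with a logged warning rather than being dropped silently.
    """
    rows = {}
    for i, sid in enumerate(table.index):
        sub_seed = _pair_seed(seed, 0, i)
        try:
            nd = nti(table.loc[sid], dist, reps, sub_seed, abundance_weighted)
            rows[sid] = {"mntd_obs": nd.observed, "nti": nd.standardized}
        except Exception as exc:  # singleton community
            logger.warning("NTI undefined for %s: %s", sid, exc)
            rows[sid] = {"mntd_obs": float("nan"), "nti": float("nan")}
    return pd.DataFrame(rows).T


def pairwise_turnover(
    table: pd.DataFrame,
    dist: pd.DataFrame,
    reps: int = 999,
    seed=None,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI + RC_bray + process class for every unordered pair of a group.

    ``table`` holds the group's communities (samples x OTUs counts, e.g.
    rarefied); ``dist`` the patristic matrix covering its OTUs.  The null
    pool for both metrics is the group itself: tip shuffles run over the
    OTUs present in the group and RC_bray uses the group's occupancies and
    regional abundances.  Per-pair seeds derive from the master ``seed`` so
    the result is independent of evaluation order.

    Returns a long-format table: sample_a, sample_b, bmntd_obs, bnti,
    bc_obs, rc_bray, process_class.
    """
    if len(table) < 2:
        raise ValueError("need at least two communities")
    present = table.columns[table.sum(axis=0) > 0]
    table = table[present]
    missing = present.difference(dist.index)
    if len(missing):
        raise KeyError(f"OTUs missing from distance matrix: {list(missing)[:5]}")
    dist = dist.loc[present, present]

    rel = table.div(table.sum(axis=1), axis=0)
    records = []
    for p, (i, j) in enumerate(itertools.combinations(range(len(table)), 2)):
        sa, sb = table.index[i], table.index[j]
        b = bnti(rel.iloc[i], rel.iloc[j], dist, reps, _pair_seed(seed, 1, p), abundance_weighted)
        r = rc_bray(table.iloc[i], table.iloc[j], table, reps, _pair_seed(seed, 2, p))
        records.append(
            {
                "sample_a": sa,
                "sample_b": sb,
                "bmntd_obs": b.observed,
                "bnti": b.standardized,
                "bc_obs": r.observed,
                "rc_bray": r.standardized,
                "process_class": classify_pair(b.standardized, r.standardized),
            }
        )
    return pd.DataFrame.from_records(records)
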