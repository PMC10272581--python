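"""Desk-scale verification experiments for the whole pipeline.

Each function here re-runs part of the package against an independent
reference — a brute-force oracle, an exhaustive enumeration, the null
model's own generative procedure, or the synthetic generator's ground
truth — and returns summary numbers.  They back both the test suite and
``scripts/acceptance.py``.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawn keys, so every experiment is
reproducible and independent of execution order.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import phylo
from .costructure import rv_coefficient
from .inference import (
    PROCESS_CLASSES,
    classify_pair,
    mantel_correlogram,
    otu_profile_distances,
    process_fractions,
)
from .io import prune_to_shared_taxa
from .nullmodels import (
    _rc_draw_community,
    bnti,
    nti,
    pairwise_turnover,
    rc_bray,
    shuffle_tip_labels,
)
from .simulate import AssemblyScenario, scenario_fixture, simulate_dataset, simulate_tree

__all__ = [
    "design_combinatorics",
    "oracle_equivalence",
    "exhaustive_null_deviation",
    "rc_selfnull_calibration",
    "bnti_shuffle_calibration",
    "regime_recovery",
    "signal_rates",
    "classification_consistency",
]


def _seq(seed, *key):
    return np.random.SeedSequence(entropy=seed, spawn_key=key)


# ---------------------------------------------------------------------------
# design combinatorics


def design_combinatorics(seed: int = 0, reps: int = 29) -> dict:
    """Pair counts of the study design: 3 groups x 10 sites, two metrics.

    Runs the full turnover pipeline on a small three-group synthetic
    dataset and counts what it produced: C(10,2) = 45 within-group pairs
    and 3 groups x 45 x 2 metrics = 270 metric-pair computations.
    """
    sc = AssemblyScenario(
        n_groups=3, pool_richness=40, depth=300, regime="drift", sad_sigma=1.0,
        seed=int(_seq(seed, 0).generate_state(1)[0] % 2**31),
    )
    ds = simulate_dataset(sc)
    pair_counts = []
    metric_computations = 0
    for g in ds.groups:
        table, dist = prune_to_shared_taxa(ds.tables[g], phylo.patristic_distances(ds.trees[g]))
        t = pairwise_turnover(table, dist, reps=reps, seed=seed)
        pair_counts.append(len(t))
        metric_computations += int(t["bnti"].notna().sum() + t["rc_bray"].notna().sum())
    assert len(set(pair_counts)) == 1
    return {
        "pairs_per_group": pair_counts[0],
        "metric_pair_computations": metric_computations,
    }


# ---------------------------------------------------------------------------
# brute-force oracle equivalence


def _naive_patristic(tree) -> pd.DataFrame:
    paths = {}
    for tip in tree.tips():
        node, path = tip, []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = path
    names = sorted(paths)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        ids_a = {id(n) for n in paths[a]}
        shared = sum(n.length for n in paths[b] if id(n) in ids_a)
        d = sum(n.length for n in paths[a]) + sum(n.length for n in paths[b]) - 2 * shared
        out.loc[a, b] = out.loc[b, a] = d
    return out


def oracle_equivalence(seed: int = 0, n_taxa: int = 20, n_draws: int = 5) -> dict:
    """Max abs deviation of each metric from a naive reimplementation."""
    rng = np.random.default_rng(_seq(seed, 1))
    tree = simulate_tree(n_taxa, seed=_seq(seed, 1, 0))
    fast = phylo.patristic_distances(tree)
    slow = _naive_patristic(tree)
    errs = {"patristic": float(np.abs(fast.loc[slow.index, slow.columns] - slow).to_numpy().max())}

    e_mntd = e_bmntd = e_bc = 0.0
    for _ in range(n_draws):
        a = pd.Series(rng.integers(0, 5, n_taxa), index=fast.index)
        b = pd.Series(rng.integers(0, 5, n_taxa), index=fast.index)
        if (a > 0).sum() < 2 or (b > 0).sum() < 2:
            continue
        # naive double loops
        fa = a[a > 0] / a[a > 0].sum()
        naive_m = sum(
            fa[i] * min(fast.loc[i, j] for j in fa.index if j != i) for i in fa.index
        )
        e_mntd = max(e_mntd, abs(phylo.mntd(a, fast) - naive_m))
        fb = b[b > 0] / b[b > 0].sum()
        naive_b = 0.5 * (
            sum(fa[i] * min(fast.loc[i, j] for j in fb.index) for i in fa.index)
            + sum(fb[i] * min(fast.loc[i, j] for j in fa.index) for i in fb.index)
        )
        e_bmntd = max(e_bmntd, abs(phylo.bmntd(a, b, fast) - naive_b))
        x, y = a.to_numpy(float), b.to_numpy(float)
        e_bc = max(
            e_bc, abs(phylo.bray_curtis(x, y) - np.abs(x - y).sum() / (x + y).sum())
        )
    errs.update({"mntd": float(e_mntd), "bmntd": float(e_bmntd), "bray_curtis": float(e_bc)})

    x = rng.normal(size=(6, 4))
    y = rng.normal(size=(6, 5))
    xc, yc = x - x.mean(0), y - y.mean(0)
    xxt, yyt = xc @ xc.T, yc @ yc.T
    naive_rv = np.trace(xxt @ yyt) / np.sqrt(np.trace(xxt @ xxt) * np.trace(yyt @ yyt))
    errs["rv"] = float(abs(rv_coefficient(xc, yc) - naive_rv))
    return errs


# ---------------------------------------------------------------------------
# exhaustive-null equivalence


def exhaustive_null_deviation(seed: int = 0, reps: int = 999, n_seeds: int = 20) -> dict:
    """Sampled NTI / betaNTI vs exhaustive tip-relabeling null on tiny trees.

    Returns the deviation of the sampled-null mean from the exhaustive value
    in units of the Monte-Carlo standard error (|dev| < 3 expected).
    """
    tree5 = simulate_tree(5, seed=_seq(seed, 2, 0))
    d5 = phylo.patristic_distances(tree5)
    comm = pd.Series({d5.index[0]: 3.0, d5.index[2]: 1.0, d5.index[4]: 2.0})
    exact = nti(comm, d5, method="exhaustive").standardized
    samples = [nti(comm, d5, reps=reps, seed=_seq(seed, 2, 1, s)).standardized for s in range(n_seeds)]
    se = np.std(samples, ddof=1) / np.sqrt(n_seeds)
    out = {"nti_dev_se": float(abs(np.mean(samples) - exact) / se)}

    tree6 = simulate_tree(6, seed=_seq(seed, 2, 2))
    d6 = phylo.patristic_distances(tree6)
    k = pd.Series(1.0, index=d6.index[:3])
    m = pd.Series([2.0, 1.0, 1.0], index=d6.index[2:5])
    exact_b = bnti(k, m, d6, method="exhaustive").standardized
    samples_b = [bnti(k, m, d6, reps=reps, seed=_seq(seed, 2, 3, s)).standardized for s in range(n_seeds)]
    se_b = np.std(samples_b, ddof=1) / np.sqrt(n_seeds)
    out["bnti_dev_se"] = float(abs(np.mean(samples_b) - exact_b) / se_b)
    return out


# ---------------------------------------------------------------------------
# self-null calibration


def rc_selfnull_calibration(seed: int = 0, n_pairs: int = 200, reps: int = 199) -> dict:
    """RC_bray on pairs generated by its own reassembly null.

    When the observed communities come from the null's own generative
    procedure, RC should be centred near 0 with few |RC| > 0.95.
    """
    ds = simulate_dataset(
        scenario_fixture("drift", seed=int(_seq(seed, 3).generate_state(1)[0] % 2**31))
    )
    pool = ds.tables["g1"]
    pool = pool[pool.columns[pool.sum(0) > 0]]
    occ = (pool > 0).sum(0).to_numpy(float)
    pool_p = pool.sum(0).to_numpy(float)
    pool_p /= pool_p.sum()
    richness = (pool > 0).sum(1).to_numpy()
    totals = pool.sum(1).to_numpy()
    rng = np.random.default_rng(_seq(seed, 3, 1))
    vals = []
    for i in range(n_pairs):
        rk, rm = richness[i % len(richness)], richness[(i + 1) % len(richness)]
        tk, tm = totals[i % len(totals)], totals[(i + 1) % len(totals)]
        a = _rc_draw_community(rng, 1, np.log(occ), pool_p.copy(), int(rk), int(tk))[0]
        b = _rc_draw_community(rng, 1, np.log(occ), pool_p.copy(), int(rm), int(tm))[0]
        res = rc_bray(
            pd.Series(a, index=pool.columns),
            pd.Series(b, index=pool.columns),
            pool,
            reps=reps,
            seed=_seq(seed, 3, 2, i),
        )
        vals.append(res.standardized)
    vals = np.asarray(vals)
    return {
        "mean": float(vals.mean()),
        "frac_extreme": float((np.abs(vals) > 0.95).mean()),
        "n_pairs": int(n_pairs),
    }


def bnti_shuffle_calibration(seed: int = 0, n_trials: int = 100, reps: int = 199) -> dict:
    """betaNTI on observations whose tip labels were themselves shuffled.

    Randomizing the observed data the same way the null does should leave
    |betaNTI| < 2 in the vast majority of trials.
    """
    ds = simulate_dataset(
        scenario_fixture(
            "variable_selection", seed=int(_seq(seed, 4).generate_state(1)[0] % 2**31)
        )
    )
    table, dist = prune_to_shared_taxa(
        ds.tables["g1"], phylo.patristic_distances(ds.trees["g1"])
    )
    rel = table.div(table.sum(1), axis=0)
    rng = np.random.default_rng(_seq(seed, 4, 1))
    pairs = list(itertools.combinations(range(len(table)), 2))
    inside = 0
    for t in range(n_trials):
        i, j = pairs[rng.integers(len(pairs))]
        d_shuf = shuffle_tip_labels(dist, seed=_seq(seed, 4, 2, t))
        z = bnti(rel.iloc[i], rel.iloc[j], d_shuf, reps=reps, seed=_seq(seed, 4, 3, t)).standardized
        inside += bool(abs(z) < 2)
    return {"frac_within_2": inside / n_trials, "n_trials": int(n_trials)}


# ---------------------------------------------------------------------------
# regime recovery


def _run_pipeline(scenario_name: str, run_seed: int, reps: int):
    ds = simulate_dataset(scenario_fixture(scenario_name, seed=run_seed))
    table, dist = prune_to_shared_taxa(
        ds.tables["g1"], phylo.patristic_distances(ds.trees["g1"])
    )
    return pairwise_turnover(table, dist, reps=reps, seed=run_seed)


def regime_recovery(seed: int = 0, n_seeds: int = 10, reps: int = 199) -> dict:
    """Fraction of master seeds whose modal class matches the regime.

    For the drift scenario the reported number is instead the fraction of
    all pairs (over the seeds) classified undominated or homogenizing
    dispersal, the two classes a neutral well-mixed metacommunity should
    produce.
    """
    out = {}
    directed = (
        "homogeneous_selection",
        "variable_selection",
        "dispersal_limitation",
        "homogenizing_dispersal",
    )
    for regime in directed:
        hits = 0
        for s in range(n_seeds):
            run_seed = int(_seq(seed, 5, directed.index(regime), s).generate_state(1)[0] % 2**31)
            t = _run_pipeline(regime, run_seed, reps)
            counts = t["process_class"].value_counts()
            hits += counts.idxmax() == regime
        out[regime] = hits / n_seeds
    stochastic = []
    for s in range(n_seeds):
        run_seed = int(_seq(seed, 5, 9, s).generate_state(1)[0] % 2**31)
        t = _run_pipeline("drift", run_seed, reps)
        stochastic.append(
            t["process_class"].isin(["undominated", "homogenizing_dispersal"]).to_numpy()
        )
    out["drift_stochastic_pair_fraction"] = float(np.concatenate(stochastic).mean())
    out["n_seeds"] = int(n_seeds)
    return out


# ---------------------------------------------------------------------------
# phylogenetic signal


def signal_rates(
    seed: int = 0,
    n_detect: int = 50,
    n_false: int = 200,
    permutations: int = 199,
    n_classes: int = 10,
) -> dict:
    """Shortest-class detection rate on structured communities and the
    class-level false-positive rate on phylogeny-independent profiles."""
    detected = 0
    for s in range(n_detect):
        run_seed = int(_seq(seed, 6, 0, s).generate_state(1)[0] % 2**31)
        ds = simulate_dataset(scenario_fixture("variable_selection", seed=run_seed))
        table, dist = prune_to_shared_taxa(
            ds.tables["g1"], phylo.patristic_distances(ds.trees["g1"])
        )
        eco = otu_profile_distances(table)
        res = mantel_correlogram(
            eco, dist.loc[eco.index, eco.index], n_classes, permutations, seed=_seq(seed, 6, 1, s)
        )
        row0 = res.table.iloc[0]
        detected += bool(row0["r"] > 0 and row0["p"] <= 0.05)

    fp = total = 0
    for s in range(n_false):
        rng = np.random.default_rng(_seq(seed, 6, 2, s))
        tree = simulate_tree(40, seed=_seq(seed, 6, 3, s))
        dist = phylo.patristic_distances(tree)
        table = pd.DataFrame(
            rng.integers(1, 50, (8, 40)),
            index=[f"s{i}" for i in range(8)],
            columns=dist.index,
        )
        eco = otu_profile_distances(table)
        res = mantel_correlogram(
            eco, dist, n_classes, permutations, seed=_seq(seed, 6, 4, s)
        )
        p = res.table["p"].dropna()
        fp += int((p <= 0.05).sum())
        total += len(p)
    return {
        "detection_rate": detected / n_detect,
        "false_positive_rate": fp / total,
        "n_detect": int(n_detect),
        "n_false_tests": int(total),
    }


# ---------------------------------------------------------------------------
# classification algebra


def classification_consistency(seed: int = 0) -> dict:
    """Exhaustiveness/exclusivity of the decision rules on a value grid and
    the worst deviation of process-fraction sums from 1."""
    ok = True
    for b in np.linspace(-4, 4, 81):
        for r in np.linspace(-1, 1, 41):
            cls = classify_pair(float(b), float(r))
            if cls not in PROCESS_CLASSES:
                ok = False
            expected = (
                "variable_selection" if b > 2
                else "homogeneous_selection" if b < -2
                else "dispersal_limitation" if r > 0.95
                else "homogenizing_dispersal" if r < -0.95
                else "undominated"
            )
            ok = ok and cls == expected
    rng = np.random.default_rng(_seq(seed, 7))
    samples = [f"s{i}" for i in range(10)]
    pairs = list(itertools.combinations(samples, 2))
    t = pd.DataFrame(
        {
            "sample_a": [a for a, _ in pairs],
            "sample_b": [b for _, b in pairs],
            "process_class": rng.choice(PROCESS_CLASSES, len(pairs)),
        }
    )
    worst = 0.0
    for by in ("group", "community"):
        f = process_fractions(t, by=by)
        worst = max(worst, float(np.abs(f[list(PROCESS_CLASSES)].sum(1) - 1).max()))
    return {"grid_consistent": float(ok), "fraction_sum_max_err": worst}
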