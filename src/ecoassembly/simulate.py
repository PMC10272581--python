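"""Synthetic communities with known assembly regimes.

The generator produces everything the inference pipeline consumes — an
ultrametric birth-death phylogeny, niche traits on its tips, per-site
environments, and read-count tables — together with truth labels recording
the generating regime, so every stage of the pipeline can be checked
against ground truth.

Niche model
-----------
Habitat affinity is phylogenetically conserved at the level of *niche
blocks*: the maximal clades whose crown age is at most a fraction
``block_depth_frac`` of the tree depth.  Each block draws an affinity value
uniformly on [-1, 1] (niches shift when new clades are founded and are
conserved within them), and tips add a small Brownian jitter so affinity
also varies continuously among close relatives.  A site with environmental
optimum ``o`` admits the fraction ``window_frac`` of the pool whose
affinity is closest to ``o``; among admitted taxa an establishment lottery
keeps each with probability ``establishment``, but never leaves an admitted
block empty (the niche is always filled by some member — a competitive
lottery).  This combination is what makes selection *detectable* by
nearest-taxon statistics at desk scale: sites retain the same tight clades
while swapping which close relatives represent them.

Regimes
-------
homogeneous_selection
    Identical optima everywhere; turnover happens only within the admitted
    clades (establishment lottery), so between-site phylogenetic turnover is
    much lower than the tip-shuffle null expects (betaNTI << 0).
variable_selection
    Optima follow a monotone environmental gradient, so sites at opposite
    ends admit phylogenetically divergent clades (betaNTI >> 0).
dispersal_limitation
    No selection; each taxon has a home site and reaches others through an
    exponential kernel exp(-distance/lambda) with lambda = -1/log(rate), so
    composition turns over in space far more than the pool-based null
    expects (RC_bray -> +1) while phylogenetic turnover stays random.
homogenizing_dispersal
    No selection; mass effects dominate: a fraction ``dispersal_rate`` of
    every site's reads is one shared realized metacommunity draw, making
    sites more similar than independent sampling from a common pool could
    (RC_bray -> -1).
drift
    No selection, well mixed: sites are independent multinomial samples of
    the regional abundance distribution at low depth; turnover is pure
    sampling drift and neither metric deviates far from its null.

All sites additionally receive a small stream of transient immigrant reads
drawn uniformly from the full pool, which keeps the realized regional pool
broad — without it, a strongly selected metacommunity contains only the
favoured clades and the tip-shuffle null has nothing to contrast against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "AssemblyScenario",
    "SimulatedDataset",
    "simulate_tree",
    "evolve_traits",
    "niche_blocks",
    "assemble_communities",
    "simulate_dataset",
    "scenario_fixture",
    "SCENARIOS",
]

REGIMES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


# ---------------------------------------------------------------------------
# phylogeny and traits


class _Lineage:
    __slots__ = ("start", "end", "children", "dead")

    def __init__(self, start: float):
        self.start = start
        self.end: float | None = None
        self.children: list[_Lineage] = []
        self.dead = False


def _to_newick(node: _Lineage, counter: list) -> str | None:
    """Emit the extant-pruned subtree, collapsing unary internal nodes."""
    length = node.end - node.start
    if not node.children:
        if node.dead:
            return None
        counter[0] += 1
        return f"T{counter[0]}:{length:.10f}"
    parts = [_to_newick(c, counter) for c in node.children]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    if len(parts) == 1:  # unary after pruning: fold branch into child
        name, _, blen = parts[0].rpartition(":")
        return f"{name}:{float(blen) + length:.10f}"
    return f"({','.join(parts)}):{length:.10f}"


def simulate_tree(n_tips: int, birth: float = 1.0, death: float = 0.0, seed=None) -> TreeNode:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant tips.

    Forward simulation from a crown of two lineages; on total extinction the
    simulation restarts.  The clock stops when the tree holds ``n_tips``
    extant lineages and the next event would be a birth, so for a pure-birth
    process the expected crown-to-tip depth is sum_{k=2..n} 1/(k*birth).
    Tips are labelled T1..Tn in tree order.  Deterministic for a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if birth <= death or death < 0:
        raise ValueError("require birth > death >= 0")
    rng = np.random.default_rng(seed)
    while True:
        root = _Lineage(0.0)
        root.end = 0.0
        active = [_Lineage(0.0), _Lineage(0.0)]
        root.children = list(active)
        t = 0.0
        while active:
            k = len(active)
            t += rng.exponential(1.0 / (k * (birth + death)))
            is_birth = rng.random() < birth / (birth + death)
            if k == n_tips and is_birth:
                break
            lin = active[rng.integers(k)]
            lin.end = t
            active.remove(lin)
            if is_birth:
                lin.children = [_Lineage(t), _Lineage(t)]
                active.extend(lin.children)
            else:
                lin.dead = True
        if len(active) == n_tips:
            for lin in active:
                lin.end = t
            counter = [0]
            newick = _to_newick(root, counter)
            assert counter[0] == n_tips
            # the crown has length 0; strip it to make a clean rooted tree
            return TreeNode.read(StringIO(newick.rpartition(":")[0] + ";"))


def evolve_traits(tree: TreeNode, sigma2: float = 1.0, seed=None) -> pd.Series:
    """Brownian motion of a continuous trait along the tree.

    Root value 0; each edge adds an independent Normal(0, sigma2 * length)
    increment, so Cov(trait_i, trait_j) = sigma2 * shared path length.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        step = 0.0 if sigma2 == 0 else rng.normal(0.0, np.sqrt(sigma2 * node.length))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait")


def niche_blocks(tree: TreeNode, depth_frac: float = 0.25) -> pd.Series:
    """Partition tips into tight clades (crown age <= depth_frac * tree depth).

    Returns tip name -> integer block id.  Blocks are the units of niche
    conservatism: habitat affinity is shared within a block.
    """
    depths = {}

    def tip_depth(node, acc):
        for ch in node.children:
            d = acc + (ch.length or 0.0)
            if ch.is_tip():
                depths[ch.name] = d
            else:
                tip_depth(ch, d)

    tip_depth(tree, 0.0)
    total = max(depths.values())
    tau = depth_frac * total
    out = {}

    def crown_age(node, acc):
        tips = [node] if node.is_tip() else list(node.tips())
        return max(depths[t.name] for t in tips) - acc

    def rec(node, acc):
        for ch in node.children:
            d = acc + (ch.length or 0.0)
            if ch.is_tip() or crown_age(ch, d) <= tau:
                cid = len(set(out.values()))
                for tp in [ch] if ch.is_tip() else ch.tips():
                    out[tp.name] = cid
            else:
                rec(ch, d)

    rec(tree, 0.0)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class AssemblyScenario:
    """Full parameterization of one synthetic assembly simulation.

    ``regime`` is one of the five process names or a mixture-weight dict
    over them (weights sum to 1; mechanisms are blended proportionally —
    a heuristic convenience, not a calibrated model).

    Parameters
    ----------
    window_frac : float
        Fraction of the pool admitted by a site's niche filter (selection
        regimes).  Smaller = stronger selection.
    establishment : float
        Per-taxon establishment probability among admitted taxa; the
        lottery that creates within-clade membership turnover.  Admitted
        blocks are never left empty.
    block_depth_frac : float
        Crown-age cutoff (fraction of tree depth) defining niche blocks.
    niche_jitter : float
        SD of the Brownian component added to block affinities (affinity
        units; affinities span [-1, 1]).
    dispersal_rate : float in (0, 1]
        Kernel range for dispersal limitation (lambda = -1/log(rate)) and
        the shared mass-effect read fraction for homogenizing dispersal.
    immigration : float
        Fraction of each site's reads that are uniform transient
        immigrants from the full pool.
    sad_sigma : float
        Lognormal sigma of regional abundances.
    depth : int or per-group tuple
        Reads per site community.
    """

    n_sites: int = 10
    n_groups: int = 3
    pool_richness: tuple[int, ...] | int = 100
    birth: float = 1.0
    death: float = 0.0
    trait_sigma2: float = 1.0
    regime: str | dict = "variable_selection"
    window_frac: float = 0.3
    establishment: float = 0.8
    block_depth_frac: float = 0.25
    niche_jitter: float = 0.05
    dispersal_rate: float = 1.0
    immigration: float = 0.02
    sad_sigma: float = 0.3
    depth: tuple[int, ...] | int = 400
    couple_groups: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.n_sites < 3:
            raise ValueError("need at least three sites")
        if isinstance(self.regime, dict):
            unknown = set(self.regime) - set(REGIMES)
            if unknown:
                raise ValueError(f"unknown regime(s): {sorted(unknown)}")
            if abs(sum(self.regime.values()) - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
        elif self.regime not in REGIMES:
            raise ValueError(f"unknown regime: {self.regime}")
        if not (0 < self.dispersal_rate <= 1):
            raise ValueError("dispersal_rate must lie in (0, 1]")
        if not (0 < self.window_frac <= 1):
            raise ValueError("window_frac must lie in (0, 1]")
        if not (0 < self.establishment <= 1):
            raise ValueError("establishment must lie in (0, 1]")
        for d in self.depths():
            if d <= 0:
                raise ValueError("depth must be positive")

    def _per_group(self, value) -> tuple:
        if isinstance(value, (tuple, list)):
            if len(value) != self.n_groups:
                raise ValueError("per-group value length mismatch")
            return tuple(value)
        return tuple([value] * self.n_groups)

    def richnesses(self) -> tuple[int, ...]:
        return self._per_group(self.pool_richness)

    def depths(self) -> tuple[int, ...]:
        return self._per_group(self.depth)

    def weights(self) -> dict:
        if isinstance(self.regime, dict):
            return {r: float(self.regime.get(r, 0.0)) for r in REGIMES}
        return {r: 1.0 if r == self.regime else 0.0 for r in REGIMES}


def assemble_communities(
    scenario: AssemblyScenario,
    tree: TreeNode,
    traits: pd.Series,
    seed=None,
    group: str = "g1",
    prey_rel: pd.DataFrame | None = None,
    prey_link: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assemble one group's site communities under the scenario's regime.

    Returns (counts table sites x OTUs, site metadata, truth labels).
    ``prey_rel``/``prey_link`` optionally couple this group's taxa to a prey
    group's site abundances (trophic coupling for co-structure demos).
    """
    rng = np.random.default_rng(seed if seed is not None else scenario.seed)
    taxa = [t.name for t in tree.tips()]
    traits = traits.loc[taxa]
    S, n = len(taxa), scenario.n_sites
    w = scenario.weights()
    pos = np.arange(n, dtype=float)
    depth = scenario.depths()[0] if isinstance(scenario.depth, (tuple, list)) else scenario.depth

    regional = rng.lognormal(0.0, scenario.sad_sigma, size=S)

    # --- niche structure (selection regimes) -------------------------------
    w_sel = w["homogeneous_selection"] + w["variable_selection"]
    niche = None
    optima = np.zeros(n)
    blocks = None
    if w_sel > 0:
        bl = niche_blocks(tree, scenario.block_depth_frac).loc[taxa]
        blocks = bl.to_numpy()
        affinity = rng.uniform(-1.0, 1.0, size=bl.nunique())[blocks]
        jitter = traits.to_numpy()
        sdj = jitter.std()
        if scenario.niche_jitter > 0 and sdj > 0:
            affinity = affinity + scenario.niche_jitter * jitter / sdj
        niche = affinity
        grad_share = w["variable_selection"] / w_sel
        anchor = niche[rng.integers(S)]
        optima = (1.0 - grad_share) * anchor + grad_share * np.linspace(-1.0, 1.0, n)

    # --- dispersal kernel (home sites) -------------------------------------
    home = None
    lam = None
    kernel = np.ones((n, S))
    if w["dispersal_limitation"] > 0:
        rate_eff = 1.0 - w["dispersal_limitation"] * (1.0 - scenario.dispersal_rate)
        if rate_eff < 1.0:
            lam = -1.0 / np.log(rate_eff)
            home = rng.integers(0, n, size=S)
            kernel = np.exp(-np.abs(pos[:, None] - pos[None, home]) / lam)

    # --- mass effects (homogenizing dispersal) -----------------------------
    mass_share = w["homogenizing_dispersal"] * scenario.dispersal_rate
    shared_reads = int(round(mass_share * depth))
    p_regional = regional / regional.sum()
    shared = rng.multinomial(shared_reads, p_regional) if shared_reads > 0 else None

    n_imm = int(round(scenario.immigration * depth))
    own_reads = depth - shared_reads - n_imm
    if own_reads < 0:
        raise ValueError("immigration + mass-effect fractions exceed 1")

    counts = np.zeros((n, S), dtype=np.int64)
    for j in range(n):
        base = regional * kernel[j]
        if niche is not None:
            gap = np.abs(niche - optima[j])
            thr = np.quantile(gap, scenario.window_frac)
            admitted = gap <= thr
            est = rng.random(S) < scenario.establishment
            # competitive lottery: an admitted niche block is never empty
            for b in np.unique(blocks[admitted]):
                members = np.flatnonzero(admitted & (blocks == b))
                if not est[members].any():
                    est[rng.choice(members)] = True
            filt = admitted & est
            if w_sel >= 1.0:
                base = base * filt
            else:  # mixture: partial weight for non-admitted taxa
                base = base * ((1.0 - w_sel) + w_sel * filt)
        if base.sum() == 0:
            base = regional
        counts[j] = rng.multinomial(own_reads, base / base.sum())
        if n_imm > 0:
            counts[j] += rng.multinomial(n_imm, np.full(S, 1.0 / S))
        if shared is not None:
            counts[j] += shared

    if prey_rel is not None and prey_link is not None:
        # trophic coupling: re-weight reads toward taxa whose prey partner
        # thrives at the site, then resample to keep totals fixed
        prey_w = prey_rel.to_numpy()[:, prey_link] + 0.05
        for j in range(n):
            wj = counts[j] * prey_w[j]
            if wj.sum() > 0:
                counts[j] = rng.multinomial(depth, wj / wj.sum())

    if (counts.sum(axis=1) == 0).any():
        raise RuntimeError("empty community generated")

    sites = [f"S{j + 1:02d}" for j in range(n)]
    samples = [f"{group}.{s}" for s in sites]
    table = pd.DataFrame(counts, index=samples, columns=taxa)
    meta = pd.DataFrame(
        {
            "site": sites,
            "group": group,
            "latitude": 30.0,
            "longitude": pos * 0.02,
            "env_optimum": optima,
        },
        index=samples,
    )
    truth = {
        "group": group,
        "regime": scenario.regime if isinstance(scenario.regime, str) else dict(scenario.regime),
        "optima": optima.tolist(),
        "dispersal_lambda": lam,
        "mass_effect_share": mass_share,
        "depth": int(depth),
        "home_site": None if home is None else home.tolist(),
    }
    return table, meta, truth


@dataclass
class SimulatedDataset:
    """Everything one scenario run produces, keyed by group label."""

    scenario: AssemblyScenario
    trees: dict
    traits: dict
    tables: dict
    metadata: pd.DataFrame
    truth: dict

    @property
    def groups(self) -> list:
        return list(self.tables)


def simulate_dataset(scenario: AssemblyScenario, group_names=None) -> SimulatedDataset:
    """Simulate every group of a scenario (tree, traits, communities).

    Groups are independent (own tree, pool and SAD) unless
    ``scenario.couple_groups`` is set, in which case each non-first group's
    taxa are linked to random taxa of the first group and their reads
    re-weighted by the linked prey's site abundance (simple trophic
    coupling producing co-structure between the tables).
    """
    ss = np.random.SeedSequence(0 if scenario.seed is None else scenario.seed)
    children = ss.spawn(scenario.n_groups * 3)
    if group_names is None:
        group_names = [f"g{i + 1}" for i in range(scenario.n_groups)]
    richness = scenario.richnesses()
    depths = scenario.depths()
    trees, traits, tables, truth = {}, {}, {}, {}
    metas = []
    prey_rel = None
    for i, gname in enumerate(group_names):
        tree = simulate_tree(richness[i], scenario.birth, scenario.death, children[3 * i])
        tr = evolve_traits(tree, scenario.trait_sigma2, children[3 * i + 1])
        sc_g = replace(scenario, depth=depths[i])
        link = None
        prey = None
        if scenario.couple_groups and prey_rel is not None:
            rng = np.random.default_rng(children[3 * i + 2].spawn(1)[0])
            link = rng.integers(0, prey_rel.shape[1], size=richness[i])
            prey = prey_rel
        table, meta, tru = assemble_communities(
            sc_g, tree, tr, seed=children[3 * i + 2], group=gname, prey_rel=prey, prey_link=link
        )
        if i == 0:
            prey_rel = table.div(table.sum(axis=1), axis=0)
        trees[gname], traits[gname], tables[gname], truth[gname] = tree, tr, table, tru
        metas.append(meta)
    return SimulatedDataset(scenario, trees, traits, tables, pd.concat(metas), truth)


# ---------------------------------------------------------------------------
# fixture registry

SCENARIOS: dict[str, AssemblyScenario] = {
    "homogeneous_selection": AssemblyScenario(
        n_groups=1, regime="homogeneous_selection", establishment=0.5, depth=400
    ),
    "variable_selection": AssemblyScenario(
        n_groups=1, regime="variable_selection", establishment=0.8, depth=400
    ),
    # high establishment: strong within-community clustering (NTI demos)
    "strong_selection": AssemblyScenario(
        n_groups=1, regime="homogeneous_selection", establishment=0.9, depth=400
    ),
    "dispersal_limitation": AssemblyScenario(
        n_groups=1, regime="dispersal_limitation", dispersal_rate=0.2, sad_sigma=1.0, depth=1000
    ),
    "homogenizing_dispersal": AssemblyScenario(
        n_groups=1, regime="homogenizing_dispersal", dispersal_rate=0.95, sad_sigma=1.0, depth=1000
    ),
    "drift": AssemblyScenario(
        n_groups=1, regime="drift", dispersal_rate=1.0, sad_sigma=1.0, depth=500
    ),
    # shape of the lake study: 3 size-fraction groups x 10 site communities,
    # per-group pool richness and rarefaction depths as reported there
    "lake-survey": AssemblyScenario(
        n_groups=3,
        pool_richness=(834, 99, 102),
        depth=(32029, 13975, 16313),
        regime="variable_selection",
        couple_groups=True,
    ),
    "tiny": AssemblyScenario(
        n_sites=4, n_groups=1, pool_richness=12, depth=200, regime="drift", sad_sigma=1.0
    ),
}


def scenario_fixture(name: str, seed: int | None = None) -> AssemblyScenario:
    """Look up a registered scenario, optionally rebinding its seed."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    sc = SCENARIOS[name]
    return sc if seed is None else replace(sc, seed=seed)
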