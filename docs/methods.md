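# Methods

This note documents the models, null procedures, numerical choices and known
limitations behind `ecoassembly`, in the order data flows through the
pipeline.

## Inputs and preparation

The pipeline consumes a rooted Newick phylogeny with branch lengths on all
edges, a sample × OTU integer count table (TSV or BIOM 1.0 JSON; the caller
must state the orientation — auto-detection is refused because both
orientations occur in the wild), and per-sample metadata with decimal
coordinates and environmental variables. Replicates are pooled by summing
counts per site key before analysis; site-level communities are the default
unit (ten per group in the motivating design, giving C(10,2) = 45 pairs per
group). OTUs missing from the tree are a hard error unless pruning is
requested explicitly — silent intersection hides data bugs.

Rarefaction draws an exact multivariate hypergeometric sample per row
(subsampling reads without replacement), so zero cells stay zero, retained
rows sum exactly to the target depth, and samples below depth are dropped
with a warning. Counts stay integers throughout; relative abundances
f<sub>ik</sub> are derived lazily and never stored rounded, so the null
models see exactly the data the observed statistics saw. Geographic
distances are haversine great circles on a spherical Earth of radius
6371 km.

## Observed metrics

Patristic distances are tip-to-tip path sums, computed once per tree and
cached as a labeled matrix; null models permute labels, never the matrix
contents. MNTD and βMNTD default to abundance weighting. βMNTD follows
`picante::comdistnt` semantics: an OTU shared by both communities has
cross-community nearest-neighbour distance 0. A singleton community has no
nearest taxon; MNTD raises a typed error and callers record a missing value
(returning 0 would fake maximal clustering). Deterministic observables are
tested against naive double-loop oracles (to 1e−12) and against
picante/vegan via Rscript on small fixtures.

## Null models and effect sizes

NTI and βNTI shuffle OTU labels across the whole patristic matrix
(the `taxa.labels` scheme), preserving composition and abundances; the
matrix is first restricted to the OTUs actually present in the group, which
defines the regional pool. Each community pair gets an independent null and
an independent deterministic sub-seed derived from the master seed via
`SeedSequence` spawn keys, so results do not depend on evaluation order.
Defaults are 999 randomizations; z-scores use the sample standard deviation
of the null. A zero-spread null yields a missing value — never ±∞ — except
in the exactly degenerate case where the observation equals the null point
(identical communities: βMNTD = 0 observed and in every replicate), which
yields 0; this keeps identical pairs classifiable by RC<sub>bray</sub>
instead of dropping them. On trees small enough to enumerate, both indices
can be computed against the exhaustive relabeling null (population SD), and
the sampled versions are verified against it.

RC<sub>bray</sub> reassembles each community of a pair per replicate:
observed richness drawn without replacement with probability ∝ occupancy
(implemented as Gumbel top-k, which is exactly sequential
probability-proportional-to-weight sampling), one founding read per member,
and the remaining reads multinomial ∝ regional relative abundance. The
observed Bray–Curtis is mid-rank scored against the null sample (ties count
half) and rescaled to [−1, 1]. The regional pool is the group itself, not
the union of groups, because each size-fraction group is analyzed
separately. Calibration is verified by feeding the null's own draws back in
as observations (mean RC ≈ 0, few |RC| > 0.95).

Classification uses strict inequalities as printed in the decision rules
(values exactly at ±2 or ±0.95 fall in the less-extreme class — a
measure-zero choice in practice). Pairs whose βNTI is missing are reported
as unclassified and excluded from fraction denominators with a warning.

## Phylogenetic signal

The correlogram relates between-OTU Bray–Curtis profile distances to
between-OTU phylogenetic distances in equal-frequency (quantile) distance
classes (default 10; the binning is not prescribed by the framework, and
equal-frequency bins keep per-class power comparable). The per-class Mantel
statistic is the negated Pearson correlation with the class indicator, so a
positive value means within-class ecological similarity; p-values come from
simultaneous row/column permutations of the ecological matrix (two-sided),
with progressive Holm correction along increasing distance — the shortest
class is uncorrected. Classes with fewer than three pairs are flagged and
not tested. The profile-based test is more conservative than niche-value
approaches: absence of signal here does not prove absence of signal, which
is why the βNTI gate can be overridden deliberately.

## Co-structure

Co-inertia analysis decomposes the cross-covariance of two column-centered,
sample-matched tables by SVD; eigenvalues are squared singular values, and
sample scores are projections on the co-inertia axes. Global association is
the RV coefficient (trace formula), tested by Monte-Carlo row permutation of
one table with p = (#{RV<sub>perm</sub> ≥ RV<sub>obs</sub>} + 1)/(n + 1) so
p is never 0. Abundance tables are Hellinger-transformed (square root of
relative abundances) before ordination by default — standard practice for
linear ordination of counts; raw and log1p modes are available, and the
rotation-invariance identities hold in raw mode. RV and per-axis score
correlations are reported separately; the package takes no position on how
a single R² should be derived from a COIA.

## Synthetic communities

The generator's purpose is ground truth: communities whose generating
process is known, at sizes a laptop can verify (defaults: 10 sites, pool of
100 taxa per group, reads drawn multinomially at depths of a few hundred;
the `lake-survey` fixture reproduces the motivating design's shape — three
groups with pool richness 834/99/102 and depths 32029/13975/16313).

Phylogenies come from a crown-conditioned forward birth–death simulation
(restarting on extinction, stopping when the target tip count is reached and
the next event would be a birth, so pure-birth crown depth has expectation
Σ<sub>k=2..n</sub> 1/k). Continuous traits evolve by Brownian motion.

Niche structure is punctuated rather than purely Brownian. Development
versions filtered a Brownian tip trait through a Gaussian niche and could
not recover selection regimes at desk scale: under Brownian motion every
clade contains lineages near any given trait value (convergence), so
trait-window communities are phylogenetically scattered and NTI/βNTI — which
have limited statistical power at pools of ~100 taxa — stay near 0
regardless of filter strength. Instead, habitat affinity is conserved within
*niche blocks* — the maximal clades whose crown age is ≤ `block_depth_frac`
(default 0.25) of tree depth — with iid uniform affinities per block plus a
small Brownian jitter (`niche_jitter`, default 0.05). A site admits the
`window_frac` (default 0.3) of the pool closest in affinity to its optimum —
a hard quantile window, because a soft Gaussian filter's tails are
overwhelmed by lognormal abundance noise — and an establishment lottery
keeps each admitted taxon with probability `establishment` while never
leaving an admitted block empty (a competitive lottery: the niche is always
filled by some member). This combination produces exactly the turnover
structure the indices were designed to detect: sites retain the same tight
clades while swapping which close relatives represent them.

Regime parameterizations (site weights multiply a lognormal regional SAD;
reads are multinomial at the configured depth):

- **homogeneous_selection** — identical optima, establishment 0.5; turnover
  is within-clade only, βNTI ≪ 0.
- **variable_selection** — optima linspace(−1, 1) across sites,
  establishment 0.8; gradient ends admit divergent clades, βNTI ≫ 0.
- **dispersal_limitation** — no selection; taxa have uniform home sites and
  an exponential kernel exp(−distance/λ), λ = −1/log(dispersal_rate)
  (default rate 0.2), SAD σ = 1, depth 1000; RC → +1 while βNTI stays
  central.
- **homogenizing_dispersal** — no selection; mass effects: a fraction
  `dispersal_rate` (default 0.95) of every site's reads is a single shared
  realized metacommunity draw. Independent sampling from a merely *shared
  expected* composition is indistinguishable from drift under the RC null
  (RC ≈ 0); only realized-level sharing drives RC → −1.
- **drift** — no selection, well mixed, low depth (500): independent
  multinomial sampling, neither index deviates far from null.

All sites also receive a small uniform stream of transient immigrant reads
(`immigration`, default 2% of depth). Without it a strongly selected
metacommunity contains only the favoured clades, the tip-shuffle null is
confined to them, and homogeneous selection becomes structurally
undetectable; transients keep the realized pool broad while contributing
negligible abundance. Selection regimes default to a flatter SAD (σ = 0.3)
than the neutral regimes (σ = 1): strong selection compresses realized
fitness differences, and σ = 1 abundance noise would drown the niche filter.
Mixture regimes blend these mechanisms proportionally to their weights; the
blend is a heuristic convenience for exploration, not a calibrated model.
Optional trophic coupling re-weights a group's reads by the site abundance
of randomly linked taxa in the first group, producing COIA co-structure.

Everything is driven by one integer seed through `SeedSequence` spawn
trees: same seed, same output, byte for byte.

### What the generator does and does not emulate

It emulates phylogenetically conserved habitat filtering, environmental
gradients, distance-limited and mass-effect dispersal, sampling drift,
skewed abundance distributions, rarefaction-scale read sampling, and
predator–prey co-structure. It does not emulate sequencing artifacts
(chimeras, clustering errors), temporal dynamics, interaction networks
beyond pairwise trophic links, or multiple interacting environmental axes.
Passing regime recovery therefore shows the inference chain is correct and
well calibrated under its own assumptions at desk scale — not that real
communities of any particular system are dominated by these processes, nor
that effect sizes at pools of thousands of taxa match those at 100.

## Verification problem sizes

The verification experiments (`ecoassembly.validation`, mirrored by
`scripts/acceptance.py` and the acceptance tests) use sizes chosen to keep
the full suite within a coffee break on one CPU: 999-replicate nulls against
exhaustive enumeration on 5–6-tip trees over 20 seeds; 200 self-null
RC pairs and 100 tip-shuffled βNTI trials at 199 replicates; regime recovery
over 10 master seeds per scenario at 199 replicates, 10 sites and pool
richness 100; 50 detection and 200 type-I correlogram runs at 199
permutations. Verified deterministic quantities hold to 1e−12.

## Known limitations

- βNTI has limited power for *homogeneous* selection at small pools; it sees
  membership turnover only (an OTU present in both communities contributes
  distance 0 regardless of abundance shifts), so dominance rearrangements
  among shared taxa are invisible to it.
- The RC null conditions on observed richness and total reads; communities
  with extreme richness relative to the pool make the membership draw
  infeasible or degenerate.
- The correlogram's quantile binning makes class boundaries data-dependent;
  tied distances can merge classes (logged).
- The CLI holds entire tables in memory; it targets OTU tables of typical
  amplicon-survey size, not shotgun-scale feature tables.
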