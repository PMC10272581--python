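# ecoassembly

Null-model inference of microbial community assembly processes.

Microbial communities are shaped by a mix of deterministic selection and
stochastic processes (dispersal and drift). Given a rooted phylogeny of OTUs,
a sample × OTU count table, and per-site metadata, `ecoassembly` quantifies
the relative influence of five processes — **variable selection, homogeneous
selection, dispersal limitation, homogenizing dispersal, and an undominated
remainder** — on community turnover, following the phylogenetic null-model
framework widely used for size-fractionated lake and other microbiome
surveys. A synthetic-community generator with known assembly regimes makes
the whole chain verifiable against ground truth.

## The statistics

For a community *k* with relative abundances *f<sub>ik</sub>* and patristic
distances Δ, the abundance-weighted mean nearest taxon distance is

MNTD = Σ<sub>i∈k</sub> f<sub>ik</sub> · min<sub>j≠i, j∈k</sub> Δ<sub>ij</sub>

and the **nearest taxon index** standardizes it against a null in which OTU
labels are shuffled across the tips of the tree (999 randomizations):

NTI = −(MNTD<sub>obs</sub> − mean MNTD<sub>null</sub>) / sd(MNTD<sub>null</sub>)

NTI > +2 indicates phylogenetic clustering, NTI < −2 overdispersion. The
between-community analogue βMNTD (computed with `comdistnt` semantics:
shared OTUs contribute distance 0) gives **βNTI**, with a separate null per
community pair. **RC<sub>bray</sub>** ranks the observed Bray–Curtis
dissimilarity of a pair within a null that probabilistically reassembles
both communities from the regional species pool (membership ∝ occupancy,
abundance ∝ regional relative abundance), rescaled to [−1, +1].

Each pair is then classified:

| condition | process |
|---|---|
| βNTI > +2 | variable selection |
| βNTI < −2 | homogeneous selection |
| \|βNTI\| < 2, RC<sub>bray</sub> > +0.95 | dispersal limitation |
| \|βNTI\| < 2, RC<sub>bray</sub> < −0.95 | homogenizing dispersal |
| \|βNTI\| < 2, \|RC<sub>bray</sub>\| < 0.95 | undominated |

Per community or group, the relative influence of each process is the
fraction of its pairwise comparisons in that class.

Interpreting βNTI as selection requires **phylogenetic signal** — close
relatives must be ecologically similar. The package tests this with a Mantel
correlogram relating between-OTU Bray–Curtis profile distances to between-OTU
phylogenetic distances, and refuses (overridably) to run turnover inference
without a significant positive short-distance class. Co-structure between
paired group tables (e.g., prokaryotes vs. micro-eukaryotes) is measured by
co-inertia analysis with the RV coefficient and a Monte-Carlo row-permutation
test; distance decay against great-circle geographic distance uses a Mantel
test.

## Worked example

Simulate ten site communities assembled under variable selection along an
environmental gradient, then run the full inference chain:

```python
import ecoassembly as ea
from ecoassembly.io import prune_to_shared_taxa
from ecoassembly.nullmodels import nti_table, pairwise_turnover
from ecoassembly.inference import process_fractions, nti_summary

ds = ea.simulate_dataset(ea.scenario_fixture("variable_selection", seed=42))
table, dist = prune_to_shared_taxa(
    ds.tables["g1"], ea.patristic_distances(ds.trees["g1"])
)

nti = nti_table(table, dist, reps=199, seed=0)
print(nti_summary(nti["nti"]))

pairs = pairwise_turnover(table, dist, reps=199, seed=0)
print(process_fractions(pairs, by="group").round(3))
```

Output:

```
{'n': 10, 'mean': 2.19, 'median': 1.97, 'sd': 0.67, 'frac_clustered': 0.4,
 'frac_significant': 0.4, 't_statistic': 10.41, 't_pvalue': 0.0}
     variable_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated  n_comparisons
all               0.533                    0.0                 0.156                   0.156        0.156           45.0
```

Mean NTI of +2.19 (significantly above zero) says coexisting taxa within
each site are more closely related than chance — communities are assembled
by selection. Of the 45 between-site comparisons, 53% have βNTI > +2:
variable selection along the gradient dominates turnover, exactly the regime
the generator imposed.

The same pipeline is available from the shell:

```bash
ecoassembly simulate --scenario variable_selection --seed 42 --out demo/
ecoassembly turnover --tree demo/g1.nwk --table demo/g1_counts.tsv \
    --rows-are samples --reps 999 --seed 0 --out demo/pairs.tsv
ecoassembly processes --turnover demo/pairs.tsv --by group --out demo/fractions.tsv
```

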