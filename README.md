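# fluvimyco

Statistical analysis of river-transect mycoplankton (planktonic fungi)
surveys: phylogeny-aware β-diversity and ordination, spatial-vs-
environmental variance decomposition, and null-model inference of the
ecological processes that assemble communities along an estuarine
salinity gradient.

The package is aimed at microbial ecologists holding the classic trio of
amplicon inputs — an OTU count table (samples × OTUs), a rooted
phylogeny over the OTUs, and a per-sample environmental table with an
along-channel coordinate — who want the full downstream stack as tested,
reusable Python, together with a synthetic community generator that
provides ground truth for every inference step.

## The statistics at the core

**Generalized UniFrac.** For communities *k*, *m* with branch-subtended
proportions *p<sub>b</sub>*, *q<sub>b</sub>* and branch lengths
*L<sub>b</sub>*,

d<sub>α</sub>(k,m) = Σ<sub>b</sub> L<sub>b</sub>(p<sub>b</sub>+q<sub>b</sub>)<sup>α</sup> |p<sub>b</sub>−q<sub>b</sub>|/(p<sub>b</sub>+q<sub>b</sub>) ÷ Σ<sub>b</sub> L<sub>b</sub>(p<sub>b</sub>+q<sub>b</sub>)<sup>α</sup>

with α = 0.5 by default. It feeds PCoA ordination, PERMANOVA
(pseudo-F with whole-row label permutation), distance-decay regression
and distance-based RDA.

**Quantitative process estimates (QPE).** The abundance-weighted β-mean
nearest taxon distance

βMNTD(k,m) = ½ [ Σ<sub>i∈k</sub> f<sub>ik</sub> min<sub>j∈m</sub> d<sub>ij</sub> + Σ<sub>j∈m</sub> f<sub>jm</sub> min<sub>i∈k</sub> d<sub>ij</sub> ]

is standardized against a null that reshuffles OTUs across the tree's
tips, giving βNTI = (βMNTD<sub>obs</sub> − mean null)/sd null. βNTI > 2
labels a pair *variable selection*, βNTI < −2 *homogenizing selection*.
Remaining pairs are split by the Raup–Crick standardized Bray–Curtis
deviation βRC<sub>bray</sub> ∈ [−1, 1]: > 0.95 *dispersal limitation*,
< −0.95 *homogenizing dispersal*, otherwise *undominated* (e.g.
ecological drift).

**Space vs environment.** Distance-based Moran's eigenvector maps
(dbMEM) of the 1-D transect supply orthogonal spatial predictors;
forward selection with a double stopping rule keeps the significant
ones; variation partitioning reports unique environmental [a], shared
[b], unique spatial [c] and unexplained [d] adjusted-R² fractions with
a+b+c+d = 1.

Also included: Hellinger and z-score transforms, Chao1 / Shannon /
Faith's PD with Tukey HSD group tests, analytic rarefaction,
Spearman-FDR collinearity screening, k-means + SIMPROF environmental
clustering, PSU water-type assignment (fresh < 0.5, brackish 0.5–30,
marine > 30) and basal-lineage frequency tests.

## Worked example

Simulate a 24-station, 200-OTU transect under strong niche selection and
ask which assembly process the null models recover:

```python
import fluvimyco as fm
from fluvimyco.beta import gunifrac, pcoa, permanova
from fluvimyco.diversity import water_types
from fluvimyco.qpe import run_qpe

table, tree, env, _ = fm.simulate_dataset("variable_selection", seed=1)
d = gunifrac(table, tree, alpha=0.5)
res = permanova(d, water_types(env), n_perm=999, seed=0)
print(f"PERMANOVA: F = {res.pseudo_f:.2f}, R2 = {res.r_squared:.2f}, "
      f"p = {res.p_value:.4f}")
qr = run_qpe(table, tree, groups=water_types(env), n_null=999, seed=0)
print((qr.labels["process"].value_counts(normalize=True) * 100).round(1))
```

prints

```
PERMANOVA: F = 3.76, R2 = 0.26, p = 0.0040
process
variable_selection        73.9
homogenizing_dispersal    17.8
undominated                5.4
homogenizing_selection     2.9
```

The water types hold significantly distinct communities (p = 0.004),
and 73.9% of sample pairs are classified as variable selection — the
process the generator actually used. The homogenizing-dispersal
fraction comes from neighbouring sites whose nearly identical
environments select nearly identical communities. The `examples/`
directory walks through each capability the same way; the
`fluvimyco` CLI (`simulate`, `alpha`, `beta`, `spatial`, `qpe`,
`watertypes`, `run-all`) exposes the pipeline for shell use, e.g.

```bash
fluvimyco run-all --otu-table fixtures/drift/otu_table.tsv \
    --tree fixtures/drift/tree.nwk --env-table fixtures/drift/env_table.tsv \
    --outdir results/ --seed 42
```

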