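# svhic

Structural-variant-aware capture Hi-C contact analysis: did a deletion change
chromatin architecture beyond the trivial effect of shortening the chromosome?

`svhic` is aimed at groups studying TAD (topologically associating domain)
boundary perturbations — for example CRISPR deletions of CTCF-clustered
boundary elements in mouse loci such as the *Pdgfra*/*Kit*/*Kdr* receptor
tyrosine kinase cluster — who compare capture Hi-C maps of wild-type and
mutant alleles and allele-specific expression in F1 hybrid crosses.

## What it computes

**The distance-only null.** A deletion moves loci closer together, so
contacts change even if folding is otherwise untouched. `svhic` builds that
null explicitly: the wild-type map is lifted onto the deleted genome under a
*balanced* model that rescales every contact by the ratio of the map's own
distance decay at the new versus old separation,

    V*(i', j') = V(i, j) · P(s') / P(s),        P(s) = mean contact at bin separation s,

then lifted back to reference coordinates under an *easy* (coordinate-only)
model. The result V\* is what the mutant map should look like if the deletion
acted purely through genomic distance.

**Differential contact enrichment.** Observed mutant map V and null V\* are
compared per position k with a window of f bins on each side:

    D(k, f) = mean log( V_ij / V*_ij )    over  i ∈ [k−f, k),  j ∈ (k, k+f],  V_ij ≠ 0, V*_ij ≠ 0,

after scaling both maps to equal totals over jointly positive pairs. D is
Z-transformed across positions; runs of |Z| above a threshold become
insulation-change calls (gain = boundary fusion, loss = new insulation).
Subtraction maps (depth-matched observed − null, coarse-binned) accompany the
track for visualization.

**Allele-specific expression.** Per SNP in a *M. musculus* × *M. castaneus*
hybrid, allelic activity is the pseudocount ratio
(musculus reads + 1)/(castaneus reads + 1); genes are summarized as
mean ± SD across SNPs and genotypes are compared with a two-tailed
Mann–Whitney U test (exact for small samples without ties). A ratio r
converts to a musculus-allele fraction r/(1+r).

**Synthetic locus generator.** A Poisson TAD block model over a power-law
decay — three TADs across a 2.275 Mb / 455-bin capture region with nested
sub-TADs, configurable boundary insulation δ, loops, and depth — generates
wild-type/mutant experiment pairs and SNP coverage tables for validation and
power analysis.

## Worked example

```python
import pandas as pd
from svhic import (default_experiment, run_simulated_experiment,
                   simulate_snp_counts, compare_alleles, allele_fraction)

# simulate a 30 kb boundary deletion that fuses two TADs, then analyze it
res = run_simulated_experiment(default_experiment(fused=True, seed=7))
for c in res.calls:
    print(f"{c.chrom}:{c.start}-{c.end}  {c.sign}  peak Z = {c.peak_z:.2f}")
```

```
chr5:1445000-1555000  gain  peak Z = 5.28
```

One broad (110 kb) gain of cross-boundary contacts, overlapping the deleted
boundary (bin 300, position 1.5 Mb): the two TADs have fused. Rerunning with
`fused=False` (the deletion spares the boundary's function) leaves only
narrow |Z| ≈ 2 noise excursions — no call at the boundary reaches |Z| ≥ 3.

```python
table = pd.concat([
    simulate_snp_counts("Kdr", n_snps=21, coverage_per_snp=100,
                        true_ratio=1.0, seed=14, genotype="Wt"),
    simulate_snp_counts("Kdr", n_snps=21, coverage_per_snp=100,
                        true_ratio=49.71, seed=15, genotype="mutant"),
])
r = compare_alleles(table, "Kdr", ("Wt", "mutant"))
print(f"Wt {r.means[0]:.2f}±{r.sds[0]:.2f}  mutant {r.means[1]:.2f}±{r.sds[1]:.2f}  "
      f"U={r.u_statistic:.0f}  p={r.p_value:.2e}")
print(f"mutant musculus-allele share: {100 * allele_fraction(r.means[1]):.1f}%")
```

```
Wt 1.05±0.22  mutant 39.56±23.75  U=0  p=2.81e-08
mutant musculus-allele share: 97.5%
```

The mutant expresses *Kdr* almost exclusively from the musculus allele
(a measured ratio of 49.71 corresponds to a 98% allele share:
`allele_fraction(49.71) = 0.9803`).

The same stages are available from the shell via the `svhic` console script
(`simulate`, `normalize`, `expected`, `liftover`, `simulate-null`,
`subtract`, `dscore`, `allelic`, `simulate-snps`); every command writes a
JSON manifest with parameters and input checksums.

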