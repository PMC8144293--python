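# coresweep

Core gut microbiomes are usually defined by a prevalence threshold: keep the
ASVs (amplicon sequence variants) detected in at least *t* of the sampled
hosts, discard the rest. Thresholds in the literature range from 10% to 90%,
and the choice changes every downstream diversity number. `coresweep` asks,
for a sample-by-ASV count table and a rooted phylogeny, *which alpha and
beta diversity measures survive that choice* — and quantifies the
macroecological structure (occupancy–abundance relationships, rare-taxon
accumulation, richness extrapolation) that determines the answer.

It is written for microbial ecologists comparing core-microbiome results
across host species or studies, and ships a calibrated synthetic-data
generator so the whole analysis runs end to end without downloading any
sequencing project.

## The measures and the sweep

Eight diversity measures spanning the abundance/phylogeny weighting grid:

| | not weighted | phylogeny | abundance | both |
|---|---|---|---|---|
| **alpha** | observed richness | Faith's PD | Shannon *H* | BWPD |
| **beta** | Jaccard | unweighted UniFrac | Morisita | weighted UniFrac |

All phylogenetic measures are functions of the *edge mass* p_e — the total
relative abundance of the taxa below edge *e* of the rooted tree — computed
in one post-order pass:

- Faith's PD = Σ_e l_e · 1[p_e > 0]
- BWPD_θ = Σ_e l_e · (2 · min(p_e, 1 − p_e))^θ, default θ = 0.5
- unweighted UniFrac = Σ_{XOR} l_e / Σ_{OR} l_e over the two edge-presence sets
- weighted UniFrac = Σ_e l_e |p_e^x − p_e^y| / Σ_e l_e (p_e^x + p_e^y)

plus Shannon H = −Σ_j p_j ln p_j, Morisita dissimilarity
1 − 2Σx_j y_j / ((λ_x+λ_y) X Y) on integer counts, Jaccard and Bray–Curtis.

The sweep rarefies each dataset to 10,000 reads, filters the rarefied table
at prevalence thresholds 0, 0.1, …, 0.9 (inclusive boundary), scores every
measure at every threshold (mean per-sample dissimilarity for the beta
measures), z-standardizes per dataset and metric, and then tests what
filtering did: Bartlett's test for variance change across thresholds,
Spearman correlation of filtered vs unfiltered per-sample scores, and a
read-depth bias check.

The macroecology module provides exact (log-space hypergeometric)
rarefaction and sample-accumulation expectations, their permutation
counterparts, and the first-order jackknife pool estimate
S_jack1 = S_obs + f₁(n−1)/n.

## Worked example

Generate the eight-dataset synthetic study (six cohesive hosts, two with
highly individualized microbiomes), then sweep and rank the measures:

```bash
python analysis/01_simulate.py --seed 1 --out-dir results/data
python analysis/02_macroecology.py --data-dir results/data --out-dir results/macroecology
python analysis/03_prevalence_sweep.py --data-dir results/data --out-dir results/sweep
python analysis/04_filtering_sensitivity.py --sweep-dir results/sweep --out-dir results/sensitivity
```

The final step prints (seed 1):

```
alpha sensitivity, |mean z change| t=0 -> 0.6 (least sensitive first):
  shannon              1.230
  bwpd                 1.554
  faith_pd             2.275
  richness             2.472
beta sensitivity, |mean dissimilarity change| t=0 -> 0.6:
  morisita             0.020
  weighted-unifrac     0.107
  unweighted-unifrac   0.169
  jaccard              0.277
mean filtered-vs-unfiltered Spearman rho by threshold:
  t=0.1: 0.954
  t=0.2: 0.938
  t=0.3: 0.907
  t=0.4: 0.852
  t=0.5: 0.747
  t=0.6: 0.563
  t=0.7: 0.356
  t=0.8: 0.107
```

Reading: presence-weighted measures (richness, Faith's PD, Jaccard,
unweighted UniFrac) are dragged hard by the threshold, because filtering
removes exactly what they count — rare taxa and their branches. The
abundance-weighted measures barely move. And past a ~50–60% threshold,
per-sample scores stop correlating with the unfiltered data (rho falls from
0.95 to 0.1), i.e. harsh filtering re-ranks individuals: results obtained
under different high thresholds are not comparable. See
`docs/methods.md` for what the synthetic generator does and does not imply
about real data — in particular why Shannon and Morisita come out *flatter*
here than in field datasets.

Everything is seeded; rerunning any command with the same seed reproduces
every output byte for byte. The same pipeline runs on real data via the CLI:

```bash
coresweep sweep --table table.tsv --tree tree.nwk --metadata metadata.tsv \
    --out-dir results/sweep --seed 11
```

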