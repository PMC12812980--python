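# trophonet

Trophic state assessment and plankton–bacteria co-occurrence network
analysis along eutrophication gradients.

`trophonet` is for freshwater ecologists and microbial ecologists who have
per-site water chemistry and taxa-by-sample abundance tables (microscopy
cell densities for phytoplankton, 16S ASV read counts for bacteria) and
want a reproducible pipeline from raw tables to (1) composite Trophic
State Index scores and trophic classes, (2) alpha/beta diversity, (3)
environment–community permutation tests, and (4) signed cross-kingdom
co-occurrence networks with topology metrics per trophic group. A
synthetic gradient generator with an exact planted truth makes every stage
testable end to end without field data.

## The statistics at the core

**Trophic State Index.** Each site is scored with a modified Carlson TSI
on four measurements (natural logarithms):

    TSI(Chl-a) = 10 (2.5   + 1.086 ln Chl-a)      Chl-a in μg/L
    TSI(TP)    = 10 (9.436 + 1.624 ln TP)         TP in mg/L
    TSI(TN)    = 10 (5.453 + 1.694 ln TN)         TN in mg/L
    TSI(SD)    = 10 (5.118 − 1.94  ln SD)         Secchi depth in m

    TSI = 0.326 TSI(Chl-a) + 0.219 TSI(TN) + 0.230 TSI(TP) + 0.225 TSI(SD)

Classes: TSI < 30 oligotrophic; 30 ≤ TSI ≤ 50 mesotrophic; 50 < TSI ≤ 60
slightly eutrophic; 60 < TSI ≤ 70 moderately eutrophic; TSI > 70
hyper-eutrophic. "Eutrophic" means TSI > 50.

**Diversity.** Shannon H = −Σ pᵢ ln pᵢ and richness S per sample, with
bacterial tables rarefied (seeded, without replacement) to a common read
depth (default 27,000) first; Bray–Curtis dissimilarity
d(x,y) = 1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ) between samples.

**Association tests.** Tie-aware Spearman correlation over all taxon pairs
with Benjamini–Hochberg FDR across the full pair family; Mantel and
partial Mantel permutation tests on distance matrices (one-tailed, add-one
p-value, default 999 permutations); a distance-based permutation
correlation between single environmental variables and community
distances.

**Co-occurrence networks.** Per trophic group (L/M/H), taxa passing a
0.01% overall relative-abundance filter (per kingdom) are correlated on
per-kingdom relative abundances; an edge is kept when |ρ| ≥ 0.6 **and**
BH-adjusted p < 0.05, signed by the sign of ρ. Topology follows the Gephi
conventions: unsigned simple graph; diameter and average path length on
the largest component; mean local clustering; modularity by Louvain with
seeded restarts (exact partition search on very small graphs); signed edge
percentages and bacteria–bacteria / phytoplankton–phytoplankton /
cross-kingdom edge composition.

## Worked example

The `analysis/` scripts run the whole study on the synthetic gradient
(30 sites per trophic group, planted correlation blocks):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_trophic_assessment.py
python analysis/03_diversity.py
python analysis/04_environment_associations.py
python analysis/05_networks.py
```

`02_trophic_assessment.py` prints:

```
assessed 90 sites
composite TSI: median 55.53, mean 52.97 ± 10.99, range [30.3, 69.1]
eutrophic (TSI > 50): 65.6% of sites
  mesotrophic: 31
  slightly_eutrophic: 30
  moderately_eutrophic: 29
```

i.e. the noisy back-solved chemistry reproduces the generator's target
classes almost exactly (one L-group site drifted across the 50 boundary).
`03_diversity.py` shows bacterial Shannon diversity declining
monotonically with trophic state (3.890 → 3.763 → 3.668 nats), and
`05_networks.py` prints the per-group topology bundle:

```
group  nodes  edges  avg_deg  diam  clust  modularity  pos%   neg%
  L      100    133     2.66     1  0.375       0.765   98.5    1.5
  M      100    221     4.42     3  0.327       0.547   81.4   18.6
  H      100    578    11.56     4  0.338       0.077   75.4   24.6
modularity trend L→M→H: decreasing; negative-edge share: increasing
planted-edge recovery vs generator truth:
  L: recall 1.00, spurious rate 0.0004, sign accuracy 1.00
  M: recall 1.00, spurious rate 0.0002, sign accuracy 1.00
  H: recall 1.00, spurious rate 0.0007, sign accuracy 1.00
```

Rising trophic state dissolves module boundaries (modularity 0.765 →
0.077) and flips cross-kingdom associations negative (1.5% → 24.6%),
while the double edge gate keeps the false-edge rate three orders of
magnitude below the planted-edge recall — the qualitative behaviour the
pipeline is designed to detect.

There is also a CLI for the individual stages:

```bash
trophonet tsi --in chemistry.csv --out report.json
trophonet simulate --seed 7 --out dataset/
trophonet run --scenario dataset/scenario.yaml --seed 7 --out results/
```

## Layout

- `src/trophonet/` — the library: `trophic` (TSI), `community` (tables,
  diversity, rarefaction, Bray–Curtis), `stats` (Spearman/BH/Mantel),
  `network` (construction, topology, trends), `simulate` (gradient
  generator + truth scoring), `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers reproducing the study flow.
- `tests/` — pytest suite with oracle cross-checks and acceptance tests.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
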