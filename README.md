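# ffnet

Microbiota–volatile association networks for fermented-food time series.

Traditional fermented vegetables acquire their flavor over multi-year
spontaneous fermentations, and the volatile compounds that define that flavor
track the succession of the microbial community. A common study design samples
the same batch at a handful of timepoints (e.g. 0, 1, 2 and 3 years), profiles
the community by DGGE band intensities (or amplicon abundances) and the
volatiles by HS-SPME-GC–MS peak areas, and then asks which microbes drive
which flavor compounds. `ffnet` implements that analysis end to end for
microbiome/flavor researchers:

* **Normalization** — band intensities and peak areas are closed per sample:
  `p_i = x_i / Σ_j x_j`, so each sample is a composition summing to 1.
* **Diversity** — per sample, Shannon–Wiener `H = −Σ p_i ln p_i` (nats),
  Pielou evenness `E = H / ln S`, and richness `S` (detected features).
* **Ordination** — PCA of sample profiles (unit-variance or center-only
  scaling) with explained-variance fractions, plus average-linkage
  hierarchical clustering of samples.
* **Association networks** — all microbe–volatile (bipartite) or
  microbe–microbe (co-occurrence/co-exclusion) pairs are scored with the
  tie-aware Spearman rank correlation ρ; an edge is kept when |ρ| > 0.6
  (strict) **and** the two-sided p-value < 0.05 (strict). Networks can be
  split by sign, mined for hubs (degree ≥ 10), and summarized as within- vs
  cross-phylum co-occurrence incidence. Both an asymptotic-t and an exact
  permutation p-value are available (see `docs/methods.md` for why the
  asymptotic convention is the default on short series).
* **Core flavor-contributing microbes** — a three-criterion rule: detected in
  every sample, at least one strong correlation (|ρ| > 0.6), and connected to
  strictly more than 35 volatiles in the significant bipartite network.
* **Synthetic data** — a generator that emits compositional microbe/volatile
  tables over a fermentation time axis with *planted*, signed, monotone
  microbe→volatile couplings and guarantees that the planted edge set is
  exactly recoverable in the noise-free limit. Every pipeline stage is
  testable against this ground truth without any study's raw data.

## Worked example

```python
from ffnet import (SimConfig, simulate_dataset, build_bipartite, split_by_sign,
                   diversity_table, pca, classify_core)

cfg = SimConfig(n_timepoints=8, n_microbes=20, n_volatiles=50,
                n_coupled_pairs=30, noise_sd=0.25, seed=42)
ds = simulate_dataset(cfg)

net = build_bipartite(ds.microbe_table, ds.volatile_table)
pos, neg = split_by_sign(net)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges "
      f"({pos.n_edges} positive, {neg.n_edges} negative)")

truth = {tuple(sorted((m, v))) for m, v, _ in ds.truth_edges}
print(f"planted couplings recovered: {len(net.edge_pairs() & truth)}/{len(truth)}")

print(diversity_table(ds.microbe_table).round(2).head(3))
res = pca(ds.microbe_table)
print(f"PC1 {100*res.explained_fraction[0]:.1f}%, PC2 {100*res.explained_fraction[1]:.1f}%")
```

prints

```
network: 48 nodes, 40 edges (18 positive, 22 negative)
planted couplings recovered: 30/30
           H     E   S
sample
T0      2.50  0.81  22
T1      1.75  0.56  22
T2      1.37  0.44  22
PC1 25.3%, PC2 17.9%
```

All 30 planted couplings are among the 40 retained edges (the extra 10 are
noise-induced at `noise_sd=0.25`; at `noise_sd=0` the retained set equals the
planted set exactly). Diversity falls over the fermentation as a few taxa take
over (H drops from 2.50 to 1.37 nats while richness S stays at 22, so evenness
drops too), and the first two components separate the succession stages.

The same operations are exposed on the command line:

```bash
ffnet simulate --out demo/ --seed 42 --timepoints 8
ffnet diversity demo/microbes.csv
ffnet network --mode bipartite --microbes demo/microbes.csv \
      --volatiles demo/volatiles.csv --annotations demo/annotations.csv \
      --out demo/net.graphml
ffnet core --microbes demo/microbes.csv --volatiles demo/volatiles.csv \
      --min-connections 2
```

Networks are written as GraphML/GEXF and open directly in Gephi.

## Layout

```
src/ffnet/
  tabular_io.py           table/annotation/network/report formats
  abundance.py            closure normalization, aggregation, detection
  diversity.py            Shannon-Wiener H, Pielou E, richness S
  ordination.py           PCA + hierarchical clustering
  association_network.py  Spearman statistics, thresholded networks,
                          hubs, phylum incidence
  core_classifier.py      three-criterion core-microbe rule
  synthetic_data.py       planted-coupling generator
  cli.py                  `ffnet` command group
docs/methods.md           model, assumptions, parameter choices, limitations
```
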