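# Methods

## Scope and data model

`ffnet` analyses feature-by-sample abundance tables from time-course surveys
of fermenting foods. Two feature roles exist: *microbes* (DGGE bands or
amplicon features, annotated with species/genus/phylum) and *volatiles*
(GC–MS compounds, annotated with one of nine chemical categories:
hydrocarbons, esters, ketones, sulfides, alcohols, aldehydes, aromatic
compounds, acids, heterocyclic compounds — a closed vocabulary). Samples are
ordered columns; column order is fermentation-time order. Tables are either
`raw` (nonnegative intensities/areas) or `relative` (each sample column sums
to 1). Readers validate; they never silently renormalize (tolerance 1e-6 on
column sums).

## Normalization and aggregation

Relative abundance is per-sample closure: `p_i = x_i / Σ_j x_j`, the standard
peak-area-normalization for GC–MS tables and relative band intensity for
DGGE lanes. Closure fails loudly on an all-zero sample. `aggregate` sums
member features per group (chemical category, or phylum/genus/species taken
verbatim from the annotation table — no external taxonomy service); when the
grouping partitions the features the per-sample sums are conserved exactly.
Detection uses a configurable threshold `detection_epsilon` (default 0: any
positive value counts as detected, since published compound counts appear to
use no trace cutoff; GC–MS tables with trace noise can raise it).

## Diversity

Per sample: `H = −Σ_{p_i>0} p_i ln p_i` (nats, with 0·ln 0 := 0),
richness `S` = number of detected features, and Pielou evenness
`E = H / ln S` for `S ≥ 2` (for `S = 1` evenness is undefined and reported
missing with a warning). The natural logarithm is the default because it makes
published (H, E) lane pairs internally consistent with integer band counts:
`exp(H/E)` should approximate `S`, and for all eight pairs of a four-stage
survey we checked it lands within 0.2 of an integer (e.g. exp(2.01/0.84) ≈
10.9 ≈ 11 bands). The log base is configurable.

## Ordination

PCA treats samples as observations and features as variables, computed by SVD
of the centered matrix. Default scaling is `unit_variance` (the convention of
the chemometrics software typically used for such studies); `center_only` is
offered because published preprocessing is often unstated, so reproduction of
any printed variance percentage is conditional on the scaling assumption.
Zero-variance features are dropped (with a warning) under unit-variance
scaling. Components are deterministic: each component's largest-magnitude
loading is made positive, ties broken by feature index; eigenvalue ties are
broken by component order. The number of components is
min(n_samples − 1, n_features). Sample clustering is agglomerative with
average linkage on Euclidean distances between sample columns (configurable;
the choice is conventional, not data-driven). A Hotelling ellipse helper is
provided for score plots but is not part of the tested pipeline.

## Association networks

All cross-role (bipartite) or within-role unordered (co-occurrence) pairs are
scored with the tie-aware Spearman correlation — the Pearson correlation of
average ranks — and retained when `|ρ| > rho_threshold` (default 0.6,
strict) and the two-sided p-value `< alpha` (default 0.05, strict). Nodes are
the endpoints of retained edges; degree-0 features never enter the graph.
Constant features are skipped with a warning rather than failing the run.
Degree counts incident edges of both signs. No multiple-testing correction is
applied by default (matching common practice in this literature); a
Benjamini–Hochberg option (`fdr_bh`) exists.

Two p-value conventions:

* `asymptotic_t` (default): `t = ρ·sqrt((n−2)/(1−ρ²))` with n−2 df;
  `|ρ| = 1` maps to p = 0.
* `exact_permutation`: the two-sided tail fraction of the full n! permutation
  null (full enumeration for n ≤ 8, Monte-Carlo beyond), computed on untied
  ranks.

**Why the asymptotic default:** with a 4-timepoint design the exact two-sided
permutation p-value can never fall below 2/24 ≈ 0.083, so *no* pair can clear
α = 0.05 — yet published 4-sample studies report thresholded significant
networks. Those networks are reproducible only under an asymptotic convention
in which perfectly monotone pairs get p ≈ 0. Both conventions are implemented;
with n = 4 and asymptotic p-values an edge effectively requires |ρ| = 1.

`split_by_sign` partitions edges into co-occurrence (positive) and
co-exclusion (negative) subnetworks, recomputing node sets. Hubs are nodes
with degree ≥ `min_hub_degree` (default 10), sorted by degree then id.
Co-occurrence incidence is computed over *all* retained edges (both signs) of
the combined bacteria+fungi network — published incidence percentages do not
state whether they are positive-only, so a positive-only figure can be
obtained by passing the positive subnetwork — as the fraction of edges whose
endpoint phyla match (within) or differ (cross), plus per-phylum-pair
fractions that sum to 1.

## Core flavor-contributing microbes

The three-criterion rule: (1) detected in every sample (the qualitative
"stability" criterion is interpreted as nonzero relative abundance at every
timepoint; the threshold is configurable); (2) at least one incident edge with
|ρ| above the correlation threshold (automatically true for any connected node
of a thresholded network; evaluated and reported for transparency);
(3) strictly more than `min_connections` volatiles connected in the
significant bipartite network (default 35, applied as a strict "more than").
The rule applies symmetrically to bacteria and fungi. The report covers every
microbe in the input table, including degree-0 ones, lists the failing
criteria, and exposes the degree as a fraction of the volatile universe
(since a fixed count like 35 implicitly references an ~84-compound universe,
about >40%; the count stays the default, the ratio makes rescaling visible).

## Synthetic data generator

The generator emulates a multi-year fermentation: per-sample compositional
profiles, succession-style latent trajectories, and volatiles monotonically
coupled to specific taxa.

Latent log-abundance of each foreground feature:
`l(t) = baseline + trend_amplitude·archetype(t) + jitter(t)` on a normalized
time axis t ∈ [0, 1], with archetypes rising = t, falling = 1 − t, peaked =
triangular at 0.5, stable = constant (mix proportions configurable; default
0.3/0.3/0.2/0.2). Gaussian per-timepoint jitter (sd `jitter_sd`, default 1.0)
gives each feature an identifiable rank signature — without it, any two
same-archetype features would be rank-identical and ground truth would be
ill-posed. A coupled volatile's latent is
`baseline + coupling_slope·sign·(l_m − mean(l_m)) + N(0, noise_sd)`; `noise_sd`
(default 0.25) is the single knob controlling recovery difficulty, and each
coupled volatile has exactly one partner microbe (a volatile cannot be
perfectly monotone in two independent trajectories, so
`n_coupled_pairs ≤ n_volatiles`).

Two mechanisms make the planted edge set exactly recoverable at
`noise_sd = 0`:

1. **Rank-safe closure.** Dividing each sample column by its own total would
   shift every feature's log trajectory by a sample-dependent offset and
   reshuffle cross-sample ranks. Instead, exponentiated latents are scaled by
   a single *global* constant (chosen so foreground totals stay below
   `background_fill` = 0.8) and two explicit background features per table
   (`*_BG1`, `*_BG2`) absorb the per-sample residual, so every column sums to
   1 exactly (within 1e-12) while all generated rank structure survives. The
   backgrounds model unresolved signal (unidentified peaks, faint bands) and
   are ordinary rows of the emitted tables.
2. **Spurious-correlation control.** Independent trajectories are
   rejection-sampled (up to `max_redraws` = 300 per feature) so that every
   non-planted microbe-side/volatile-side pair has |ρ| ≤ `max_spurious_rho`
   (default 0.65, deliberately below 0.7067, the |ρ| needed for asymptotic
   p < 0.05 at n = 8); the background split is re-balanced the same way. The
   default study design (8 timepoints, 20 microbes, 50 volatiles, 30 planted
   pairs) achieves noise-free precision = recall = 1 across all seeds checked.
   With 4 timepoints only 24 rank patterns exist, so the cap cannot be
   enforced for realistic feature counts; the guard deactivates below 5
   timepoints and recovery guarantees hold for ≥ 5 (in practice ≥ 6). Setting
   `max_spurious_rho = 1` disables the guard, yielding succession-driven
   co-variation among same-archetype taxa — useful for co-occurrence demos.

All randomness derives from one seed through a fixed `SeedSequence` spawn
tree (archetypes, couplings, one stream per feature, backgrounds,
annotations), so adding features never perturbs earlier draws and identical
configs are bitwise-reproducible. `n_timepoints` defaults to 4 — the classic
0/1/2/3-year design — while recovery experiments pass 8 explicitly, since
4-point series carry almost no rank information.

What the generator does *not* emulate: gel-electrophoresis physics,
chromatographic peak shapes, sequencing error, compositional count noise
(sampling depth), technical replicates, or genuine ecological interaction
dynamics. Passing recovery tests therefore demonstrates the correctness of
the statistical machinery on monotone couplings, not performance on real
community data, where compositional effects and unmodeled confounding can
induce or mask correlations.

## Numerical choices

* Spearman ρ values within 1e-12 of ±1 are snapped to ±1, so perfectly
  monotone pairs are exact and map to p = 0 under the asymptotic convention.
* Exact permutation tails count equalities into the tail with a 1e-9 guard.
* Relative-mode validation tolerance 1e-6 (reader) vs generator closure
  exactness 1e-12.
* Ties in ranks use average ranks (scipy `rankdata`); the exact permutation
  null assumes untied ranks (continuous data), an approximation when ties
  exist.
* PCA on 2 samples yields exactly one component with explained fraction 1.

## Problem sizes used by the tests and acceptance script

Recovery experiments use 8 timepoints × 20 microbes × 50 volatiles × 30
planted pairs (single dataset noise-free; 100-seed averages in tests and
50-seed averages in the acceptance script at `noise_sd = 0.5`); the
heavy-noise null check uses 200 replicates of a 3×4-feature design. These
sizes give stable Monte-Carlo averages while keeping the full suite around
ten seconds.

## Known limitations

* Spearman on 4-point series is essentially a monotonicity indicator; the
  asymptotic p-value convention is a reproduction necessity, not a
  statistical endorsement. For real inference at n = 4 the exact test is the
  honest option — and it can never reach significance.
* Correlation networks on compositional data are subject to closure-induced
  dependence; no SparCC/SPIEC-EASI-style compositional correction is
  implemented (out of scope).
* The incidence and hub statistics describe the retained edge set only; they
  inherit every thresholding decision upstream.
* Reproduction of any published study's exact numbers requires that study's
  supplementary abundance tables, which are loadable through `tabular_io`
  when available but are not distributed here.
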