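# Methods

This note records the models, rules and numerical choices behind
`corrpath`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about measured data.

## Data model

A profile is one entity's replicate-resolved time course under one
condition: strictly increasing day indices, ≥ 1 finite value per day, and
a unit (µM for intracellular metabolites, FPKM for gene expression, mM or
cells for culture metrics). Metabolite/culture profiles and gene profiles
may live on different day grids (typically days 0–5 vs 0–3); the package
never interpolates across grids — every pairwise computation uses the
intersection of the two grids, and pairs with fewer than `min_points`
(default 3) shared days yield NA with a logged warning. Missing
observations are encoded by omitting the row; empty or non-numeric cells
are parse errors, because silently imputed zeros would corrupt every
correlation downstream.

All statistics operate on per-time replicate means. The per-time SD uses
the population convention (ddof = 0) so that a single replicate reports
SD 0 rather than NaN. Profile CSVs round-trip exactly: floats are written
with `repr` and re-parsed with Python's exact `float()` (pandas' fast
CSV float parser can be off by 1 ulp, which breaks byte-level
reproducibility of the manifest hashes).

## Pattern classification

Visual grouping of time courses into increase / decrease / variable /
constant is replaced by a deterministic rule chain on the mean course v,
normalised by m = max|v| so the labels are invariant to positive scaling:

* constant if the coefficient of variation SD(v)/|mean(v)| < `const_cv`
  (default 0.10), or if v ≡ 0;
* increase if net change (v_T − v_0)/m ≥ `net_change` (default 0.20) and
  no step falls below −`step_tol` (default 0.05); decrease mirrored;
* variable if range/m ≥ `net_change` while |net|/m < `net_change`
  (a transient excursion that returns near its start);
* otherwise unclassified.

The defaults are a reproducible surrogate for by-eye judgement, not an
estimate of anything; all three thresholds are exposed in the CLI/config.
`step_tol` exists because replicate jitter puts small counter-steps into
genuinely monotone courses. Condition-contrast groupings ("high only
under the strong dose on day 1") are not shapes and are deliberately out
of the classifier's scope — they are what comparative mapping detects.

## Correlation

Pearson r on mean profiles over the shared grid, computed from the
definitional centred-sum formula in float64 and clipped to [−1, 1] to
absorb ~1e−16 overshoot. A profile constant on the shared grid has
undefined r and returns NaN — it must never masquerade as ±1. Correlations
use replicate means rather than pooled replicate points because the
heatmap semantics require one value per entity pair and the measurement
protocol reports averaged triplicates; pooling replicates would inflate n
with within-day technical variance. No p-values are computed: with 4–6
time points per vector the display scheme is about r magnitudes, and
significance testing on such short autocorrelated series would be
decorative.

A minimum of 3 shared points is admitted (configurable): restrictive
enough to reject empty/degenerate overlaps, permissive enough that the
4-point gene grid, and 3-point degenerate intersections, still compute.

## Clustering and heatmap

Features for clustering are the rows of the square within-set correlation
matrix (culture metrics included on both axes), so entities cluster by how
they relate to everything else, not by raw level. NA features are imputed
as 0 — "no correlation" — which places constant profiles neutrally without
biasing sign. Agglomerative clustering uses average linkage (UPGMA) on
Euclidean distances by default; nothing in the analysis depends on this
choice being optimal, and both knobs are exposed. Determinism is enforced
structurally: entities are sorted lexicographically before any distance is
computed (making the merge tree independent of input order), and all
naming ties break toward the lexicographically smallest member.

The tree is cut into k flat clusters (default k = 2) and the two largest
become A and B; with k > 2 the remainder is reported unassigned. This
mirrors the practice of reading the two dominant blocks off a clustered
heatmap while keeping finer cuts available. The heatmap colour scale is a
symmetric diverging map anchored blue (#2257C4) at r = −1, white at 0,
red (#D0021B) at +1, linear per half — so colour(r) and colour(−r) are
exact reflections; NA cells render blank. Culture-metric labels are
flagged (bold + asterisk) rather than underlined, a limitation of the
text renderer.

## Pathway styling

Cluster projection paints nodes/edges orange (cluster A) or light blue
(cluster B); absence — unmeasured or unassigned — is white for nodes and
grey for edges, so the map never invents signal. An edge whose isozyme
gene labels fall in conflicting clusters is greyed and logged rather than
arbitrated.

Comparative mapping bins the between-condition r per entity:

| bin | rule | style |
|---|---|---|
| strong_pos | r > 0.9 | red, node ×1.6 / edge ×2.5 |
| pos | 0.5 < r ≤ 0.9 | red |
| weak_pos | 0 ≤ r ≤ 0.5 | green |
| neg | −0.5 ≤ r < 0 | blue |
| strong_neg | r < −0.5 | blue, bold/big |
| na | undefined r | white node / grey edge |

The display legend's strict inequalities leave the boundary values
{0.9, 0.5, 0, −0.5} formally unassigned; closure here attaches each
boundary to the weaker (inner) bin, with 0 joining weak_pos — totality
with conservative styling. The positive side splits at 0.9 and 0.5 but
the negative side only at −0.5; that asymmetry is part of the scheme and
is preserved, not symmetrised. Boldness/size encodes exactly the two
strong bins (a two-bin reading of "close to ±1"), not a continuous scale.
Multi-gene edges take the most extreme |r| among their measured genes:
metabolic-map edges aggregate isozymes, and the most extreme response is
the conservative thing to highlight. Measured entities absent from the
map are listed in an `unmapped_entities.txt` sidecar, never dropped
silently.

The colour-variation report labels each entity `<colour A/B>/<colour
A/C>` using the legend colour words; both red bins collapse onto "red"
and both blue bins onto "blue" (size is a salience cue, not a colour),
matching the red/green/blue vocabulary such summaries use. The full bins
remain in the per-entity bin CSV.

Palette (bit-exact in SVG/GraphML output): orange #F5A623, light blue
#9BD7E5, red #D0021B, green #2E9E3F, blue #2257C4, white #FFFFFF, grey
#BDBDBD.

## Synthetic data

The generator emulates the study design the analysis assumes: 34
metabolites and 40 genes (defaults; echoing a central-metabolism scope) in
triplicate, metabolites/culture on days 0–5 and genes on days 0–3, a
control plus two dose conditions. Entities are partitioned into blocks;
each block has a base temporal shape and each entity a log-uniform
amplitude in [10, 1000] (µM and FPKM values spanning decades). Shapes:

* increase — logistic ramp 0.1 → 1.0 centred mid-course;
* decrease — its mirror;
* variable — symmetric Gaussian bump returning to baseline;
* constant — flat.

Within a block, profiles differ only by amplitude, so pairwise r = 1
before noise. Across blocks the design requires |r| ≤ 0.1 on every
configured grid, and generation fails with an explanatory error
otherwise. The default pairing (ramp, bump) achieves exact orthogonality:
on a symmetric day grid the centred ramp is odd about the midpoint and
the bump is even, so their centred product sums to zero. An
increase/decrease pairing is rejected by the same check (r = −1), which
is why the default planted classes are {increase, variable}; decrease and
constant shapes remain available and are unit-tested directly.

Dose conditions blend each affected entity's unit shape toward an
orthogonal alternative with weight p ∈ [0, 1]; the between-condition r
against control then decays monotonically with p (≈ 0.92 at p = 0.3,
≈ 0.40 at p = 0.7 on the 6-day grid), giving the strong-dose comparison
fewer strong-positive entities than the weak-dose one — the qualitative
signature the comparative map is meant to show. Replicate noise is
multiplicative log-normal with mean 1 and relative SD `noise_cv`
(default 0.05), since concentrations and FPKM are positive with
scale-proportional error. σ is set to √log(1+cv²) with mean −σ²/2 so the
factor's moments are exact. Everything derives from one seed;
regeneration is bit-identical.

The culture-metric triple (cell_number rise-then-fall, extracellular
glucose decrease, extracellular lactate increase, fixed realistic
amplitudes 10⁶ cells / 20 mM / 10 mM) is generated alongside but outside
the block system: a monotone-decrease shape cannot satisfy the
cross-block orthogonality bound against an increase block (r = −1), so
the triple carries no block id, ground-truth cluster scoring covers omics
blocks only, and the culture metrics exist to exercise the both-axes
insertion paths. Their pattern classes are recorded in the ground truth.

Ground truth stores each entity's planted pattern class, block id, and
expected comparative bin versus control computed from the noise-free
curves. `truth_check` scores pattern accuracy, adjusted Rand index (ARI)
of recovered vs planted blocks, and bin agreement.

**What passing these tests shows — and does not.** Synthetic profiles are
phenomenological: smooth shapes, exchangeable log-normal replicates, exact
block structure, no kinetics, no batch drift, no missingness, no
measurement floor/saturation. Perfect zero-noise recovery and robust
5 %-noise recovery demonstrate that the pipeline's machinery is correct
and stable, not that two clusters or five bins are the right description
of any real culture; on measured data the cluster count, the linkage and
the thresholds deserve sensitivity checks.

## Problem sizes and numerical conventions

Test and acceptance runs use deliberately modest sizes — up to ~30
entities per axis, 20 generator seeds per stochastic property — which
complete in seconds while exercising every code path; all sizes scale via
`SyntheticConfig`. Tolerances: correlation values are asserted to 1e−12
against an independent definitional implementation; round trips are
exact. Degenerate inputs have defined behaviour throughout: zero-variance
profiles → NA → "na" bin and absence styling; < 3 time points → input
error; empty clusters export empty files. SVG output carries no
timestamps and force-directed layouts are seeded, so renders are
byte-reproducible; run manifests record parameter values and SHA-256
hashes of every output.

## Known limitations

* Pearson r on 4–6 points is a coarse similarity; the pipeline treats it
  as a display statistic, not an inference.
* KGML import is best-effort (compounds → nodes, reactions → gene-labelled
  edges); relation elements and group entries are ignored.
* GO/PANTHER enrichment is out of scope by design — the package exports
  per-cluster gene lists for external submission.
* The heatmap flags culture metrics typographically (bold/asterisk)
  rather than with true underlines.
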