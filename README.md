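# corrpath

Time-series multi-omics correlation analysis and metabolic pathway mapping
for cell-culture profiling.

## The problem

Batch cultures of production cell lines (the motivating system is CHO —
Chinese hamster ovary — cells, the dominant host for biopharmaceutical
protein manufacture) are routinely profiled over a few days on several
channels at once: intracellular metabolite concentrations (µM, daily, e.g.
days 0–5), gene expression (FPKM, often on a shorter grid, e.g. days 0–3),
and culture metrics — viable cell number and extracellular glucose/lactate
(mM) — under one or more medium conditions (e.g. 0/5/10 mM lactate added).
Identifying which genes and metabolites move together, and which respond to
the condition, from a handful of short, heterogeneous time courses is a
correlation-and-visualisation problem rather than a model-fitting one.
`corrpath` implements that analysis as a reproducible pipeline:

1. **Pattern classification** — each profile's replicate-mean time course
   is assigned to one of {increase, decrease, variable, constant,
   unclassified} by a deterministic, scale-invariant rule chain.
2. **All-pairs Pearson correlation** — profiles are reduced to vectors of
   per-time replicate means and correlated with

   r = Σᵢ(xᵢ−x̄)(yᵢ−ȳ) / √(Σᵢ(xᵢ−x̄)² · Σᵢ(yᵢ−ȳ)²)

   on each pair's shared time points (no interpolation across the day-0–5
   vs day-0–3 grid mismatch; constant profiles give NA, never ±1).
3. **Correlation-profile clustering and heatmap** — entities are clustered
   (UPGMA, Euclidean) on their rows of the within-set correlation matrix,
   with culture metrics inserted on both axes; the two largest clusters
   per axis (A/B) annotate the gene × metabolite heatmap (blue −1 → white
   0 → red +1).
4. **Pathway projection** — on a metabolic map with metabolites as nodes
   and genes as reaction edges, cluster A is tagged orange and cluster B
   light blue; unmeasured metabolites stay white and unmeasured genes grey.
5. **Comparative mapping** — per entity, the correlation R between its
   time course under two conditions is placed in five display bins
   (R > 0.9 bold red; 0.9 ≥ R > 0.5 red; 0.5 ≥ R ≥ 0 green;
   0 > R ≥ −0.5 blue; R < −0.5 bold blue) and drawn on the map; a
   Table-of-colour-variations report contrasts two comparisons (e.g.
   control/low dose vs control/high dose).

A synthetic-data generator with planted pattern classes, correlation
blocks and dose effects makes every stage testable end to end without any
measured dataset.

## Worked example

Generate a synthetic study (two correlation blocks, three conditions with
perturbation strengths 0 / 0.3 / 0.7, 5 % replicate noise), then run the
full pipeline:

```bash
corrpath simulate  --out demo/sim --seed 1 --noise-cv 0.05
corrpath classify  --profiles demo/sim/profiles.csv --out demo/cls
corrpath correlate --profiles demo/sim/profiles.csv --condition 0mM --out demo/cor
corrpath map       --profiles demo/sim/profiles.csv --pathway examples/synthetic_pathway.json \
                   --condition 0mM --out demo/map
corrpath compare   --profiles demo/sim/profiles.csv --pathway examples/synthetic_pathway.json \
                   --cond-a 0mM --cond-b 5mM --cond-c 10mM --out demo/cmp
```

`demo/cls/patterns.csv` starts:

```
entity_id,condition,pattern,net_change_value,cv_value
G000,0mM,increase,0.8988886816069898,0.6835963191344403
G000,10mM,unclassified,0.21120236317608215,0.21885305613183673
G000,5mM,unclassified,0.5881541875652417,0.36150755063438245
G001,0mM,variable,-0.0012173239980889329,0.23715619031850224
```

G000's planted ramp is recovered as *increase* in the control; under the
perturbed conditions its blended shape no longer meets the monotone rule
and drops to *unclassified* — the classifier sees the dose effect.
`demo/cor/clusters_metabolite.csv` splits the 34 metabolites + 3 culture
metrics into clusters A (18) and B (19), exactly the planted ramp/bump
blocks. The variation report contrasting control/5 mM with control/10 mM
(`demo/cmp/variation_report.csv`):

```
pattern,kind,entities
red/green,metabolite,M000;M001;M002;M003;M004;M005
red/green,gene,G001;G002;G003;G004
red/red,gene,G000
```

Nearly every mapped entity is red (R > 0.5 vs control) under the weak
perturbation but green (uncorrelated) under the strong one — the
dose-dependent loss of correlation the comparative map is designed to
expose. Alongside the CSVs the pipeline writes the clustered heatmap
(`heatmap.png/.svg`), styled pathway maps (`cluster_map.svg`,
`comparative_*.svg`, plus GraphML), per-cluster gene lists ready for
enrichment submission, and a `manifest.json` with parameter values and
SHA-256 hashes of every output (reruns with the same seed hash
identically).

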