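# heteronet

Heterosis statistics and signed weighted gene co-expression network analysis
for purebred/crossbred expression designs.

`heteronet` is built for studies that ask *why a cross outperforms its
parents* — the canonical example being egg production in chicken reciprocal
crosses (White Leghorn × Beijing You: purebreds WW and YY, crosses WY and
YW), phenotyped in 4-week laying windows and expression-profiled in the
ovary at five laying stages. It implements the full computational chain such
a study needs, over plain TSV/CSV inputs:

* **Heterosis index and significance.** For a trait with cross mean F̄ and
  parent means P̄ₚ, P̄ₘ, the mid-parent value is MPV = (P̄ₚ + P̄ₘ)/2 and

      H = (F̄ − MPV) / MPV,
      t = H / ( 2·s / ((P̄ₚ + P̄ₘ)·√n) )   with df = n − 1,

  where s is the sample SD of the n cross phenotypes; the second expression
  is algebraically (F̄ − MPV)·√n/s and both forms are computed and checked
  against each other.
* **Expression preprocessing**: FPKM from counts
  (counts·10⁹/(libsize·length)), the expressed-gene filter (FPKM > 0.1 in at
  least 30% of samples), top-50%-MAD gene selection, sample PCA and
  sample–sample correlation on log2(FPKM+1).
* **Signed co-expression networks** per genetic group: adjacency
  a_ij = ((1+r_ij)/2)^β with β chosen by the scale-free topology criterion
  over powers 1–30, topological overlap (TOM), average-linkage clustering of
  1 − TOM cut at height 0.995 with minimum module size 50, module eigengenes
  (first PC), iterative merging at eigengene dissimilarity 0.25, and
  module–trait correlation with the Student-t p-value.
* **Consensus modules** across groups: quantile-scaled TOMs combined at
  consensus quantile 0 (elementwise minimum), deeper tree splitting,
  merging on the 0.25-quantile consensus of eigengene correlations; module
  membership kME as the biweight midcorrelation between a gene and its
  module eigengene; hub genes at kME > 0.70 and P < 1e-5; Fisher exact
  module-overlap tests; eigengene networks.
* **Module preservation** between a reference and a test dataset:
  permutation Z-scores of two density and two connectivity statistics,
  summarized as Zsummary (> 10 strong, 2–10 weak-to-moderate, ≤ 2 none).
* **Gene-action classification** of each gene × stage into the 12
  roman-numeral inheritance categories — additivity (IV, X), high-/low-
  parent dominance (III, XI / V, IX), and overdominance above/below the
  parents (I, VII) or beyond the better/worse parent (II, XII / VI, VIII) —
  from Welch t-tests on FPKM with Benjamini–Hochberg FDR at 0.05.
* **Gene-set enrichment** (hypergeometric over-representation against GMT
  collections with BH adjustment).
* A **synthetic-data generator** that emulates the whole study design with
  planted ground truth (heterosis trajectory, co-expression modules with hub
  gradients, per-gene×stage action modes), so every stage of the chain can
  be validated against known answers.

The clustering/classification-shaped pieces are scikit-learn-style
estimators (`CoexpressionModules`, `ConsensusModules`, `ModulePreservation`,
`GeneActionClassifier`) with plain functions underneath.

## Worked example

```python
import heteronet as hn
from heteronet.network import CoexpressionModules

spec = hn.SimulationSpec(seed=7, n_genes=500, module_sizes=(100, 100, 100),
                         n_hens_per_group=300, windows=20)
ph, truth = hn.simulate_phenotypes(spec)
est = hn.heterosis_by_window(ph, cross="WY")
print(est[["window", "f_bar", "mpv", "h_percent", "t", "p"]].head(3).round(3))
```

```
 window  f_bar    mpv  h_percent      t   p
      1 24.578 22.948      7.104 10.314 0.0
      2 23.807 22.331      6.610 10.617 0.0
      3 23.225 21.911      5.997 10.063 0.0
```

Each row is one 4-week window: the WY cross laid `f_bar` eggs on average
against a mid-parent value `mpv`, a heterosis of ~6–7% early in lay
(matching the planted trajectory), significant in all 20 windows.

```python
sim = hn.simulate_expression(spec)
ww = sim.fpkm.for_group("WW")
model = CoexpressionModules(power=12, deep_split=2, min_module_size=50).fit(ww)
report = hn.module_preservation(ww, model.labels_, sim.fpkm.for_group("WY"),
                                power=12, n_perm=100, seed=7)
print(report[["module", "moduleSize", "Zdensity", "Zconnectivity",
              "Zsummary", "call"]].round(2))
```

```
   module  moduleSize  Zdensity  Zconnectivity  Zsummary   call
     blue         148     21.98          19.75     20.86 strong
    brown         138     21.76          17.96     19.86 strong
turquoise         171     19.73          20.91     20.32 strong
```

The three planted modules detected in the WW purebred are strongly
preserved (Zsummary > 10) in the WY cross — the crossbred transcriptome
carries the same co-expression architecture as the parent, which is the
premise for then asking *how* module genes differ in expression level
(the gene-action classification).

## Command line

```bash
heteronet simulate  --out sim --seed 7
heteronet heterosis --phenotypes sim/phenotypes.csv --cross WY --out het.tsv
heteronet network   --matrix sim/expression_fpkm.tsv \
                    --metadata sim/expression_metadata.tsv --group WW \
                    --power 12 --out net/
heteronet pipeline  --config examples/fixture_config.yaml --out run/
```

`heteronet pipeline` runs the whole chain from one YAML config and writes a
manifest with a SHA-256 checksum per output; reruns with the same config and
seed are byte-identical.

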