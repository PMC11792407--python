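# Methods

This note records the statistical models implemented in `heteronet`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the published
procedures leave room.

## Heterosis statistics

Heterosis for a trait in a cross is H = (F̄ − MPV)/MPV with
MPV = (P̄ₚ + P̄ₘ)/2, reported both as a fraction and as a percentage. Its
significance uses the transformed Student t

    t = H / ( 2·s / ((P̄ₚ + P̄ₘ)·√n) ),   df = n − 1,

with s the sample SD of the n cross phenotypes. This is algebraically
(F̄ − MPV)·√n/s; both forms are evaluated and asserted equal at 1e-9
relative tolerance on every call.

**Caveat — parent means as constants.** The formula carries no variance term
for the parent means. Conditional on the parent means (the statistic's own
sampling model) the test is exactly calibrated: in a 1,000-replicate null
simulation with n = 300 cross phenotypes the rejection rate at 0.05 sits
inside the binomial confidence interval. When the parent means are
themselves estimated from n = 300 birds per group, the unconditional
rejection rate rises to ~11–12% (the z-scale inflation is √1.5 with equal
group sizes and SDs). Both behaviours are asserted by the test suite. Users
comparing groups of similar size should read "significant" conditionally on
the parent estimates.

The p-value is two-sided by default (`two_sided=False` gives the upper
tail); the publication style this follows does not state sidedness, and
two-sided is the conservative symmetric choice for negative heterosis.
Stage-level heterosis is the unweighted mean of window H within a stage.

## Expression preprocessing

* FPKM[g,i] = counts[g,i]·10⁹ / (libsize_i · length_g).
* Expressed-gene filter: FPKM strictly greater than 0.1 in at least
  ⌈0.30·n_samples⌉ samples ("at least 30%" read inclusively, over all
  samples rather than per group).
* MAD selection: per-gene median absolute deviation without the 1.4826
  consistency constant (only the ranking matters); ties at the cutoff break
  by gene-ID lexicographic order for determinism.
* PCA and sample correlations run on log2(FPKM + 1): a fixed, dependency-free
  variance-stabilizing transform used in place of model-based shrinkage
  transforms, surfaced in the configuration. Networks use the same scale.

## Signed networks and modules

Adjacency a_ij = ((1 + r_ij)/2)^β from Pearson correlation between gene
profiles; unsigned TOM on this signed adjacency (the standard pairing),

    TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij).

β is chosen as the smallest power in 1..30 whose signed scale-free fit R²
reaches 0.8; the fit discretizes connectivity into 10 **equal-width** bins
and regresses log10 p(k) on log10 k̄ (equal-occupancy bins would make p(k)
constant by construction and the regression degenerate). When no power
reaches the target — which is typical for block-structured synthetic data,
whose degree distribution is not scale-free — the maximizing power is used
and flagged. For planted-module benchmarks the package uses the
field-standard signed-network default β = 12 instead of the flagged
fallback; benchmark results are insensitive to β in the 6–16 range.

Modules come from average-linkage clustering of 1 − TOM cut at height 0.995
with minimum module size 50; leftover genes are grey. The `deep_split`
parameter adds recursive sub-branch splitting for branches larger than three
times the minimum size: the branch is re-clustered and cut at the highest
height that separates at least two children of minimum size (peripheral
genes outside every such child drop to grey), recursing `deep_split` times.
This mirrors the "higher deepSplit = more aggressive splitting" semantics of
dynamic tree cutting without reimplementing its hybrid PAM stage. A known
consequence of omitting the PAM stage: some background genes attach to a
module's periphery instead of staying grey; planted-module recovery is
therefore evaluated over module genes.

Module eigengenes are the first right singular vectors of the
gene-standardized module submatrix (unit norm, sign-aligned to correlate
non-negatively with the module mean profile); variance explained is the
leading singular value's share. Merging clusters eigengenes by 1 − cor,
merges branches below 0.25, recomputes and iterates to a fixpoint; a merged
module keeps its largest member's color. Colors come from a fixed ordered
palette assigned by decreasing module size.

Module–trait correlation is Pearson r with the Student-t p-value
t = r√(n−2)/√(1−r²), df = n − 2 (p = 0 at |r| = 1).

## Consensus modules

Per-group TOMs are power-scaled so each one's 0.95 off-diagonal quantile
hits the **geometric mean** of the per-group quantiles — a reference-free
target chosen so the result cannot depend on group order (scaling everything
to one designated group would break that symmetry; the pairwise
`scale_tom_quantile` with exponent log Q_ref / log Q_test is also provided).
The consensus TOM is the elementwise quantile across groups at consensus
quantile 0, i.e. the minimum: an edge counts only as strongly as its weakest
group supports it. Detection uses the same tree cut with deep_split 2, cut
height 0.995 and minimum size 50; merging uses the 0.25 elementwise quantile
(linear interpolation) of the per-group eigengene correlation matrices at
cut height 0.25, iterated to a fixpoint.

kME is the biweight midcorrelation (tuning constant 9; weights (1 − u²)²
zeroed beyond 9 MADs; Pearson fallback when a MAD is zero) between a gene
and its own module's eigengene, with the Student-t p-value at df = n − 2.
Hub genes satisfy kME > 0.70 AND p < 1e-5, both strict by a literal reading
of the thresholds. CM-to-group-module relationships use the one-sided
(enrichment) Fisher exact test over the shared gene universe.

## Module preservation

For each reference module, four statistics are evaluated in the test data:
meanAdj and propVarExplained (density family), cor.kIM and cor.adj
(connectivity family; correlations of intramodular connectivity and of
within-module adjacency entries between reference and test networks). The
published family is larger; this reduced set keeps each family's median
well-defined with two members per family.

The null permutes module membership **on the test side only**: each of
`n_perm` (default 100, seeded) draws replaces the module's gene set in the
test network with a random same-size set, while the reference side keeps the
true module genes. This detail matters: permuting both sides leaves the
ref–test gene correspondence intact, and in any globally modular network
such a null is itself "preserved", driving the connectivity Z negative for
genuinely preserved modules. Z = (obs − null mean)/null SD per statistic,
Zdensity/Zconnectivity are family medians, Zsummary their mean, with the
usual reading: > 10 strong, 2–10 weak to moderate, ≤ 2 none. Separability
(eigengene correlation between module pairs in the test data, flagged above
|cor| 0.9) is reported on the side and not folded into Zsummary.

## Gene-action classification

Per gene, cross and stage, on FPKM: Welch t-tests (robust at n = 6; a pooled
option exists) for WW vs YY, F1 vs WW, F1 vs YY, and a one-sample t of the
F1 replicates against the estimated mid-parent constant (a two-sample
variant against recentred parent pseudo-samples is available by flag — the
one-sample default treats the mid-parent as fixed, consistent with the
heterosis formula, and is slightly anticonservative for the additivity
call). BH FDR is applied per comparison across genes within a stage and
cross. Decision order (fixed so every gene gets exactly one label):
overdominance (F1 significant vs both parents in the same direction) →
dominance (significant vs exactly one) → additivity (parents significantly
different, F1 not significantly different from mid-parent) → none. A gene
significantly above one parent and below the other falls through to the
additivity check. Within each mirrored numeral pair the sign of μ_YY − μ_WW
picks the numeral (first numeral: YY higher), so swapping parent labels
mirrors numerals and never changes the supercategory — a tested invariant.

## Synthetic data

The generator emulates the study design end to end:

* **Phenotypes**: per-hen egg numbers per 4-week window (default 20 windows,
  300 hens/group), normal with SD = cv·mean (cv 0.10) truncated at zero;
  crossbred window means are (1 + H_w)·MPV, with a default H trajectory that
  is strong at onset (7.4%), weaker through persistent lay (4.0/3.0/2.7%),
  and strongest in prolonged lay (10%). Oviduct length and body weight are
  stable per-hen traits with crosses near mid-parent.
* **Expression**: genes × (4 groups × 5 stages × 6 replicates) on the log2
  scale. Module genes load on a latent per-sample factor with an evenly
  spaced loading gradient ρ_g ∈ √c ± 0.15 — a deterministic function of a
  gene's position, so independently simulated datasets share the hub
  ordering (without a reproducible gradient, connectivity-based preservation
  statistics would carry no signal). Mean pairwise within-module correlation
  is the target c. Module factors get a stage-dependent sinusoidal mean
  shift (amplitude 0.5) so eigengene trajectories are non-trivial while the
  realized correlation at c = 0.6 stays inside its Monte-Carlo band.
  Baselines are uniform on log2 ∈ [2, 7]; values are exponentiated to
  FPKM-like numbers, and the emitted count matrix is the exact inverse image
  of the FPKM matrix given the emitted gene lengths and library sizes (so
  counts are real-valued expected fragments, not integers).
* **Gene-action planting**: group×stage mean shifts on the log2 scale in
  units of the per-gene SD, with parents separated by the full effect and
  the F1 placed per category; validation rejects categories whose defining
  inequalities need a difference when the effect is zero.
* **Noise level**: within-group log2 SD defaults to 0.35 (replicate CV
  ≈ 25%), a mainstream value for bulk-tissue RNA-seq biological replicates
  in controlled designs. This matters because t statistics on the FPKM scale
  are bounded near √n/CV regardless of effect size; at CV ≈ 0.78 no planted
  effect would be detectable at n = 6 after FDR, at CV ≈ 0.25 large (5 SD)
  effects are detected reliably.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: count overdispersion and the mean–variance
relation of sequencing noise, batch effects, correlated phenotype windows
within a hen, parent-of-origin differences between the reciprocal crosses,
unequal module sizes/overlapping modules, and any biology linking the
planted phenotype trajectory to the planted expression modules.

## Problem sizes in the test and benchmark suites

Benchmarks run at desk scale, chosen to exercise every code path with
comfortable statistical margins: networks of 500–600 genes with 4–5 planted
100-gene modules at 30 samples; preservation with 100 permutations;
classifier power studies with 120 planted effects over 50 seeds; heterosis
calibration with 1,000 replicates at n = 300. The end-to-end pipeline
fixture (240 genes, 3 modules, 80 hens/group) completes in seconds and is
checksum-reproducible under a fixed seed.

## Known limitations

* The tree cut has no PAM refinement stage, so module peripheries can absorb
  nearby background genes (quantified above).
* The scale-free criterion is a poor guide on block-structured data; the
  flagged fallback plus a documented fixed β is the supported path there.
* The heterosis t ignores parent-mean sampling error (quantified above).
* Preservation's statistic set is the reduced 2+2 family, not the full
  published list; medianRank-style statistics are out of scope.
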