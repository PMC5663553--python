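# Methods

`mycnsig` implements a cross-platform screening procedure for expression
biomarkers of *MYCN* amplification in neuroblastoma-style cohorts, together
with a synthetic-data generator that plants a known ground truth so that
every stage of the procedure can be tested end to end. This note records the
models, the defaults and why they were chosen, and what the synthetic
results do and do not show.

## The screening procedure

The pipeline mirrors a common multi-cohort biomarker design:

1. **Preprocessing** (experimental-style probe data only): probe rows with
   any non-positive intensity are dropped, intensities are
   quantile-normalized, and replicate probes are collapsed to one value per
   gene by geometric averaging.
2. **Case-to-normal ratios (CNR).** For gene *n* and sample *s*,
   `CNR(n,s) = expr(n,s) / mean(expr(n, reference))`. The reference set is
   either a designated normal-control group or all tumor samples of the
   cohort ("mean transcriptome" normalization). Reference averaging is the
   arithmetic mean on the linear scale, read literally from the definition
   of "average expression"; a geometric-mean option is provided.
3. **Pathway activation strength (PAS).** For pathway *p* and sample *s*,

       PAS(p,s) = Σ_n ARR(n,p) · BTIF(n,s) · log10 CNR(n,s)

   summed over the pathway's member genes measured in the cohort, where ARR
   ∈ {±1, ±0.5} is the gene's signed activator/repressor role weight (data,
   loaded from the pathway database) and BTIF ∈ {0,1} gates genes whose
   change is too small to count. Positive PAS means activation relative to
   the reference, negative means inhibition. The decimal logarithm is a
   convention: any base rescales all PAS values by a constant and leaves
   every downstream AUC unchanged.
4. **Marker screening.** Every non-constant gene (on CNR) and pathway (on
   PAS) is scored by the Mann–Whitney AUC against amplification status with
   ties counted ½. Because markers move in both directions, gating uses the
   oriented AUC `max(AUC, 1−AUC)` at a single threshold (default 0.8), with
   the direction recorded per feature. No multiple-testing correction is
   applied here; error control comes from the next step.
5. **Cross-cohort intersection.** Markers passing the gate independently in
   both cohorts ("double markers") are intersected. Significance of the
   overlap is assessed by drawing, 10,000 times, random subsets of the same
   cardinalities from each cohort's own measured-feature universe,
   intersecting them, and approximating the discrete null by a normal
   distribution. The reported p-value is the upper tail at
   `observed − ½` (continuity correction), always accompanied by the
   empirical tail fraction, which guards against approximation failure far
   in the tail. For uniform draws the analytic null mean is
   `k_a·k_b·|shared| / (|U_a|·|U_b|)`.
6. **Pathway reconstruction.** The double marker genes seed a connecting
   subnetwork over the merged interaction databases: node union, parallel
   edges collapsed (conflicting signs stored as ambiguous), every seed pair
   within 4 hops linked by **all** shortest paths (unit edge weights), and
   loosely-connected branches cut by iteratively deleting non-seed nodes of
   degree ≤ 1. Retaining all shortest paths instead of one arbitrary path
   removes tie-breaking nondeterminism; seeds are never pruned.
7. **Validation.** The reconstructed pathway is treated as a single gene
   set and its PAS per sample is scored as a biomarker on a held-out
   cohort, once per normalization mode (mean transcriptome and each control
   set), reporting the oriented AUC.

## BTIF rules

The gating flag is configurable because the exact rule is a methodological
choice rather than a derived quantity. The default is a fold-change rule:
`BTIF(n,s) = 1` iff `|log10 CNR(n,s)| ≥ log10 1.5`, i.e. at least a 1.5-fold
change in either direction, applied per cell. The alternative is a
cohort-wide rule: a two-sided Welch t-test of the gene's log2 expression,
tumor vs reference, at α = 0.05, giving one flag per gene. The test rule
requires at least two reference samples and both rules should be regarded as
approximations of the original significance-gating idea.

## The synthetic-data generator

`mycnsig.synthetic` draws cohorts from the simplest model with the
multiplicative structure CNR assumes:

    log2 intensity = baseline(gene) + direction(gene)·effect_log2·1[amplified ∧ marker]
                     + Normal(0, noise_sd_log2)

with per-gene baselines uniform on `baseline_log2_range` (default 4–12, a
realistic microarray dynamic range) and reported intensities `2^log2`, hence
strictly positive log-normal noise. Half of the marker genes (sorted order)
are shifted up in amplified samples and half down, so screening must be
direction-agnostic. Control samples sit at baseline. The amplified count is
`round(n·frac_amplified)` with a floor of 2 (an AUC needs both classes).

Defaults are chosen to emulate the shape of real neuroblastoma cohorts at
desk scale: two discovery cohorts of 200 tumor samples with 20% amplified
(the clinical amplification frequency), gene universes of 2,000 genes that
overlap in 1,600 (cross-platform chips measure overlapping but non-identical
gene sets), 50 planted markers at `effect_log2 = 2` (a 4-fold shift, the
order of magnitude of a copy-number-driven expression change) with
`noise_sd_log2 = 0.7`, a 150-pathway database of which 12 draw ≥ 60% of
their members from the planted markers with ARR signs matching the planted
direction, and a 41-sample validation cohort with 5 amplified samples and
two control sets (7 + 4), mirroring a small clinical validation series. The
interaction network plants a connector scaffold — markers attached
round-robin to 10 connector nodes that form a clique, guaranteeing every
marker pair is joined through at most two connectors — on top of
Erdős–Rényi background edges with mean degree 2.

One seed drives each generator; sub-streams are derived by fixed offsets so
regeneration is bit-reproducible and no seed bookkeeping leaks into
downstream code.

**What the generator does not emulate:** probe-level chip physics, batch
and site effects, correlated gene–gene noise, clinical covariates (stage,
ploidy, chromosomal losses), partial-volume tumor purity, or biologically
structured pathway overlap. Passing tests therefore demonstrate that the
procedure is implemented correctly and recovers planted structure under
idealized noise — not that it would achieve the same sensitivity on real
cohorts, where correlated noise and purity effects reduce effective effect
sizes.

## Numerical and design choices

- **Quantile normalization** maps each column's ranks onto the across-column
  mean of order statistics; tied values within a column receive the mean of
  the reference values over their tied rank span (deterministic standard tie
  rule). The procedure is idempotent on tie-free data; with ties the first
  pass can collapse values, so exact idempotence is only guaranteed for
  continuous data.
- **Preprocessing order**: dropping non-positive probes always comes first;
  whether replicate probes are averaged before or after quantile
  normalization is genuinely ambiguous for on-chip replicate designs, so
  both orders are supported (`collapse_first`), with normalization at the
  probe level as the default.
- **Probe collapse** uses `exp(mean(log(·)))` with single-probe genes passed
  through exactly (no log/exp round-trip error).
- **Gene-id matching is case-sensitive** everywhere; silent harmonization is
  worse than a loud mismatch.
- **Hierarchical clustering** (Euclidean distance, complete linkage) is
  written out explicitly so that ties merge the lexicographically smallest
  cluster pair, making dendrograms identical across platforms; the merge
  table uses the standard linkage-matrix layout so existing tree-cutting
  and drawing utilities apply. Leaf order puts the smaller subtree first.
  The co-clustering score of the amplified group is the maximum, over the k
  clusters of a tree cut (default k = 2), of the F1 between cluster
  membership and the amplified label.
- **Null simulation universes**: random subsets are drawn from each
  cohort's own measured-feature universe and intersected on shared ids
  (platforms differ in gene coverage); drawing from the shared universe
  instead is a caller choice by passing identical universes.
- **Reconstruction knobs**: unit edge weights (hop count is the only
  distance merged public databases support); hop limit 4 by default —
  unbounded all-shortest-paths on dense merged graphs explodes
  combinatorially, and connecting pathways of interest use few
  intermediaries; pairs farther apart are left unlinked and reported.
  Branch cutting = iterative degree-≤1 non-seed removal; this is one
  literal reading of "cut loosely connected branches" with a well-defined
  fixed point, documented as an interpretation.
- **ARR weights for the reconstructed pathway** default to the discovery
  marker directions (up_in_amplified → +1, down → −1) for seed genes and +1
  for intermediaries, via an explicit override mapping. A flat +1 for all
  members would make balanced up/down marker sets cancel in the summed
  score by construction; using the observed direction as the sign context
  is the auditable default, and any mapping can be supplied.
- **Validation-cohort genes** absent from the pathway membership are
  ignored, not imputed, mirroring cross-platform chip coverage.

## Problem sizes

The default study (two cohorts of 200 samples over 2,000 genes, 150
pathways, 10,000 null replicates) is the package's reference desk scale: it
is large enough that the AUC gate, the intersection null and the
reconstruction operate in their intended regimes, while a full run completes
in seconds. Unit and property tests use smaller cohorts (40–80 samples,
40–300 genes) chosen so that each statistical assertion retains power; the
null-calibration checks use 10⁴–10⁵ replicates so that three-standard-error
bands are tight around the analytic expectations.

## Known limitations

- The intersection p-value is a normal approximation to a discrete null;
  in the far tail it can underflow to 0, which should be read as
  "p below the resolution of the approximation" (the empirical tail
  fraction is reported alongside).
- All-shortest-paths enumeration is exponential in the worst case; the hop
  limit keeps it tractable but means distant seed pairs are simply not
  linked.
- The co-clustering F1 takes the best-matching cluster, so with many small
  clusters (large k) it is optimistically biased; compare scores only at
  fixed k.
- The test-rule BTIF applies one flag per gene cohort-wide, which couples
  samples; the fold rule is the per-sample default.
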