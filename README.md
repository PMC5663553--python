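# mycnsig

Cross-platform screening of gene- and pathway-level expression biomarkers of
*MYCN* amplification in neuroblastoma-style cohorts.

Amplification of the *MYCN* proto-oncogene marks the high-risk neuroblastoma
subtype (~20% of cases). Single-cohort expression signatures of the
amplified subtype travel poorly between microarray platforms, so a robust
screen asks three things at once: does a feature discriminate amplified from
wild-type samples well (ROC AUC), does it do so **independently in two
cohorts measured on different platforms** (double markers), and is the size
of that cross-cohort overlap larger than chance (a random-subset simulation
null)? `mycnsig` implements that procedure at two feature levels — single
genes (on case-to-normal expression ratios) and signaling pathways (on
pathway activation strength scores) — and then reconstructs a connecting
"amplification pathway" from the double marker genes over merged molecular
interaction networks, validating it as a single biomarker on a held-out
cohort.

The core quantities:

- **CNR** (case-to-normal ratio): `CNR(n,s) = expr(n,s) / mean(expr(n, reference))`,
  where the reference is a normal-control group or the cohort's mean
  transcriptome.
- **PAS** (pathway activation strength):
  `PAS(p,s) = Σ_n ARR(n,p) · BTIF(n,s) · log10 CNR(n,s)` over pathway
  members, with signed activator/repressor weights ARR ∈ {±1, ±0.5} and a
  beyond-tolerance gate BTIF (default: ≥1.5-fold change). Positive PAS =
  pathway activated relative to the reference.
- **Oriented AUC**: `max(AUC, 1−AUC)` of the Mann–Whitney AUC against
  amplification status, ties counted ½, with the direction recorded; the
  marker gate is oriented AUC ≥ 0.8.
- **Intersection null**: 10,000 random subset draws of matching
  cardinalities from each cohort's feature universe; overlap p-value from a
  continuity-corrected normal approximation, reported with the empirical
  tail.

Every stage is exercised end to end on synthetic cohorts with planted
ground truth (`mycnsig.synthetic`): a known marker set with up- and
down-shifted halves, pathway databases enriched for those markers with
coherent role signs, and interaction networks with a planted connector
subgraph. See `docs/methods.md` for the models and defaults.

## Worked example

```python
from mycnsig import pipeline

result = pipeline.run_all(pipeline.StudyConfig(seed=1))
report = result["report"]
print(report["cohort_a"])                      # {'n_gene_markers': 50, 'n_pathway_markers': 16}
print(report["gene_intersection"]["n_double"]) # 50
print(round(report["gene_intersection"]["null_mean"], 2),
      round(report["gene_intersection"]["null_sd"], 2))   # 1.01 1.0
print(report["reconstruction"])
# {'n_seeds_found': 50, 'n_intermediaries': 22, 'n_edges': 117,
#  'unreachable_seeds': [], 'missing_seeds': []}
print(report["validation"]["control_adrenal"]["auc"])     # 1.0
```

Reading: each discovery cohort yields 50 gene markers at the AUC ≥ 0.8 gate
(all 50 planted markers, no false positives at this effect size); all 50
intersect across cohorts while random subsets of the same sizes share only
1.01 ± 1.0 features, so the overlap is non-random far beyond p < 0.001. The
50 seed gene products are joined through 22 intermediary nodes (the 10
planted connectors plus shortcuts through background edges), and the
reconstructed pathway's activation score separates amplified from wild-type
validation samples perfectly under each normalization mode.

The same stages are available as a CLI (`mycnsig simulate | preprocess |
pas | screen | intersect | build-pathway | cluster | run-all`) and as
narrative drivers under `analysis/` (`01_simulate_study.py` …
`06_validate_pathway.py`, each `--seed`-driven, printing what it found and
writing tables under `results/`).

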