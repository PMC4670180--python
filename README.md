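# silscreen

Analysis toolkit for arrayed drug-modifier (synthetic-lethality) siRNA
screens, implemented as a tested, reusable pipeline:

1. **Primary screen** — per-plate viability normalization against GL2
   negative-control wells (`V = FI_well / mean FI_GL2`), sensitization
   index (`SI = mean V_drug / mean V_vehicle`), empirical-Bayes moderated
   t-test on log2 V with Benjamini-Hochberg FDR control, and hit calling
   at `SI <= 0.85` and `FDR < 10%`.
2. **Deconvolution** — re-screening hits with 4 individual siRNAs per
   gene; a gene validates when >= 2 of 4 siRNAs have average `SI <= 0.85`;
   the two lowest-SI siRNAs become the gene's "best-two" pool.
3. **Knockdown confirmation** — ddCt arithmetic
   (`knockdown% = (1 - 2^-ddCt) * 100`) with a >= 70% filter.
4. **Specificity** — best-two pools re-screened under a counter drug;
   genes sensitizing to both drugs are removed.
5. **Expression-sensitivity correlation** — 4PL dose-response fits per
   cell line (GraphPad parameterization), viability interpolated at a
   reference dose, Spearman correlation of delta-Ct vs. sensitivity with
   exact permutation p-values for small panels.
6. **Cohort relevance** — tumor vs. normal anti-log fold-change with an
   equal-variance two-tailed t-test; selection at fold-change >= 1.5 and
   p < 0.05.
7. **Synergy** — Chou-Talalay median-effect fits and combination-index
   analysis for constant-molar-ratio designs, plus the percent-scale
   Bliss additivity expectation for fold-change readouts.

A synthetic-data module (`silscreen.simdata`) generates screens, qPCR,
dose-response, and cohort-expression data with known planted ground
truth, so the full funnel is verifiable end to end with no external
downloads. The packaged `funnel_default` fixture plants effects whose
recovered stage counts are 638 genes -> 84 primary hits -> 40 validated
(44 removed) -> 31 knockdown-confirmed -> 29 drug-specific (2
counter-drug-common) -> 4 panel-predictive -> 5 cohort-overexpressed ->
5 final candidates.

## CLI

```bash
# full funnel on the packaged fixture (report.json + report.md + tables)
silscreen funnel --fixture funnel_default --seed 20151 --out-dir out/

# write a synthetic screen to disk, then analyze it from the files
silscreen simulate --fixture funnel_default --seed 1 --out-dir sim/
silscreen screen --platemap sim/platemap.csv \
    --measurements sim/measurements.csv --out hits.csv

# other subcommands: deconv, qpcr, doseresp, synergy, cohort
silscreen --help
```

File schemas (CSV, long format; gzip accepted):

* plate map — `plate_id, well_id, payload_type, payload_id, si_key,
  sirna_ids, pooled`
* measurements — `plate_id, well_id, arm, replicate, fi`
* Ct table — `gene_id, sample_id, condition, target, ct`
* dose-response — `cell_line, dose_molar, replicate, viability_pct`
* cohort expression — TSV, probes x samples, two-line header
  (sample id, group in {tumor, normal})

## Notes on conventions

* The moderated test estimates its variance-shrinkage hyper-parameters
  (prior df `d0`, prior variance `s0^2`) by moment matching of `log s^2`
  with digamma/trigamma inversion; `prior_df=0` reduces exactly to the
  ordinary two-sample t-test and `prior_df=inf` to complete variance
  pooling. Testing is on log2 V; SI is reported on the natural scale.
* Thresholds are inclusive where the screen's selection rules are
  inclusive: `SI <= 0.85`, knockdown `>= 70%`, fold-change `>= 1.5`;
  FDR and p-value cuts are strict (`< 0.10`, `< 0.05`).
* The combination index uses the mutually-exclusive two-term form by
  default (`exclusive=False` adds the cross term); fa values outside
  (0.01, 0.99) are excluded from median-effect regression, not clipped.
* Bliss additivity is computed literally on the percent-like fold-change
  scale (`fc_a + fc_b*(100-fc_a)/100`), as used for flow-cytometry
  fold-change readouts.
* In `select_predictive`, "inverse" marks genes whose *expression* is
  inversely correlated with drug sensitivity (rho(delta-Ct, viability) <
  0, since delta-Ct is inversely related to expression and viability to
  sensitivity) — the actionable direction for a second-site target.
* Final candidates = (cohort-overexpressed specific hits minus the
  configured direct-drug-target exclusion list) union inverse-correlated
  predictive genes; the rule is a documented interpretation and is
  recorded in every report.
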