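# itscore

Construction, scoring, and outcome evaluation of a combinatorial
immunotherapy-response gene signature, with a seeded synthetic-cohort
generator for end-to-end validation.

Response to immune checkpoint blockade tracks several tumor axes at once:
cytotoxic T-lymphocyte (CTL) infiltration, tumor mutation burden (TMB), and
TGF-β-driven immunosuppression. `itscore` implements a pipeline that combines
the three into a single gene signature and score:

1. **Construct** — screen every gene for positive Spearman correlation with a
   CTL score (mean log2 expression of CD8A, CD8B, GZMA, GZMB, PRF1; rho > 0.3,
   BH FDR < 0.01), for up-regulation in the high vs low TMB tertile (rank-sum,
   FDR < 0.01), and for correlation with a TGF-β response score. The signature
   is `(CTL-correlated ∩ TMB-associated) \ TGF-β-correlated`.
2. **Score** — per-sample single-sample GSEA (rank-weighted running sum,
   computed in closed form), with z-score and PLAGE (first singular vector)
   alternatives.
3. **Evaluate** — median-split Kaplan-Meier curves, log-rank test, Cox
   proportional hazards (Efron ties), responder AUC, IPCW time-dependent AUC
   over a follow-up window, and gene-subsampling robustness.
4. **Associate** — linear mixed-model scan of per-sample features against the
   score (likelihood-ratio tests, conditional R², BH FDR).
5. **Simulate** — a generator that plants the whole structure (latent immune /
   mutational / suppression factors, gene blocks, Weibull survival, logistic
   response) so every step can be validated against a known truth.

## Worked example

```python
from itscore import (CohortConfig, GeneSet, build_signature, generate_cohort,
                     ssgsea_score, stratify_survival, truth_overlap_report)

cohort = generate_cohort(CohortConfig(seed=42))     # 2000 genes x 300 samples
tgfb = GeneSet("tgfb_response", cohort.truth.tgfb_block)
sig = build_signature(cohort.expression, cohort.clinical, tgfb)

print(sig.set_sizes)
# {'ctl_passed': 119, 'tmb_passed': 120, 'tgfb_excluded': 40, 'final': 60}
print(truth_overlap_report(sig.gene_set, cohort.truth))
# sensitivity 1.000, false discovery proportion 0.000, retained suppressors 0

sv = ssgsea_score(cohort.expression.log2(), sig.gene_set)
strat = stratify_survival(sv, cohort.clinical, adjust=("age", "sex"))
print(strat.logrank_p, strat.hr)
# log-rank p = 3.1e-09, HR (high vs low) = 0.44 [0.33, 0.58]
```

The `examples/` directory walks through each capability as a narrative
script: `01_simulate_and_build.py`, `02_score_and_evaluate.py`,
`03_robustness.py`, `04_feature_association.py`. With 80% of the signature's
genes dropped at random, the subset score still rank-correlates with the full
score at a median of 0.95 (`examples/03_robustness.py`).

## Command line

Every step is also a CLI subcommand over plain TSV/GMT/JSON files, with
byte-deterministic outputs for a given config and seed:

```bash
itscore simulate --seed 7 --out-dir cohort/
itscore build    --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
                 --tgfb tgfb.gmt --out-dir sig/
itscore score    --expr cohort/expression.tsv --gmt sig/its.gmt --out scores.tsv
itscore evaluate --scores scores.tsv --clinical cohort/clinical.tsv \
                 --adjust age,sex --out-dir eval/
itscore associate --scores scores.tsv --features features.tsv \
                  --clinical cohort/clinical.tsv --out associations.tsv
```

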