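# lncnet

Identification of clinically-relevant lncRNA–mRNA co-expression networks
and candidate "master regulator" lncRNAs in paired tumor/non-tumor
expression cohorts (e.g. hepatocellular carcinoma microarray profiles),
together with a synthetic-cohort generator that makes every stage of the
analysis verifiable by parameter recovery.

## Who this is for

Cancer transcriptomics groups with a paired tumor (T) / non-tumor (NT)
expression matrix, per-patient clinical data and a feature annotation who
want to go from normalized intensities to an interpretable set of
lncRNA-anchored co-expression networks linked to clinical phenotypes —
without hand-wiring a dozen scripts.

## The method

1. **Preprocessing** — detection-flag filtering (keep features called
   Present/Marginal in ≥ 50% of samples) and quantile normalization.
2. **Differential expression** — paired Student *t*-test on per-patient
   T − NT log2 differences; Benjamini–Hochberg FDR *q* < 0.05 and signed
   linear fold change |FC| ≥ 2.
3. **Clinical association** — eight raw characteristics collapsed into
   five groups (tumor properties, grade, capsule, invasion, overall
   survival), dichotomized good/poor; tumor expression tested per group
   (pooled-variance *t*-test, |FC| ≥ 1.5, unadjusted *p* < 0.05;
   univariate Cox with Breslow ties for survival; a logistic mode for
   validation cohorts). A feature is *potentially oncogenic* when
   up-regulated in tumors **and** higher in a poor-phenotype group, and a
   *potential tumor suppressor* in the mirrored case.
4. **Guilt-by-association** — all-pairs Pearson correlation between DE
   lncRNAs and DE mRNAs; pairs with |R| ≥ 0.9 are "strong", with *cis*
   annotation when the mRNA is the lncRNA's nearest protein-coding gene.
5. **Networks** — connected components of the bipartite graph restricted
   to clinically-relevant lncRNAs, classified oncogenic / suppressive /
   mixed and scored for clinical *concordance* (fraction of member mRNAs
   sharing a direction-concordant significant clinical group with a
   correlated lncRNA). *Master regulators*: the minimal lncRNA subset of
   a large (≥ 20 mRNAs), concordant (> 80%), pathway-enriched component
   whose partners cover the component's mRNAs (greedy set cover).
6. **Enrichment** — exact hypergeometric over-representation of network
   mRNAs against GMT gene sets, *p* < 0.01.
7. **Validation helpers** — cross-cohort sign/trend concordance and
   integration of lncRNA-overexpression DE tables with patient-cohort
   correlations (|FC| ≥ 2 ∩ |R| ≥ 0.6, same direction).

The synthetic generator plants co-expression modules through a shared
per-sample latent factor (`x = μ + b·z + Δ·1[T] + ε`, within-module
correlation `r = b²/(b²+σ²)`), tumor shifts, phenotype links (labels
thresholded on the patient's tumor latent factor) and proportional-hazards
survival, and emits a machine-readable truth record for recovery tests.

## Worked example

```python
import lncnet as L

cfg = L.SimConfig(
    n_patients=12, n_lnc=30, n_mrna=40, feature_noise_sd=0.2,
    modules=[L.ModuleSpec(3, 5, target_r=0.95, tumor_shift=1.5,
                          linked_group="grade", phenotype_effect=1.0)],
    seed=7,
)
cohort = L.generate_cohort(cfg)
result = L.run_pipeline(cohort.expression, cohort.design, cohort.clinical,
                        cohort.annotation, cohort.gene_sets,
                        L.RunConfig(min_mrna=3))
s = result.summary
print("DE lncRNAs:", s["de"]["lncRNA"])
print("DE mRNAs:  ", s["de"]["protein_coding"])
print("strong pairs:", s["n_pairs"], "(cis:", s["n_cis_pairs"], ")")
print("clinically relevant lncRNAs:", s["relevant_lnc"])
for c in s["components"]["per_component"]:
    print("component:", c["cls"], len(c["lnc_ids"]), "lncRNAs x",
          len(c["mrna_ids"]), "mRNAs, concordance", c["concordance"],
          "master set", c["master_set"], "enriched", c["enriched_sets"])
```

prints

```
DE lncRNAs: {'up': 3, 'down': 0, 'total': 3}
DE mRNAs:   {'up': 6, 'down': 2, 'total': 8}
strong pairs: 11 (cis: 1 )
clinically relevant lncRNAs: {'oncogenic': 3, 'suppressor': 0, 'total': 3}
component: oncogenic 3 lncRNAs x 5 mRNAs, concordance 1.0 master set ['LNC00001'] enriched ['MODULE0_PATHWAY']
```

The planted 3-lncRNA × 5-mRNA grade-linked module is recovered as one
oncogenic component whose mRNAs all share the lncRNAs' clinical
association (concordance 1.0); a single lncRNA suffices to cover every
member mRNA, and the module's planted pathway is the enriched gene set.

A command-line interface mirrors the library
(`lncnet simulate|de|clin|corr|network|enrich|validate|perturb|run`);
`lncnet run --config run.yaml --out rundir/` writes one inspectable TSV,
SIF or JSON file per stage plus a count summary, and is byte-reproducible
for identical inputs.

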