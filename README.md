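# tastecourse

Stage-series transcriptome analysis for taste organoid growth experiments —
and, more generally, for any two-replicate bulk RNA-seq time course measured
as gene-level counts.

Taste organoids grown from Lgr5+/Lgr6+ stem/progenitor cells mature over
roughly two weeks: proliferation genes dominate early, taste receptors and
transduction components appear only in late-stage organoids. The analysis
this package implements asks three questions of a series sampled at days
2, 4, 6, 8, 10, 12 and 14 in two independent replicates:

1. **Which temporal shapes exist?** After RPKM quantification
   (`rpkm = 10^9 · count / (mapped_total · length)`), low-expression genes are
   trimmed (day-14 RPKM ≥ 0.2 and cross-stage RPKM sum > 0.2), profiles are
   log-transformed (`log2(RPKM + 1)`) and centered per gene, and restarted
   K-means (K = 4, 30 starts, 30,000 max iterations) groups genes into four
   archetypes: a steep **late rise** (receptor-like genes), an **early rise**
   that slows late (signalling/differentiation genes), **flat** profiles, and
   an **early drop** between days 4 and 6 (proliferation genes). Hierarchical
   clustering of the stage columns shows the early/late structure of the
   series (days 2–8 vs 10–14 as the two root branches).
2. **Which genes change reproducibly?** Clusters of the two replicates are
   matched (optimal assignment on centroid distance, or archetype-label
   identity) and intersected into consensus sets; per gene, a log-link
   negative-binomial GLM (variance `μ + φμ²`) is fitted with
   `~ stage + replicate` against `~ replicate`, and the ANOVA-like
   likelihood-ratio statistic `2(ℓ_full − ℓ_reduced)` is referred to χ²(6),
   with Benjamini–Hochberg FDR control at 0.05. Dispersion is estimated by
   Cox–Reid adjusted profile likelihood (genewise, common, or genewise shrunk
   toward the common curve — the default).
3. **What are those genes?** Consensus sets are scored against GMT gene-set
   collections with the one-sided hypergeometric tail `P(X ≥ k)` and a
   Benjamini column, producing DAVID-style chart records.

A seeded synthetic-data generator emulates the study's statistical structure
(four archetypes in the observed proportions, NB count noise with gene-wise
dispersion, correlated replicates, and a planted "taste transduction"-like
category enriched in late-rise genes), so the full pipeline is testable
without any sequencing data.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
import tastecourse as tc

rep_a, rep_b, truth, _ = tc.generate_dataset(tc.SimConfig(n_genes=2000, seed=1))
rpkm_a, rpkm_b = tc.compute_rpkm(rep_a), tc.compute_rpkm(rep_b)
report = tc.trim_genes(rpkm_a, rpkm_b)

model = tc.kmeans_cluster(tc.log_normalize(report.apply(rpkm_a)), k=4, seed=7)
tc.label_archetypes(model, tc.default_archetypes())
print({model.archetype_labels[c]: n for c, n in model.sizes().items()})
print(adjusted_rand_score(truth.archetype, model.assignments))
```

prints

```
{'flat': 1371, 'late_rise': 76, 'early_drop': 273, 'early_rise': 280}
0.9723...
```

— the four clusters recover the planted archetype sizes, and an adjusted Rand
index of 0.97 means cluster membership almost perfectly matches the planted
labels. The `examples/` directory has one short script per capability
(clustering, differential testing, enrichment, full pipeline); each prints
the numbers it computes with a note on what they mean.

The whole pipeline runs as one call (or `tastecourse run-all` from a shell):

```python
result = tc.run_pipeline(tc.RunConfig(outdir="run", seed=42))
print(result.manifest["n_significant"])      # genes with a stage effect
print(result.charts["cluster1"].iloc[0])     # top enrichment record
```

Re-running with the same `RunConfig` reproduces byte-identical manifests; one
root seed derives every stage seed.

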