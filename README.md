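# sarcotype

Transcriptomic subtype discovery and prognostic benchmarking for
soft-tissue sarcoma (STS) expression cohorts.

High-grade STS (dedifferentiated liposarcoma, leiomyosarcoma,
undifferentiated pleomorphic sarcoma) is classified morphologically, which
correlates only loosely with outcome. An alternative is to let the
transcriptome define the subtypes: cluster a discovery cohort's RNA-seq
profiles, derive per-cluster gene signatures, classify external samples by
single-sample enrichment against those signatures, and ask whether the
resulting labels carry prognostic information beyond clinical nomograms and
published expression signatures. `sarcotype` implements that full analysis
as a tested, reusable pipeline, together with a synthetic-cohort generator
so every stage can be exercised without access to patient data.

## What the pipeline computes

1. **Preprocessing** (`sarcotype.preprocess`) — low-expression filtering
   (CPM ≥ 1 in ≥ 20% of samples), log₂-CPM transform
   `log2((count + 0.5)/(libsize + 1)·1e6)` with precision weights
   `w = ŝ(fitted log-count)⁻⁴` from a lowess mean–variance trend, optional
   quantile normalization, and a median-absolute-deviation filter keeping
   the top 55% most variable genes.
2. **Subtype discovery** (`sarcotype.consensus`) — resampled consensus
   clustering: each resample draws 80% of samples, clusters them by
   average-linkage hierarchical clustering on 1 − Pearson correlation, and
   the consensus matrix M_k(i,j) records co-clustering fractions. The
   number of clusters k\* is chosen where the area A(k) under the CDF of
   consensus entries stops growing (elbow: maximal deviation of (k, A(k))
   from the chord through (1, 0) and (k_max, A(k_max))).
3. **Signatures** (`sarcotype.signatures`) — pairwise moderated-t
   differential expression (weighted least squares with empirical-Bayes
   variance shrinkage, s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)), BH-FDR per
   contrast, and same-direction intersection across all contrasts into the
   2k gene sets `C{c}_over` / `C{c}_under`.
4. **Classification** (`sarcotype.enrichment`) — single-sample gene-set
   enrichment: rank-weighted running-sum ES per (sample, set), standardized
   against a gene-permutation null (NES), normal two-sided p, BH across all
   scored sets per sample; each sample is assigned to the cluster of the
   most significant signature set with adjusted p < 0.05, else UNASSIGNED.
5. **Survival** (`sarcotype.survival`) — Kaplan–Meier, k-group log-rank,
   Cox proportional hazards (Newton–Raphson on the Efron partial
   likelihood), Grambsch–Therneau tests on scaled Schoenfeld residuals,
   sequential likelihood-ratio ANOVA, and Harrell's concordance index.
6. **Benchmarking** (`sarcotype.benchmark`) — apparent (and optionally
   cross-validated) C-index tables over prognostic model specifications
   (clusters, age, an external 5-year-OS risk score, comparator
   classifications), sub-stratification of nomogram risk groups at the
   predicted 5-year OS = 60% boundary, gene-set overlap, and Spearman
   correlation of NES vectors.

The synthetic generator (`sarcotype.simulate`) plants the structure the
analysis assumes: negative-binomial counts (variance μ + φμ²) with
per-subtype over/under marker blocks at a controlled log₂ effect,
subtype-dependent exponential survival with administrative and dropout
censoring, clinical covariates, a noisy nomogram-style 5-year-OS risk
score, and comparator gene lists with controlled signature overlap.

## Worked example

```python
import pandas as pd
from sarcotype import *

# discovery cohort with four planted subtypes
cohort = gen_cohort(CohortConfig(seed=7))
norm = normalize(expression_filter(cohort.counts))
result = discover_subtypes(mad_filter(norm), k_range=range(2, 9),
                           n_resamples=250, seed=7)
print("selected k* =", result.k_star)
print("CDF areas:", {k: round(a, 3) for k, a in result.A.items()})

sig = derive_signatures(all_pairwise_de(norm, result.labels))
print("signature sizes:", {n: len(s) for n, s in sorted(sig.sets.items())})

# classify an independent cohort drawn from the same generative truth
external = gen_cohort(CohortConfig(seed=13))
norm_ext = normalize(expression_filter(external.counts), quantile=True)
enrich = score_cohort(norm_ext.logexpr, dict(sig.sets), n_perm=1000, seed=13)
calls = classify_samples(enrich, sig.names())
print("assigned:", (calls.assigned_cluster != UNASSIGNED).sum(), "/", len(calls))

# prognostic value of the transferred labels
data = external.clinical.join(
    calls.assigned_cluster.map("C{}".format).rename("cluster"))
table = compare_models(
    data,
    [ModelSpec("TC", ["cluster"]), ModelSpec("AGE", ["age_years"]),
     ModelSpec("TC+AGE", ["cluster", "age_years"])],
    time_col="os_months", event_col="os_event")
print(table[["c_index", "n_events"]].round(3))
```

which prints:

```
selected k* = 4
CDF areas: {2: 0.378, 3: 0.63, 4: 0.756, 5: 0.761, 6: 0.766, 7: 0.771, 8: 0.776}
signature sizes: {'C1_over': 40, 'C1_under': 41, 'C2_over': 40, 'C2_under': 40, 'C3_over': 40, 'C3_under': 40, 'C4_over': 40, 'C4_under': 40}
assigned: 120 / 120
        c_index  n_events
model
TC+AGE    0.575        92
TC        0.573        92
AGE       0.503        92
```

The CDF-area curve climbs steeply to k = 4 (the planted subtype count) and
plateaus; the derived signatures recover the 40-gene marker blocks (plus
one borderline gene in `C1_under`); every external sample is assigned, and
the transcriptomic-cluster (TC) model outranks age alone on Harrell's C for
overall survival.

The same analysis runs from the shell:

```sh
sarcotype simulate --seed 7 --outdir cohortA
sarcotype preprocess --counts cohortA/counts.tsv --outdir prep
sarcotype discover --norm prep/logexpr.tsv --weights prep/weights.tsv \
    --resamples 250 --seed 7 --outdir disc
sarcotype run-all --seed 7 --outdir full_run     # end-to-end, both cohorts
```

`run-all` persists every stage artifact (consensus matrices, A(k) table,
labels, DE tables, signatures GMT, enrichment table, calls, Cox summaries,
Schoenfeld diagnostics, C-index table) plus the resolved configuration and
seed; reruns with the same configuration are bit-identical.

## Layout

- `src/sarcotype/` — library modules (`simulate`, `preprocess`,
  `consensus`, `signatures`, `enrichment`, `survival`, `benchmark`,
  `io`, `config`, `pipeline`, `cli`)
- `tests/` — pytest suite; oracle-based unit tests, property tests, and
  pipeline-level acceptance checks
- `docs/methods.md` — the modeling and numerical choices in detail
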