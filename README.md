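# epileptome

Screening pipeline for blood-leukocyte transcriptome correlates of epilepsy
duration and age at seizure onset.

Epilepsy duration and onset age are routinely recorded clinical parameters
whose molecular correlates in peripheral blood are poorly characterized.
Given a normalized bulk RNA-seq expression matrix (CPM, genes × samples) and
per-patient clinical covariates, this package identifies genes whose
expression tracks disease chronicity or onset timing in a small cohort,
while guarding against the dominant confounder in blood transcriptomics:
chronological age, which is tightly entangled with disease duration
(onset age + duration ≈ age at sampling).

## What it computes

* **Preprocessing** — genes are retained when CPM > 1 in at least 50 % of
  samples; values become log₂(CPM + c) with the dataset-derived pseudocount
  c = min(nonzero CPM)/1000.
* **Cohort comparison** — patients are stratified at a threshold on a
  clinical variable (duration ≤/> 20 y; onset ≤/> 12 y) and every clinical
  variable is compared between strata with a two-sided Mann–Whitney U test
  (midranks, tie-corrected variance, 0.5 continuity correction, normal
  approximation; an exact permutation mode is available).
* **Differential expression** — per gene, log₂FC = mean(log₂, high group) −
  mean(log₂, low group) with Welch's t-test (rank-sum optional); volcano
  labels `up`/`down` when p < 0.05 and |log₂FC| > 0.5.
* **Correlation screen** — per gene, Spearman's ρ against the trait in raw
  years, two-sided p from t = ρ√((n−2)/(1−ρ²)) with n−2 df; flagged when
  |ρ| > 0.5 and p < 0.05. A published list of age-associated blood genes can
  be excluded from the reported view.
* **Partial Spearman correlation** — expression and trait are each replaced
  by OLS residuals against age at sampling, gender, and etiology
  (indicator-coded, most frequent level as reference), and the residual
  vectors are rank-correlated — the covariate-adjusted association.
* **Directional overlaps** — intersections such as duration-positive ∩
  onset-negative gene sets.
* **Band enrichment** — hypergeometric upper-tail over-representation of a
  gene list on cytogenetic bands with Benjamini–Hochberg adjustment,
  computed locally.

A synthetic-data module generates cohorts and expression matrices with known
ground truth (null, duration-, onset- and age-driven genes) for calibration
and recovery testing, and packages the 16-patient temporal-lobe-epilepsy
clinical table the defaults are modelled on.

## Worked example

```python
import epileptome as ep
from epileptome.association import partial_spearman, screen_genes
from epileptome.synthetic_data import SpikeSpec

clinical = ep.fixture_clinical_table()
split = ep.stratify(clinical, "duration", 20)
report = ep.clinical_comparison_table(clinical, split)
age = report.variables["age"]
print(f"age, short-duration group: mean {age.low.mean:.2f}, sd {age.low.std_dev:.2f}")
print(f"age, long-duration group:  mean {age.high.mean:.2f}, sd {age.high.std_dev:.2f}")
print(f"rank-sum p = {age.test.p:.4f}")

matrix, truth = ep.generate_expression(clinical, SpikeSpec(seed=1))
log_matrix, pc = ep.preprocess(matrix)
print(f"retained {log_matrix.n_genes}/{matrix.n_genes} genes, pseudocount {pc:.3g}")

duration = clinical.values_for("duration", log_matrix.sample_ids)
screen = screen_genes(log_matrix, duration)
partial = partial_spearman(log_matrix, duration, clinical)
```

Output:

```
age, short-duration group: mean 29.62, sd 9.75
age, long-duration group:  mean 49.25, sd 11.04
rank-sum p = 0.0073
retained 1986/2000 genes, pseudocount 0.000265
```

The two duration strata (8 vs 8 patients) differ in age at sampling
(p = 0.0073) — exactly the entanglement the partial correlation adjusts
for. On this simulation the plain screen flags 90 % of the purely
age-driven genes as duration-correlated; after covariate adjustment only
15 % remain flagged, while 39 of the 40 spiked duration genes that survive
expression filtering are recovered.

The same pipeline is available from the shell:

```sh
epileptome simulate --n-genes 2000 --seed 1 \
    --out-expr sim.tsv --out-clinical cohort.tsv --out-truth truth.tsv
epileptome preprocess --expr sim.tsv --out filtered_log2.tsv
epileptome clinical-stats --clinical cohort.tsv --variable duration --threshold 20 --out table.tsv
epileptome run-all --config run.yaml     # all stages + manifest.json
```

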