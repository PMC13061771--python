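"""Synthetic cohorts and expression matrices with known ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: a small clinical cohort in which onset age plus disease duration
equals age at sampling (so age and duration are naturally entangled), and
a log-normal expression matrix containing

* null genes (baseline + noise),
* genes with a linear log-scale dependence on epilepsy duration or onset
  age (positive or negative slope), and
* age-confounded genes driven purely by age at sampling — the class the
  partial-correlation adjustment exists to demote.

Matrices are exported on the CPM-like scale ``2**log2value`` (strictly
positive), so the pseudocount/log-transform path is exercised end to end.
A packaged 16-patient clinical fixture with the cohort's published
covariates is included for deterministic tests and examples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix

__all__ = [
    "SpikeSpec",
    "GENE_CLASSES",
    "fixture_clinical_table",
    "generate_cohort",
    "generate_expression",
]

# 16-patient temporal lobe epilepsy cohort (GSM accession, seizures/month,
# gender, age, duration and onset age in years, etiology abbreviation).
_FIXTURE_TSV = """\
sample_id\tseizure_frequency\tgender\tage\tduration\tonset_age\tetiology
GSM6725527\t1\tM\t26\t4\t22\tUnk
GSM6725534\t60\tM\t19\t7\t12\tTBI
GSM6725528\t0.33\tF\t32\t8\t24\tCVA
GSM6725532\t4\tF\t45\t8\t37\tAbor
GSM6725529\t4\tM\t16\t10\t6\tUnk
GSM6725530\t1\tF\t35\t13\t22\tUnk
GSM6725524\t3\tM\t38\t17\t21\tUnk
GSM6725537\t1\tM\t26\t19\t7\tUnk
GSM6725536\t2\tM\t32\t25\t7\tUnk
GSM6725525\t0.25\tM\t37\t35\t2\tUnk
GSM6725531\t1\tF\t54\t36\t18\tEcl
GSM6725538\t4\tM\t45\t37\t8\tUnk
GSM6725539\t2\tF\t58\t37\t21\tUnk
GSM6725533\t2\tM\t46\t43\t3\tUnk
GSM6725526\t0.25\tM\t60\t47\t13\tUnk
GSM6725535\t2\tF\t62\t61\t1\tInf
"""

#: recognised ground-truth gene classes
GENE_CLASSES = (
    "null",
    "duration_pos",
    "duration_neg",
    "onset_pos",
    "onset_neg",
    "age_confounded",
)


def fixture_clinical_table() -> ClinicalTable:
    """The packaged 16-patient clinical table, keyed by GSM accession."""
    df = pd.read_csv(io.StringIO(_FIXTURE_TSV), sep="\t", dtype=str)
    return ClinicalTable(df)


def generate_cohort(n: int, seed: int) -> ClinicalTable:
    """Random cohort with the fixture's covariate structure.

    Ages uniform on [16, 62] years; onset age uniform on [1, age - 3];
    duration = age - onset age exactly, reproducing the natural negative
    onset/duration coupling; gender Bernoulli(1/2); etiology drawn from
    the fixture's empirical label frequencies; seizure frequency
    log-uniform on [0.25, 60] seizures/month.
    """
    if n < 6:
        raise ValueError("need at least 6 samples for a meaningful cohort")
    rng = np.random.default_rng(seed)
    age = rng.uniform(16.0, 62.0, size=n)
    onset = rng.uniform(1.0, age - 3.0)
    duration = age - onset
    gender = rng.choice(["F", "M"], size=n)
    fixture = fixture_clinical_table().data
    labels = fixture["etiology"].value_counts(normalize=True)
    etiology = rng.choice(labels.index.to_numpy(), size=n, p=labels.to_numpy())
    freq = np.exp(rng.uniform(np.log(0.25), np.log(60.0), size=n))
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(1, n + 1)],
            "seizure_frequency": freq,
            "gender": gender,
            "age": age,
            "duration": duration,
            "onset_age": onset,
            "etiology": etiology,
        }
    )
    return ClinicalTable(df)


@dataclass(frozen=True)
class SpikeSpec:
    """Composition and effect sizes of a generated expression matrix.

    Defaults: 2000 genes of which 20 per spiked class; slopes of
    +-0.05 log2 units per year of the driving variable against noise of
    0.5 log2 units, placing spiked genes near |Spearman r| ~ 0.7 at
    n = 16 — strong enough for stable recovery, weak enough that the
    joint |r| > 0.5 and p < 0.05 rule is not trivially saturated.
    Baselines are N(5, 2) on the log2 CPM scale.
    """

    n_genes: int = 2000
    n_duration_pos: int = 20
    n_duration_neg: int = 20
    n_onset_pos: int = 20
    n_onset_neg: int = 20
    n_age_confounded: int = 20
    effect: float = 0.05
    noise_sd: float = 0.5
    baseline_mean_log2: float = 5.0
    baseline_sd_log2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_duration_pos,
            self.n_duration_neg,
            self.n_onset_pos,
            self.n_onset_neg,
            self.n_age_confounded,
        )
        if any(c < 0 for c in counts) or self.n_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if sum(counts) > self.n_genes:
            raise ValueError("spiked classes exceed the total gene count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_null(self) -> int:
        return self.n_genes - (
            self.n_duration_pos
            + self.n_duration_neg
            + self.n_onset_pos
            + self.n_onset_neg
            + self.n_age_confounded
        )


def generate_expression(
    clinical: ClinicalTable, spec: SpikeSpec = SpikeSpec()
) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression matrix plus per-gene ground-truth classes.

    On the log2 scale each gene is ``baseline + beta * driver + noise``
    with driver = duration, onset age, or age by class and beta = +-effect
    (0 for null genes).  The returned matrix is ``2**log2`` (CPM-like,
    strictly positive).  The truth table is a Series gene_id -> class.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = clinical.n_samples
    drivers = {
        "duration": clinical.values_for("duration"),
        "onset_age": clinical.values_for("onset_age"),
        "age": clinical.values_for("age"),
    }
    classes = (
        ["duration_pos"] * spec.n_duration_pos
        + ["duration_neg"] * spec.n_duration_neg
        + ["onset_pos"] * spec.n_onset_pos
        + ["onset_neg"] * spec.n_onset_neg
        + ["age_confounded"] * spec.n_age_confounded
        + ["null"] * spec.n_null
    )
    driver_of = {
        "duration_pos": ("duration", +1.0),
        "duration_neg": ("duration", -1.0),
        "onset_pos": ("onset_age", +1.0),
        "onset_neg": ("onset_age", -1.0),
        "age_confounded": ("age", +1.0),
        "null": (None, 0.0),
    }
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]

    baselines = rng.normal(spec.baseline_mean_log2, spec.baseline_sd_log2, size=spec.n_genes)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    log2 = baselines[:, None] + noise
    for i, cls in enumerate(classes):
        driver, sign = driver_of[cls]
        if driver is not None:
            log2[i] += sign * spec.effect * drivers[driver]

    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.exp2(log2), index=pd.Index(gene_ids, name="gene_id"), columns=clinical.sample_ids
        ),
        log_scale=False,
    )
    truth = pd.Series(classes, index=pd.Index(gene_ids, name="gene_id"), name="class")
    return matrix, truth
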