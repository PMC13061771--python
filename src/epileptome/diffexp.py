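"""Two-group differential expression on the log2 matrix with volcano labels.

The effect size is the difference of group means on the log2 scale
(high/late-stratum mean minus low/early-stratum mean), i.e. the log2 of a
ratio of geometric means of CPM — not a ratio of arithmetic means.  The
per-gene p-value comes from Welch's unequal-variance t-test by default,
with the tie/continuity-corrected rank-sum test as an option.  Genes are
labelled ``up`` / ``down`` when p < 0.05 and |log2 fold change| > 0.5
(strict inequalities), otherwise ``ns``.  Raw p-values are used for the
labels; Benjamini-Hochberg adjusted values can be added alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import StratifiedCohort, rank_sum_test
from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["DeParams", "group_de", "classify_volcano", "differential_expression"]

#: columns of a differential-expression record table
DE_SCHEMA = ("gene_id", "log2_fc", "p", "status")


@dataclass(frozen=True)
class DeParams:
    """Volcano thresholds and test choice (p < 0.05, |log2FC| > 0.5 defaults)."""

    p_threshold: float = 0.05
    lfc_threshold: float = 0.5
    test: str = "welch_t"

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.test not in ("welch_t", "mann_whitney"):
            raise ValueError("test must be 'welch_t' or 'mann_whitney'")


def _welch_p(high: np.ndarray, low: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(high, low, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant: 0/0 -> nan; equal means => no evidence (p=1),
    # unequal means with zero variance => t is infinite (p=0)
    zero_var = (np.var(high, axis=1) == 0) & (np.var(low, axis=1) == 0)
    if zero_var.any():
        equal = np.isclose(high.mean(axis=1), low.mean(axis=1))
        p[zero_var & equal] = 1.0
        p[zero_var & ~equal] = 0.0
    return p


def group_de(
    log_matrix: ExpressionMatrix,
    cohort: StratifiedCohort,
    params: DeParams = DeParams(),
) -> pd.DataFrame:
    """Per-gene log2 fold change (high minus low group) and p-value.

    Returns one row per gene in input order with columns
    ``gene_id, log2_fc, p`` (status is added by :func:`classify_volcano`).
    """
    if not log_matrix.log_scale:
        raise ValueError("group_de expects a log2-transformed matrix")
    if len(cohort.group_low) < 2 or len(cohort.group_high) < 2:
        raise ValueError("each group needs at least 2 samples")
    low = log_matrix.subset_samples(cohort.group_low).values
    high = log_matrix.subset_samples(cohort.group_high).values

    log2_fc = high.mean(axis=1) - low.mean(axis=1)
    if params.test == "welch_t":
        p = _welch_p(high, low)
    else:
        p = np.array(
            [rank_sum_test(h, l).p for h, l in zip(high, low)], dtype=float
        )
    return pd.DataFrame(
        {"gene_id": log_matrix.gene_ids, "log2_fc": log2_fc, "p": p}
    )


def classify_volcano(records: pd.DataFrame, params: DeParams = DeParams()) -> pd.DataFrame:
    """Attach ``status`` in {up, down, ns} by the joint p/|log2FC| rule."""
    records = records.copy()
    sig = records["p"] < params.p_threshold
    up = sig & (records["log2_fc"] > params.lfc_threshold)
    down = sig & (records["log2_fc"] < -params.lfc_threshold)
    records["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    logger.info(
        "volcano classification: %d up, %d down, %d ns (p<%g, |log2FC|>%g)",
        int(up.sum()),
        int(down.sum()),
        int((~(up | down)).sum()),
        params.p_threshold,
        params.lfc_threshold,
    )
    return records


def differential_expression(
    log_matrix: ExpressionMatrix,
    cohort: StratifiedCohort,
    params: DeParams = DeParams(),
    adjust: bool = False,
) -> pd.DataFrame:
    """group_de followed by volcano classification; optional BH column ``fdr``."""
    records = classify_volcano(group_de(log_matrix, cohort, params), params)
    if adjust:
        from .enrichment import bh_adjust

        records["fdr"] = bh_adjust(records["p"].to_numpy())
    return records
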