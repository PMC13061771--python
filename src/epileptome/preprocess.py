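"""Expression filtering and log transformation.

Bulk RNA-seq screening on a small cohort starts from a library-size
normalized CPM matrix.  Genes with negligible expression are removed
(detected above a CPM threshold in at least a given fraction of samples),
a dataset-derived pseudocount — the smallest non-zero value divided by
1000 — guards ``log(0)``, and the retained values are log2-transformed.
Because every downstream correlation statistic is rank-based or computed
on group means of log values, the choice of log base only rescales fold
changes; base 2 is used so fold changes read in the conventional log2
units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data_io import DataValidationError, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessParams",
    "filter_low_expressed",
    "compute_pseudocount",
    "log_transform",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Filtering/transformation parameters.

    cpm_threshold
        Expression level a sample must exceed for a gene to count as
        detected (CPM units; default 1).
    min_fraction
        Minimum fraction of samples in which the gene must be detected
        (default 0.5, i.e. at least half the cohort).
    pseudocount_divisor
        The pseudocount is min(non-zero values)/divisor (default 1000).
    comparison
        ``"gt"`` (strict ``>``, default) or ``"ge"`` at the detection
        boundary.
    """

    cpm_threshold: float = 1.0
    min_fraction: float = 0.5
    pseudocount_divisor: float = 1000.0
    comparison: str = "gt"

    def __post_init__(self) -> None:
        if self.cpm_threshold < 0:
            raise ValueError("cpm_threshold must be >= 0")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.pseudocount_divisor <= 0:
            raise ValueError("pseudocount_divisor must be > 0")
        if self.comparison not in ("gt", "ge"):
            raise ValueError("comparison must be 'gt' or 'ge'")


def filter_low_expressed(
    matrix: ExpressionMatrix, params: PreprocessParams = PreprocessParams()
) -> ExpressionMatrix:
    """Retain genes detected (> or >= threshold) in at least ceil(f*n) samples."""
    if matrix.log_scale:
        raise DataValidationError("filtering operates on raw CPM values, not log values")
    values = matrix.values
    if params.comparison == "gt":
        detected = values > params.cpm_threshold
    else:
        detected = values >= params.cpm_threshold
    min_samples = math.ceil(params.min_fraction * matrix.n_samples)
    keep = detected.sum(axis=1) >= min_samples
    logger.info(
        "expression filter (CPM %s %g in >= %d/%d samples): retained %d of %d genes",
        ">" if params.comparison == "gt" else ">=",
        params.cpm_threshold,
        min_samples,
        matrix.n_samples,
        int(keep.sum()),
        matrix.n_genes,
    )
    if not keep.any():
        logger.warning("expression filter removed every gene")
    return ExpressionMatrix(matrix.data.loc[keep].copy(), log_scale=False)


def compute_pseudocount(
    matrix: ExpressionMatrix, params: PreprocessParams = PreprocessParams()
) -> float:
    """Smallest strictly positive value of the matrix divided by the divisor."""
    values = matrix.values
    positive = values[values > 0]
    if positive.size == 0:
        raise DataValidationError("cannot derive a pseudocount from an all-zero matrix")
    return float(positive.min()) / params.pseudocount_divisor


def log_transform(matrix: ExpressionMatrix, pseudocount: float) -> ExpressionMatrix:
    """Replace every value v by log2(v + pseudocount); marks the result log-scale."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    data = np.log2(matrix.data + pseudocount)
    return ExpressionMatrix(data, log_scale=True)


def preprocess(
    matrix: ExpressionMatrix,
    params: PreprocessParams = PreprocessParams(),
    pseudocount_on_filtered: bool = True,
) -> tuple[ExpressionMatrix, float]:
    """Filter then log-transform; returns (log matrix, pseudocount used).

    The pseudocount is derived from the filtered matrix by default (the
    processing order filters first); set ``pseudocount_on_filtered=False``
    to derive it from the full input matrix instead.
    """
    filtered = filter_low_expressed(matrix, params)
    source = filtered if pseudocount_on_filtered else matrix
    pc = compute_pseudocount(source, params)
    logger.info("pseudocount: %.6g", pc)
    return log_transform(filtered, pc), pc
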