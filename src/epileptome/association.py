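"""Trait-expression correlation screening and covariate adjustment.

Every gene's expression is correlated with a clinical trait (epilepsy
duration or onset age, in raw years) by Spearman's rank correlation;
genes with |r| > 0.5 and p < 0.05 are flagged as strongly correlated.
Because chronological age drives much of the blood transcriptome and is
tightly coupled to epilepsy duration, two complementary de-confounding
devices are provided:

* exclusion of a published list of age-associated genes from the reported
  view of the screen, and
* a partial Spearman correlation: expression and trait are each replaced
  by their ordinary-least-squares residuals against a common covariate set
  (age at sampling, gender, etiology), and the residual vectors are then
  rank-correlated.

p-values use the t approximation t = r * sqrt((n-2)/(1-r^2)) with n-2
degrees of freedom (midranks for ties).  For the partial correlation the
same n-2 df are used by default — the procedure is plain Spearman applied
to residuals — with a covariate-adjusted df variant behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ClinicalTable, ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "CovariateSpec",
    "spearman",
    "spearman_matrix",
    "spearman_permutation_p",
    "screen_genes",
    "exclude_genes",
    "reported_view",
    "build_design",
    "residualize",
    "partial_spearman",
    "overlap_sets",
]


@dataclass(frozen=True)
class ScreenParams:
    """Joint flagging rule: |r| > r_threshold and p < p_threshold."""

    r_threshold: float = 0.5
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass(frozen=True)
class CovariateSpec:
    """Covariates for residualization.

    Numeric covariates enter as-is; categorical covariates are encoded as
    indicator columns dropping the most frequent level as reference.  An
    intercept is always included.
    """

    numeric: tuple[str, ...] = ("age",)
    categorical: tuple[str, ...] = ("gender", "etiology")


# ---------------------------------------------------------------------------
# Spearman core
# ---------------------------------------------------------------------------


def _t_approx_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p from t = r*sqrt(df/(1-r^2)); |r|=1 -> p=0, nan -> p=1."""
    r = np.asarray(r, dtype=float)
    p = np.ones_like(r)
    ok = np.isfinite(r)
    edge = ok & (np.abs(r) >= 1.0 - 1e-14)
    mid = ok & ~edge
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[mid] * np.sqrt(df / (1.0 - r[mid] ** 2))
    p[mid] = 2.0 * stats.t.sf(np.abs(t), df)
    p[edge] = 0.0
    return np.minimum(p, 1.0)


def spearman_matrix(values: np.ndarray, trait: np.ndarray, df: int | None = None):
    """Row-wise Spearman correlation of a (genes x samples) array with a trait.

    Midranks, Pearson on ranks, t-approximation p.  Rows (or a trait) with
    zero variance yield r = nan, p = 1.  Returns (r, p) arrays.
    """
    values = np.asarray(values, dtype=float)
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if values.ndim != 2 or values.shape[1] != n:
        raise ValueError("values must be 2-D with one column per trait entry")
    if n < 4:
        raise ValueError("need at least 4 samples for a Spearman screen")

    rx = stats.rankdata(values, axis=1)
    ry = stats.rankdata(trait)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom_y = float(np.sqrt((ry**2).sum()))
    denom_x = np.sqrt((rx**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rx @ ry) / (denom_x * denom_y)
    if denom_y == 0:
        r = np.full(values.shape[0], np.nan)
    r = np.where(denom_x == 0, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    p = _t_approx_p(r, df if df is not None else n - 2)
    return r, p


def spearman(x, y) -> tuple[float, float]:
    """Spearman correlation of two vectors with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    r, p = spearman_matrix(x[None, :], y)
    return float(r[0]), float(p[0])


def spearman_permutation_p(x, y, n_perm: int = 100_000, seed: int | None = None) -> float:
    """Permutation p-value for Spearman r: shuffle y, P(|r*| >= |r_obs|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs, _ = spearman(x, y)
    if not np.isfinite(r_obs):
        return 1.0
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array([rng.permutation(ry) for _ in range(n_perm)])
    r_perm, _ = spearman_matrix(perms, rx)
    return float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))


# ---------------------------------------------------------------------------
# genome-wide screen
# ---------------------------------------------------------------------------

#: columns of a correlation screen record table
SCREEN_SCHEMA = ("gene_id", "r", "p", "flagged", "direction", "age_associated")


def screen_genes(
    matrix: ExpressionMatrix,
    trait: np.ndarray,
    params: ScreenParams = ScreenParams(),
) -> pd.DataFrame:
    """Spearman screen of every gene against a per-sample trait vector.

    ``trait`` must be ordered like ``matrix.sample_ids``.  Returns one row
    per gene in input order with columns ``gene_id, r, p, flagged,
    direction`` (direction is 'positive'/'negative' by the sign of r,
    empty for undefined r).
    """
    trait = np.asarray(trait, dtype=float)
    if trait.size != matrix.n_samples:
        raise ValueError("trait length must match the number of samples")
    r, p = spearman_matrix(matrix.values, trait)
    flagged = (np.abs(r) > params.r_threshold) & (p < params.p_threshold)
    flagged = np.where(np.isfinite(r), flagged, False)
    direction = np.where(
        ~np.isfinite(r), "", np.where(r > 0, "positive", "negative")
    )
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "r": r,
            "p": p,
            "flagged": flagged.astype(bool),
            "direction": direction,
        }
    )
    logger.info(
        "screen: %d/%d genes flagged (|r|>%g and p<%g)",
        int(out["flagged"].sum()),
        len(out),
        params.r_threshold,
        params.p_threshold,
    )
    return out


def exclude_genes(records: pd.DataFrame, exclusion: GeneList) -> pd.DataFrame:
    """Mark records on the exclusion list with ``age_associated=True``.

    The full record set is returned (nothing dropped); use
    :func:`reported_view` for the reported subset.
    """
    records = records.copy()
    records["age_associated"] = records["gene_id"].isin(exclusion.identifiers)
    n = int(records["age_associated"].sum())
    if n:
        logger.info("%d gene(s) marked age-associated (%s)", n, exclusion.label)
    return records


def reported_view(records: pd.DataFrame) -> pd.DataFrame:
    """Records without the age-associated genes (the view that is reported)."""
    if "age_associated" not in records.columns:
        return records.copy()
    return records.loc[~records["age_associated"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------


def build_design(
    clinical: ClinicalTable,
    sample_ids: list[str] | None = None,
    covariates: CovariateSpec = CovariateSpec(),
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (intercept + numeric + indicator-coded categoricals).

    The most frequent level of each categorical covariate is the reference
    (dropped).  Indicator columns that are constant across the cohort are
    removed with a warning, since they carry no information and degrade
    conditioning.
    """
    frame = clinical.data.set_index("sample_id")
    if sample_ids is not None:
        frame = frame.loc[list(sample_ids)]
    cols: list[np.ndarray] = [np.ones(len(frame))]
    names: list[str] = ["intercept"]
    for cov in covariates.numeric:
        cols.append(frame[cov].to_numpy(dtype=float))
        names.append(cov)
    for cov in covariates.categorical:
        levels = frame[cov].astype(str)
        reference = levels.value_counts().idxmax()
        for level in sorted(levels.unique()):
            if level == reference:
                continue
            indicator = (levels == level).to_numpy(dtype=float)
            if indicator.std() == 0:
                logger.warning(
                    "dropping constant indicator %s=%s from the design", cov, level
                )
                continue
            cols.append(indicator)
            names.append(f"{cov}[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning(
            "design matrix is rank-deficient (%d columns, rank %d); "
            "minimum-norm least squares will be used",
            X.shape[1],
            np.linalg.matrix_rank(X),
        )
    return X, names


def residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of one vector or of each row of a matrix against a design.

    Rank-deficient designs are handled by minimum-norm least squares; the
    residuals are orthogonal to every design column either way.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[None, :] if single else y
    if Y.shape[1] != design.shape[0]:
        raise ValueError("y and design disagree on the number of samples")
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    resid = (Y.T - design @ beta).T
    return resid[0] if single else resid


#: columns of a partial-correlation record table
PARTIAL_SCHEMA = ("gene_id", "r_partial", "p", "flagged", "direction")


def partial_spearman(
    matrix: ExpressionMatrix,
    trait: np.ndarray,
    clinical: ClinicalTable,
    covariates: CovariateSpec = CovariateSpec(),
    params: ScreenParams = ScreenParams(),
    adjust_df: bool = False,
    return_residuals: bool = False,
):
    """Covariate-adjusted Spearman screen via double residualization.

    Expression of each gene and the trait are each regressed (OLS) on the
    same covariate design; the residual vectors are then Spearman
    correlated.  With ``adjust_df=True`` the p-value uses
    n - 2 - (non-intercept columns) degrees of freedom instead of n - 2.

    Returns a record table (``gene_id, r_partial, p, flagged, direction``);
    with ``return_residuals=True`` also the (genes x samples) expression
    residual matrix and the trait residual vector, for residual-residual
    scatter plots.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.size != matrix.n_samples:
        raise ValueError("trait length must match the number of samples")
    X, names = build_design(clinical, matrix.sample_ids, covariates)
    expr_resid = residualize(matrix.values, X)
    trait_resid = residualize(trait, X)
    # a variable that is an exact linear function of the covariates leaves
    # only floating-point noise behind; flatten it so the correlation is
    # reported as undefined rather than as ranks of rounding error
    scale = np.linalg.norm(matrix.values, axis=1) + 1.0
    degenerate = np.linalg.norm(expr_resid, axis=1) <= 1e-10 * scale
    expr_resid[degenerate] = 0.0
    if np.linalg.norm(trait_resid) <= 1e-10 * (np.linalg.norm(trait) + 1.0):
        trait_resid = np.zeros_like(trait_resid)
    df = matrix.n_samples - 2 - (len(names) - 1 if adjust_df else 0)
    if df < 1:
        raise ValueError("not enough samples for the requested degrees of freedom")
    r, p = spearman_matrix(expr_resid, trait_resid, df=df)
    flagged = (np.abs(r) > params.r_threshold) & (p < params.p_threshold)
    flagged = np.where(np.isfinite(r), flagged, False)
    direction = np.where(~np.isfinite(r), "", np.where(r > 0, "positive", "negative"))
    records = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "r_partial": r,
            "p": p,
            "flagged": flagged.astype(bool),
            "direction": direction,
        }
    )
    logger.info(
        "partial screen (covariates: %s): %d/%d genes flagged",
        ", ".join(names[1:]) or "none",
        int(records["flagged"].sum()),
        len(records),
    )
    if return_residuals:
        return records, expr_resid, trait_resid
    return records


def overlap_sets(a: GeneList, b: GeneList) -> GeneList:
    """Intersection of two gene lists; the label records both inputs."""
    shared = a.identifiers & b.identifiers
    label = f"{a.label or 'A'} & {b.label or 'B'}"
    return GeneList(frozenset(shared), label)
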