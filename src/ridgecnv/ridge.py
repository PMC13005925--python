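"""Ridge-regression self-normalization.

The test sample's log2 depths on its stable chromosome are regressed on
the column-standardized log2 PoN matrix restricted to the same targets;
the closed-form ridge solution (normal equations with an L2 penalty,
response and features centered so the intercept separates) is then
applied genome-wide to predict a personalized diploid reference, and
the self-normalized log2 ratio is the difference observed - predicted.

The standardization uses the population standard deviation (divisor N),
and the linear system is solved with a symmetric positive-definite
Cholesky factorization of (X'X + alpha*I) — never an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .baseline import BaselineCohort
from .depth import DepthVector, Stage
from .targets import Panel

__all__ = [
    "RidgeModel",
    "LogRatioProfile",
    "standardize_baseline",
    "fit_ridge",
    "predict_reference",
    "log2_ratio_profile",
    "self_normalize",
]

DEFAULT_ALPHA = 1.0
DEFAULT_PSEUDOCOUNT = 1e-3


@dataclass
class RidgeModel:
    """Standardization statistics and fitted ridge coefficients."""

    col_means: np.ndarray     # per retained baseline sample, log2 scale
    col_sds: np.ndarray       # population sd (divisor N)
    kept_cols: np.ndarray     # indices of retained PoN columns
    weights: np.ndarray       # w*
    intercept: float          # b*
    alpha: float
    trained_on: str = ""      # stable chromosome id
    n_train: int = 0


@dataclass
class LogRatioProfile:
    """Self-normalized log2 ratios over the unmasked panel targets."""

    values: np.ndarray
    target_indices: np.ndarray  # panel ordinals of the unmasked targets
    sample_id: str = ""
    stable_chrom: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.target_indices = np.asarray(self.target_indices, dtype=np.int64)
        if self.values.shape != self.target_indices.shape:
            raise ValueError("values and target_indices must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log2 ratios must be finite")

    def __len__(self) -> int:
        return len(self.values)


def standardize_baseline(
    cohort: BaselineCohort,
    panel: Panel,
    chrom: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
):
    """Column-standardize the log2 PoN matrix on one chromosome.

    Returns ``(X_tilde, col_means, col_sds, kept_cols, row_indices)``.
    Columns with zero spread on the chromosome are dropped.
    """
    rng = panel.chrom_index[chrom]
    rows = np.arange(rng.start, rng.stop)
    rows = rows[cohort.mask[rows]]
    if len(rows) < 2:
        raise ValueError(f"chromosome {chrom}: fewer than 2 unmasked targets")
    X = np.log2(cohort.matrix[rows, :] + pseudocount)
    col_means = X.mean(axis=0)
    col_sds = X.std(axis=0)  # population form, divisor N
    kept = np.flatnonzero(col_sds > 0)
    if kept.size == 0:
        raise ValueError(f"chromosome {chrom}: all PoN columns are degenerate")
    if kept.size < X.shape[1]:
        import warnings

        warnings.warn(
            f"dropping {X.shape[1] - kept.size} constant PoN column(s) on {chrom}"
        )
    Xt = (X[:, kept] - col_means[kept]) / col_sds[kept]
    return Xt, col_means[kept], col_sds[kept], kept, rows


def fit_ridge(
    Xt: np.ndarray,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    trained_on: str = "",
    kept_cols: np.ndarray | None = None,
    col_means: np.ndarray | None = None,
    col_sds: np.ndarray | None = None,
) -> RidgeModel:
    """Closed-form ridge fit with centered response and features.

    w* = (Xc' Xc + alpha I)^-1 Xc' yc with Xc, yc column-centered, and
    b* = mean(y) - w*' mean(X).  N < M (more baseline samples than
    training targets) is fine: the penalty regularizes the rank
    deficiency.
    """
    Xt = np.asarray(Xt, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xt.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("response vector contains non-finite values")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    xbar = Xt.mean(axis=0)
    ybar = float(y.mean())
    Xc = Xt - xbar
    yc = y - ybar
    m = Xt.shape[1]
    A = Xc.T @ Xc + alpha * np.eye(m)
    w = cho_solve(cho_factor(A, lower=True), Xc.T @ yc)
    b = ybar - float(w @ xbar)
    return RidgeModel(
        col_means=np.zeros(m) if col_means is None else np.asarray(col_means, float),
        col_sds=np.ones(m) if col_sds is None else np.asarray(col_sds, float),
        kept_cols=np.arange(m) if kept_cols is None else np.asarray(kept_cols),
        weights=w,
        intercept=b,
        alpha=float(alpha),
        trained_on=trained_on,
        n_train=Xt.shape[0],
    )


def predict_reference(
    model: RidgeModel,
    cohort: BaselineCohort,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Predicted diploid reference log2 depth for every unmasked panel target.

    PoN rows are standardized with the model's training column
    statistics before applying the fitted coefficients, so the model
    trained on the stable chromosome extends genome-wide.
    """
    rows = np.flatnonzero(cohort.mask)
    X = np.log2(cohort.matrix[np.ix_(rows, model.kept_cols)] + pseudocount)
    Xt = (X - model.col_means) / model.col_sds
    return Xt @ model.weights + model.intercept


def log2_ratio_profile(
    y_all: np.ndarray,
    yhat_all: np.ndarray,
    target_indices: np.ndarray,
    sample_id: str = "",
    stable_chrom: str = "",
) -> LogRatioProfile:
    """r_i = y_i - yhat_i (both on log2 scale)."""
    y_all = np.asarray(y_all, float)
    yhat_all = np.asarray(yhat_all, float)
    if y_all.shape != yhat_all.shape:
        raise ValueError("observed and predicted vectors must align")
    return LogRatioProfile(
        values=y_all - yhat_all,
        target_indices=target_indices,
        sample_id=sample_id,
        stable_chrom=stable_chrom,
    )


def self_normalize(
    test: DepthVector,
    cohort: BaselineCohort,
    panel: Panel,
    stable_chrom: str,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[LogRatioProfile, RidgeModel]:
    """Fit on the stable chromosome, predict genome-wide, emit log2 ratios."""
    if test.stage != Stage.NORM:
        raise ValueError(f"expected stage RD_nor, got {test.stage}")
    Xt, col_means, col_sds, kept, train_rows = standardize_baseline(
        cohort, panel, stable_chrom, pseudocount
    )
    y_train = np.log2(test.values[train_rows] + pseudocount)
    model = fit_ridge(
        Xt,
        y_train,
        alpha=alpha,
        trained_on=stable_chrom,
        kept_cols=kept,
        col_means=col_means,
        col_sds=col_sds,
    )
    rows = np.flatnonzero(cohort.mask)
    yhat = predict_reference(model, cohort, pseudocount)
    y_all = np.log2(test.values[rows] + pseudocount)
    profile = log2_ratio_profile(
        y_all, yhat, rows, sample_id=test.sample_id, stable_chrom=stable_chrom
    )
    return profile, model
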