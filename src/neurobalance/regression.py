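"""Multiple linear regression of the Berg Balance Scale on EEG/fNIRS features.

The model is

    BBS = b0 + b1 * ERD + b2 * HBO + b3 * AGE + b4 * HBO^2 + e,

fitted by ordinary least squares on untransformed predictors (coefficients
stay on the clinical scale), with classical t-based 95% confidence
intervals and p-values. Out-of-sample performance is assessed by
leave-one-out cross-validation — with eight subjects this is exactly an
eight-fold split with singleton test sets — summarised as the RMSE of the
held-out predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "DESIGN_COLUMNS",
    "RegressionFit",
    "CVResult",
    "validate_feature_table",
    "build_design",
    "fit_ols",
    "loo_cv",
    "summarize",
]

#: Required feature-table columns (schema is by name, not position).
FEATURE_COLUMNS: tuple[str, ...] = ("AGE", "ERD", "HBO", "BBS")

#: Fixed design-matrix column order for the BBS model.
DESIGN_COLUMNS: tuple[str, ...] = ("Constant", "ERD", "HBO", "AGE", "HBOxHBO")

BBS_RANGE: tuple[float, float] = (0.0, 56.0)


@dataclass
class RegressionFit:
    """OLS fit of the BBS model: coefficients, inference, residuals."""

    beta: pd.Series
    ci95: pd.DataFrame
    p: pd.Series
    r2: float
    r2_adj: float
    residuals: np.ndarray
    n: int
    k: int

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        return design[list(self.beta.index)].to_numpy() @ self.beta.to_numpy()

    def summary_frame(self) -> pd.DataFrame:
        """One row per coefficient: estimate, 95% CI, p-value."""
        return pd.DataFrame(
            {
                "beta": self.beta,
                "ci_low": self.ci95["low"],
                "ci_high": self.ci95["high"],
                "p": self.p,
            }
        )


@dataclass
class CVResult:
    """Leave-one-out predictions and their RMSE in BBS points."""

    fold_predictions: pd.Series
    actual: pd.Series
    rmse: float
    scheme: str = "leave-one-out"


def validate_feature_table(
    table: pd.DataFrame, check_range: bool = False
) -> pd.DataFrame:
    """Check schema and completeness; returns the table unchanged on success.

    Clinical BBS values live on the 0-56 scale; out-of-range responses are
    rejected when ``check_range`` is set (the I/O boundary for real
    clinical tables) and logged otherwise — unclipped synthetic cohorts
    may legitimately exceed the scale.
    """
    missing_cols = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table missing columns: {missing_cols}")
    sub = table[list(FEATURE_COLUMNS)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"feature table has missing values in: {bad}")
    lo, hi = BBS_RANGE
    if ((table["BBS"] < lo) | (table["BBS"] > hi)).any():
        if check_range:
            raise ValueError(
                f"BBS values outside the scale range [{lo}, {hi}]")
        logger.warning("BBS values outside the clinical scale range "
                       "[%g, %g]", lo, hi)
    return table


def build_design(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix [1, ERD, HBO, AGE, HBO^2] and the BBS response.

    Columns are selected by name, so input column order is irrelevant.
    Predictors are not standardized: coefficients remain in BBS points per
    unit of each predictor. A full fit needs at least as many rows as
    columns (cross-validation needs one more).
    """
    validate_feature_table(table)
    design = pd.DataFrame(
        {
            "Constant": np.ones(len(table)),
            "ERD": table["ERD"].to_numpy(dtype=float),
            "HBO": table["HBO"].to_numpy(dtype=float),
            "AGE": table["AGE"].to_numpy(dtype=float),
            "HBOxHBO": table["HBO"].to_numpy(dtype=float) ** 2,
        },
        index=table.index,
    )
    y = table["BBS"].astype(float)
    return design, y


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the culprits: columns whose removal restores full rank
        collinear = [
            c for c in design.columns
            if np.linalg.matrix_rank(design.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < "
            f"{X.shape[1]}); collinear columns: {collinear}"
        )


def fit_ols(design: pd.DataFrame, y: pd.Series | np.ndarray) -> RegressionFit:
    """Ordinary least squares with classical small-sample inference.

    95% CIs and two-sided p-values come from the t distribution with
    n - k - 1 degrees of freedom (k predictors plus intercept);
    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1).
    """
    _check_full_rank(design)
    y = pd.Series(np.asarray(y, dtype=float), index=design.index, name="BBS")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["low", "high"]
    n, k = len(y), design.shape[1] - 1
    return RegressionFit(
        beta=res.params,
        ci95=ci,
        p=res.pvalues,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        residuals=np.asarray(res.resid),
        n=n,
        k=k,
    )


def loo_cv(table: pd.DataFrame, predictors: tuple[str, ...] | None = None) -> CVResult:
    """Leave-one-out cross-validation of the BBS model.

    Each subject in turn is held out, the model is refitted on the other
    n - 1 rows, and the held-out BBS is predicted; the RMSE over all n
    held-out predictions is reported. Fully deterministic and invariant to
    row order. ``predictors`` restricts the design to the intercept plus
    the named columns (default: the full model).
    """
    design, y = build_design(table)
    if predictors is not None:
        design = design[["Constant", *predictors]]
    n, p = design.shape
    if n < p + 1:
        raise ValueError(
            f"leave-one-out needs n >= {p + 1} rows for {p} coefficients, "
            f"got {n}"
        )
    X = design.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi = X[mask]
        if np.linalg.matrix_rank(Xi) < p:
            raise ValueError(
                f"fold holding out row {design.index[i]!r} is rank deficient"
            )
        beta, *_ = np.linalg.lstsq(Xi, yv[mask], rcond=None)
        preds[i] = X[i] @ beta
    rmse = float(np.sqrt(np.mean((preds - yv) ** 2)))
    return CVResult(
        fold_predictions=pd.Series(preds, index=design.index, name="BBS_pred"),
        actual=y,
        rmse=rmse,
    )


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean and sample standard deviation (n - 1 denominator).

    A single-row table reports the SD as missing (NaN), not zero.
    """
    if len(table) == 0:
        raise ValueError("feature table is empty")
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if not cols:
        raise ValueError(f"no known feature columns among {list(table.columns)}")
    sub = table[cols].astype(float)
    return pd.DataFrame({"mean": sub.mean(), "sd": sub.std(ddof=1)})
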