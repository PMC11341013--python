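"""Blood feature matrix and the dichotomized-VAF logistic screening model.

The screen models the log-odds of cancer as a linear function of mutation
indicators over the discovered panel::

    ln(p / (1 - p)) = beta0 + sum_i beta_i * x_i

where ``x_i`` is 1 when panel mutation *i* is present in the blood sample at
a VAF strictly above the dichotomization cutoff (default 0.01) and 0
otherwise. Each coefficient ``beta_i`` is the log odds-ratio (LOR) of cancer
for carriage of mutation *i*, controlling for the rest of the panel.

Fitting minimizes the class-weighted, L2-penalized negative log-likelihood
(intercept unpenalized); the fit is delegated to a deterministic quasi-Newton
solver. Class weights (default ``{0: 1, 1: 4}``) up-weight the cancer class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class FeatureMatrix:
    """Samples x panel VAF values (raw) or mutation indicators (binary).

    ``values`` is indexed by sample_id with columns in panel order;
    ``cohorts`` maps each sample to its cohort (batch); ``labels`` is 1 for
    cancer, 0 for non-cancer, or None when unlabeled.
    """

    values: pd.DataFrame
    cohorts: pd.Series
    labels: pd.Series | None
    kind: str  # "raw" | "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "binary"):
            raise ValueError(f"kind must be 'raw' or 'binary', got {self.kind!r}")

    @property
    def panel(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        ids = [s for s in sample_ids if s in self.values.index]
        missing = set(sample_ids) - set(ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
        return FeatureMatrix(
            values=self.values.loc[ids].sort_index(),
            cohorts=self.cohorts.loc[ids].sort_index(),
            labels=None if self.labels is None else self.labels.loc[ids].sort_index(),
            kind=self.kind,
        )


@dataclass
class FittedModel:
    """Fitted logistic screen: intercept, per-mutation LORs, and settings."""

    panel: list[str]
    beta0: float
    beta: np.ndarray
    vaf_cutoff: float
    class_weight: dict[int, float]
    l2_strength: float
    converged: bool
    n_iter: int = 0
    grad_inf_norm: float = float("nan")

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.panel):
            raise ValueError("beta length must equal panel size")

    @property
    def n_zero_coefficients(self) -> int:
        return int(np.sum(self.beta == 0.0))


def build_vaf_matrix(profiles: pd.DataFrame, panel: Sequence[str]) -> FeatureMatrix:
    """Assemble the raw samples x panel VAF matrix from a blood-profile table.

    ``profiles`` must carry sample_id, cohort_id, optionally label, and one
    VAF column per panel mutation; a panel mutation missing from the table is
    an error (never silently zero-filled), as are duplicate sample ids. Rows
    are sorted by sample_id so the matrix is invariant to input order.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must not be empty")
    dups = profiles["sample_id"][profiles["sample_id"].duplicated()].unique()
    if len(dups):
        raise ValueError(f"duplicate sample ids: {sorted(dups)[:5]}")
    missing = [v for v in panel if v not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack VAF columns for panel mutations: {missing[:5]}")
    indexed = profiles.set_index("sample_id").sort_index()
    values = indexed[panel].astype(float)
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing VAF values in columns: {bad[:5]}")
    if ((values < 0) | (values > 1)).any().any():
        raise ValueError("raw VAF values must lie in [0, 1]")
    labels = indexed["label"].astype(int) if "label" in indexed.columns else None
    return FeatureMatrix(
        values=values,
        cohorts=indexed["cohort_id"],
        labels=labels,
        kind="raw",
    )


def dichotomize(matrix: FeatureMatrix, cutoff: float = 0.01) -> FeatureMatrix:
    """Binarize a raw VAF matrix: indicator of VAF strictly above ``cutoff``."""
    if matrix.kind != "raw":
        raise ValueError("matrix is already dichotomized")
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    return FeatureMatrix(
        values=(matrix.values > cutoff).astype(int),
        cohorts=matrix.cohorts,
        labels=matrix.labels,
        kind="binary",
    )


def _objective_gradient(X, y, w, beta0, beta, l2_strength):
    """Gradient of the weighted L2-penalized negative log-likelihood."""
    p = expit(beta0 + X @ beta)
    r = w * (p - y)
    g_beta = X.T @ r + l2_strength * beta
    g0 = r.sum()
    return float(max(np.abs(g0), np.max(np.abs(g_beta)) if len(beta) else 0.0))


def fit_logistic(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[int] | None = None,
    class_weight: Mapping[int, float] | None = None,
    l2_strength: float = 1.0,
    vaf_cutoff: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
) -> FittedModel:
    """Fit the weighted, L2-penalized logistic screen on binary features.

    The objective is ``sum_i w_{y_i} * crossentropy_i + (l2_strength/2)*||beta||^2``
    with the intercept unpenalized; ``l2_strength = 0`` gives plain weighted
    maximum likelihood. The solver is deterministic for fixed inputs (the
    seed parameter exists for interface symmetry; no randomness is used).
    """
    if isinstance(X, FeatureMatrix):
        if X.kind != "binary":
            raise ValueError("fit_logistic requires a dichotomized matrix")
        panel = X.panel
        if y is None:
            if X.labels is None:
                raise ValueError("labels required to fit")
            y_arr = X.labels.to_numpy()
        else:
            y_arr = np.asarray(y, dtype=int)
        X_arr = X.values.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        panel = [f"x{i}" for i in range(X_arr.shape[1])]
        if y is None:
            raise ValueError("labels required to fit")
        y_arr = np.asarray(y, dtype=int)
    if not set(np.unique(X_arr)) <= {0.0, 1.0}:
        raise ValueError("features must be binary indicators")
    classes = set(np.unique(y_arr))
    if not classes <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit")
    if l2_strength < 0:
        raise ValueError("l2_strength must be non-negative")
    cw = dict(class_weight) if class_weight is not None else {0: 1.0, 1: 1.0}

    if l2_strength == 0:
        clf = LogisticRegression(
            penalty=None, solver="lbfgs", tol=tol, max_iter=max_iter,
            class_weight=cw,
        )
    else:
        clf = LogisticRegression(
            penalty="l2", C=1.0 / l2_strength, solver="lbfgs", tol=tol,
            max_iter=max_iter, class_weight=cw,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn re-warns on max_iter; handled below
        clf.fit(X_arr, y_arr)
    n_iter = int(clf.n_iter_[0])
    beta = clf.coef_[0].copy()
    beta0 = float(clf.intercept_[0])
    w = np.where(y_arr == 1, cw.get(1, 1.0), cw.get(0, 1.0))
    grad = _objective_gradient(X_arr, y_arr, w, beta0, beta, l2_strength)
    converged = n_iter < max_iter
    if not converged:
        warnings.warn(
            f"logistic fit did not converge within {max_iter} iterations "
            f"(gradient inf-norm {grad:.3g})",
            ConvergenceWarning,
        )
    return FittedModel(
        panel=panel,
        beta0=beta0,
        beta=beta,
        vaf_cutoff=vaf_cutoff,
        class_weight={int(k): float(v) for k, v in cw.items()},
        l2_strength=float(l2_strength),
        converged=converged,
        n_iter=n_iter,
        grad_inf_norm=grad,
    )


def linear_predictor(model: FittedModel, x: np.ndarray) -> np.ndarray:
    """Log-odds ``beta0 + beta . x`` for one indicator vector or a matrix."""
    x = np.asarray(x, dtype=float)
    expected = len(model.panel)
    if x.ndim == 1:
        if len(x) != expected:
            raise ValueError(f"expected {expected} features, got {len(x)}")
    elif x.shape[1] != expected:
        raise ValueError(f"expected {expected} features, got {x.shape[1]}")
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("indicator vector must be binary")
    return model.beta0 + x @ model.beta


def predict_probability(model: FittedModel, x: np.ndarray) -> np.ndarray | float:
    """Predicted probability of cancer, ``1 / (1 + exp(-(beta0 + beta.x)))``."""
    eta = linear_predictor(model, x)
    p = expit(eta)
    return float(p) if np.ndim(p) == 0 else p


def predict_matrix(model: FittedModel, matrix: FeatureMatrix) -> pd.Series:
    """Predicted probabilities for every sample of a feature matrix.

    A raw matrix is dichotomized at the model's own VAF cutoff first.
    """
    fm = dichotomize(matrix, model.vaf_cutoff) if matrix.kind == "raw" else matrix
    if fm.panel != model.panel:
        raise ValueError("matrix panel does not match model panel")
    p = predict_probability(model, fm.values.to_numpy(dtype=float))
    return pd.Series(p, index=fm.values.index, name="p_cancer")


def classify(p, cutpoint: float = 0.5):
    """Predict cancer (1) when the probability strictly exceeds ``cutpoint``."""
    if not 0 <= cutpoint <= 1:
        raise ValueError("cutpoint must lie in [0, 1]")
    p_arr = np.asarray(p, dtype=float)
    out = (p_arr > cutpoint).astype(int)
    return int(out) if np.ndim(p) == 0 else out
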