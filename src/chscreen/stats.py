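"""Inference machinery: binomial proportion CIs and bootstrap LOR statistics.

Classification rates (accuracy, sensitivity, specificity) get
normal-approximation binomial confidence intervals. Logistic-regression
coefficients (log odds-ratios) get bootstrap standard errors from resampling
samples with replacement and refitting, from which Z statistics, Wald-style
CIs and two-sided p-values follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import FeatureMatrix, FittedModel, fit_logistic


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its normal-approximation CI (clipped)."""

    successes: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "successes": self.successes,
            "n": self.n,
            "p_hat": self.p_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
        }


def binom_ci_normal(successes: int, n: int, alpha: float = 0.05) -> ProportionEstimate:
    """Normal-approximation (Wald) CI for a binomial proportion.

    ``p_hat +/- z_{1-alpha/2} * sqrt(p_hat (1 - p_hat) / n)``, clipped to
    [0, 1]. The multiplier is the exact normal quantile (1.959964 at
    alpha = 0.05), not the rounded 1.96.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    p_hat = successes / n
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return ProportionEstimate(
        successes=int(successes),
        n=int(n),
        p_hat=p_hat,
        ci_low=float(max(0.0, p_hat - half)),
        ci_high=float(min(1.0, p_hat + half)),
        alpha=alpha,
    )


def occurrence_fractions(X: FeatureMatrix, y=None) -> pd.DataFrame:
    """Per-mutation carriage fractions within each label group.

    Returns a frame indexed by variant_id with columns frac_cancer and
    frac_noncancer (column means of the binary matrix within y==1 and y==0).
    """
    if X.kind != "binary":
        raise ValueError("occurrence_fractions requires a dichotomized matrix")
    if y is None:
        if X.labels is None:
            raise ValueError("labels required")
        y_arr = X.labels.to_numpy()
    else:
        y_arr = np.asarray(y, dtype=int)
    if not ((y_arr == 1).any() and (y_arr == 0).any()):
        raise ValueError("both classes must be present")
    vals = X.values.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "frac_cancer": vals[y_arr == 1].mean(axis=0),
            "frac_noncancer": vals[y_arr == 0].mean(axis=0),
        },
        index=X.panel,
    )


def bootstrap_coefficients(
    X: FeatureMatrix,
    y=None,
    fit_config: dict | None = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap SE / Z / CI / p for every panel coefficient.

    Rows (samples) are resampled with replacement ``B`` times and the model
    refit per resample; ``se_boot`` is the standard deviation of the
    resampled coefficient estimates. Z and the Wald-style CI and two-sided
    p-value are computed on the original-fit coefficients. Resamples lacking
    a class are redrawn (the count is reported in ``df.attrs['n_redrawn']``);
    more than ``B/2`` redraws aborts.

    Returns a frame indexed by variant_id with columns beta_hat, se_boot, z,
    ci_low, ci_high, p_value, frac_cancer, frac_noncancer.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if B < 100:
        warnings.warn(f"bootstrap with B={B} gives a noisy standard error", UserWarning)
    fit_config = dict(fit_config or {})
    if y is None:
        if X.labels is None:
            raise ValueError("labels required")
        y_arr = X.labels.to_numpy()
    else:
        y_arr = np.asarray(y, dtype=int)
    X_arr = X.values.to_numpy(dtype=float)
    n = len(y_arr)

    original = fit_logistic(X_arr, y_arr, **fit_config)
    rng = np.random.default_rng(seed)
    boots = np.empty((B, len(original.beta)))
    boots0 = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            yb = y_arr[idx]
            if yb.min() != yb.max():
                break
            n_redrawn += 1
            if n_redrawn > B // 2:
                raise RuntimeError(
                    f"more than {B // 2} degenerate (single-class) bootstrap "
                    "resamples; the data is too unbalanced for a row bootstrap"
                )
        fit = fit_logistic(X_arr[idx], yb, **fit_config)
        boots[b] = fit.beta
        boots0[b] = fit.beta0

    se = boots.std(axis=0, ddof=1)
    z_mult = sps.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, original.beta / se, np.inf * np.sign(original.beta))
        z = np.where((se == 0) & (original.beta == 0), 0.0, z)
    p = 2.0 * sps.norm.sf(np.abs(z))
    frac = occurrence_fractions(X, y_arr)
    out = pd.DataFrame(
        {
            "beta_hat": original.beta,
            "se_boot": se,
            "z": z,
            "ci_low": original.beta - z_mult * se,
            "ci_high": original.beta + z_mult * se,
            "p_value": p,
            "frac_cancer": frac["frac_cancer"].to_numpy(),
            "frac_noncancer": frac["frac_noncancer"].to_numpy(),
        },
        index=pd.Index(X.panel, name="variant_id"),
    )
    out.attrs["n_redrawn"] = n_redrawn
    out.attrs["B"] = B
    out.attrs["beta0_hat"] = original.beta0
    out.attrs["se_beta0"] = float(boots0.std(ddof=1))
    return out


def coefficient_report(
    model: FittedModel, stats_df: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-mutation coefficient table ordered by p-value.

    Adds a ``significant`` flag (raw p below ``alpha``) and a
    Benjamini-Hochberg adjusted column ``p_bh`` for reference; summary counts
    of positive / negative / zero coefficients and significant LORs are in
    ``df.attrs['counts']``.
    """
    missing = set(model.panel) - set(stats_df.index)
    if missing:
        raise ValueError(f"stats missing for panel mutations: {sorted(missing)[:5]}")
    rep = stats_df.loc[model.panel].copy()
    rep["significant"] = rep["p_value"] < alpha
    rep["p_bh"] = multipletests(rep["p_value"].to_numpy(), method="fdr_bh")[1]
    rep = rep.sort_values("p_value", kind="mergesort")
    rep.attrs["counts"] = {
        "n_positive": int((rep["beta_hat"] > 0).sum()),
        "n_negative": int((rep["beta_hat"] < 0).sum()),
        "n_zero": int((rep["beta_hat"] == 0).sum()),
        "n_significant": int(rep["significant"].sum()),
    }
    return rep
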