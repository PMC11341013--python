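"""Multi-cohort study design: splitting, batch-aware selection, evaluation.

Cohorts (sequencing studies) are the batch unit. A subset of cohorts is
designated *development*: each is split into training / validation / test by
the two-stage ceil rule (test first, then validation from the remainder); the
other cohorts contribute all their samples to the independent test set.
Model selection scores each candidate configuration by *unweighted
batch-average* validation accuracy — the arithmetic mean of per-cohort
accuracies, ignoring cohort sizes — so large cohorts cannot dominate the
choice. Final evaluation reports pooled accuracy / sensitivity / specificity
with normal-approximation binomial CIs, per-batch accuracies, AUC, and the
fractions of confidently classified samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import FeatureMatrix, FittedModel, classify, dichotomize, fit_logistic, predict_matrix
from .stats import ProportionEstimate, binom_ci_normal

TRAIN, VALIDATION, TEST = "train", "validation", "test"


def split_counts(n: int, test_frac: float = 0.25, val_frac: float = 0.25) -> tuple[int, int, int]:
    """(train, validation, test) counts for one development cohort of size n.

    Held-out counts round up at both stages: ``n_test = ceil(n * test_frac)``
    then ``n_val = ceil((n - n_test) * val_frac)``; training takes the rest.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not (0 < test_frac < 1 and 0 < val_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")
    n_test = math.ceil(n * test_frac)
    n_val = math.ceil((n - n_test) * val_frac)
    n_train = n - n_test - n_val
    return n_train, n_val, n_test


def split_cohorts(
    cohorts: Mapping[str, int] | Mapping[str, Sequence[str]],
    development: Iterable[str],
    test_frac: float = 0.25,
    val_frac: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign every sample to train / validation / test.

    ``cohorts`` maps cohort id to either a sample-id list or an integer size
    (sizes generate ids ``{cohort}-s0000`` … matching the simulator's
    naming). Development cohorts are split by the ceil rule with membership
    randomized by ``seed``; all other cohorts are wholly test (role
    ``independent_test``). Returns a frame with columns sample_id,
    cohort_id, partition, role.
    """
    development = set(development)
    unknown = development - set(cohorts)
    if unknown:
        raise ValueError(f"development cohorts not in cohorts map: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for cid in sorted(cohorts):
        spec = cohorts[cid]
        if isinstance(spec, int):
            if spec < 1:
                raise ValueError(f"cohort {cid!r} has size 0")
            ids = [f"{cid}-s{i:04d}" for i in range(spec)]
        else:
            ids = list(spec)
            if not ids:
                raise ValueError(f"cohort {cid!r} has no samples")
        if cid in development:
            n_train, n_val, n_test = split_counts(len(ids), test_frac, val_frac)
            order = rng.permutation(len(ids))
            parts = np.empty(len(ids), dtype=object)
            parts[order[:n_test]] = TEST
            parts[order[n_test : n_test + n_val]] = VALIDATION
            parts[order[n_test + n_val :]] = TRAIN
            role = "development"
        else:
            parts = np.full(len(ids), TEST, dtype=object)
            role = "independent_test"
        for sid, part in zip(ids, parts):
            rows.append((sid, cid, part, role))
    return pd.DataFrame(rows, columns=["sample_id", "cohort_id", "partition", "role"])


def batch_accuracy(
    predictions, labels, batch_ids
) -> tuple[dict[str, float], float]:
    """Per-batch accuracies and their unweighted arithmetic mean.

    Every batch counts equally in the mean, regardless of its size.
    """
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    batches = np.asarray(batch_ids)
    if len(pred) != len(lab) or len(pred) != len(batches):
        raise ValueError("predictions, labels and batch_ids must align")
    if len(pred) == 0:
        raise ValueError("at least one sample required")
    per_batch: dict[str, float] = {}
    for b in sorted(set(batches.tolist())):
        mask = batches == b
        if not mask.any():
            raise ValueError(f"empty batch {b!r}")
        per_batch[b] = float((pred[mask] == lab[mask]).mean())
    return per_batch, float(np.mean(list(per_batch.values())))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the tie-corrected rank statistic.

    Equals ``P(score_cancer > score_noncancer) + 0.5 * P(tie)`` over all
    cancer/non-cancer pairs (Mann-Whitney).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks for ties
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class EvalReport:
    """Test-set evaluation: pooled and per-batch metrics with CIs."""

    n: int
    confusion: dict[str, int]  # tp, fp, tn, fn
    accuracy: ProportionEstimate
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    auc: float
    per_batch_accuracy: dict[str, float]
    batch_mean_accuracy: float
    frac_cancer_high_confidence: float  # p > 0.9 among cancer samples
    frac_noncancer_low_confidence: float  # p < 0.1 among non-cancer samples
    cutpoint: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "confusion": self.confusion,
            "accuracy": self.accuracy.as_dict(),
            "sensitivity": self.sensitivity.as_dict(),
            "specificity": self.specificity.as_dict(),
            "auc": self.auc,
            "per_batch_accuracy": self.per_batch_accuracy,
            "batch_mean_accuracy": self.batch_mean_accuracy,
            "frac_cancer_high_confidence": self.frac_cancer_high_confidence,
            "frac_noncancer_low_confidence": self.frac_noncancer_low_confidence,
            "cutpoint": self.cutpoint,
        }


def evaluate(
    model: FittedModel,
    test: FeatureMatrix,
    cutpoint: float = 0.5,
    high_bin: float = 0.9,
    low_bin: float = 0.1,
) -> EvalReport:
    """Score a fitted model on a labeled test matrix.

    Probabilities come from the model at its own dichotomization cutoff;
    class calls use ``p > cutpoint``. Pooled accuracy, sensitivity and
    specificity carry normal-approximation binomial CIs; per-batch accuracies
    and their unweighted mean quantify batch effects; the probability-bin
    fractions report how many samples are classified with high confidence.
    """
    if test.labels is None:
        raise ValueError("test samples are unlabeled")
    p = predict_matrix(model, test)
    y = test.labels.loc[p.index].to_numpy()
    yhat = classify(p.to_numpy(), cutpoint)
    tp = int(((yhat == 1) & (y == 1)).sum())
    fp = int(((yhat == 1) & (y == 0)).sum())
    tn = int(((yhat == 0) & (y == 0)).sum())
    fn = int(((yhat == 0) & (y == 1)).sum())
    n = len(y)
    per_batch, batch_mean = batch_accuracy(
        yhat, y, test.cohorts.loc[p.index].to_numpy()
    )
    p_arr = p.to_numpy()
    n_cancer = tp + fn
    n_noncancer = tn + fp
    if n_cancer == 0 or n_noncancer == 0:
        raise ValueError("both classes must be present in the test set")
    return EvalReport(
        n=n,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        accuracy=binom_ci_normal(tp + tn, n),
        sensitivity=binom_ci_normal(tp, n_cancer),
        specificity=binom_ci_normal(tn, n_noncancer),
        auc=roc_auc(p_arr, y),
        per_batch_accuracy=per_batch,
        batch_mean_accuracy=batch_mean,
        frac_cancer_high_confidence=float((p_arr[y == 1] > high_bin).mean()),
        frac_noncancer_low_confidence=float((p_arr[y == 0] < low_bin).mean()),
        cutpoint=cutpoint,
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting/export."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # collapse tied thresholds
    distinct = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / max(n1, 1)]
    fpr = np.r_[0.0, fps[distinct] / max(n0, 1)]
    thr = np.r_[np.inf, s[distinct]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


@dataclass
class GridSearchResult:
    best_config: dict
    best_model: FittedModel
    best_score: float
    leaderboard: pd.DataFrame


def _config_key(cutoff: float, params: Mapping) -> str:
    items = ",".join(f"{k}={params[k]}" for k in sorted(params))
    return f"cutoff={cutoff:.4f};{items}"


def default_hyper_grid() -> list[dict]:
    """Logistic-regression hyperparameter grid: class weighting x penalty."""
    return [
        {"class_weight": {0: 1, 1: 1}, "l2_strength": 1.0},
        {"class_weight": {0: 1, 1: 4}, "l2_strength": 1.0},
    ]


def default_cutoff_grid(start: float = 0.0, stop: float = 0.30, step: float = 0.01) -> list[float]:
    """Dichotomization cutoffs 0.00-0.30 in steps of 0.01 (31 values)."""
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


def grid_search(
    train: FeatureMatrix,
    validation: FeatureMatrix,
    cutoff_grid: Sequence[float] | None = None,
    hyper_grid: Sequence[dict] | None = None,
    fit_fn: Callable[..., FittedModel] | None = None,
    cutpoint: float = 0.5,
) -> GridSearchResult:
    """Select the dichotomization cutoff and hyperparameters by unweighted
    batch-average validation accuracy.

    Every (cutoff, hyperparameters) combination is trained on ``train`` and
    scored on ``validation``; configurations that fail to fit are recorded
    and skipped. Ties break toward fewer nonzero coefficients, then the
    lexicographically smallest configuration key. ``fit_fn`` allows plugging
    an external classifier adapter with the ``fit_logistic`` signature.
    """
    if train.kind != "raw" or validation.kind != "raw":
        raise ValueError("grid_search expects raw VAF matrices")
    if train.labels is None or validation.labels is None:
        raise ValueError("train and validation must be labeled")
    cutoffs = list(cutoff_grid) if cutoff_grid is not None else default_cutoff_grid()
    hypers = list(hyper_grid) if hyper_grid is not None else default_hyper_grid()
    if not cutoffs or not hypers:
        raise ValueError("grids must be non-empty")
    if validation.cohorts.nunique() < 2:
        raise ValueError("validation needs >= 2 batches for a batch-mean score")
    fit = fit_fn or fit_logistic

    rows = []
    best = None  # (score, n_nonzero, key, config, model)
    for cutoff in cutoffs:
        Xtr = dichotomize(train, cutoff)
        Xva = dichotomize(validation, cutoff)
        for params in hypers:
            key = _config_key(cutoff, params)
            try:
                mdl = fit(Xtr, vaf_cutoff=cutoff, **params)
                p = predict_matrix(mdl, Xva)
                yhat = classify(p.to_numpy(), cutpoint)
                _, score = batch_accuracy(
                    yhat,
                    Xva.labels.loc[p.index].to_numpy(),
                    Xva.cohorts.loc[p.index].to_numpy(),
                )
                n_nonzero = len(mdl.beta) - mdl.n_zero_coefficients
                rows.append(
                    {
                        "config": key,
                        "cutoff": cutoff,
                        "batch_mean_accuracy": score,
                        "n_nonzero": n_nonzero,
                        "failed": False,
                        **{f"param_{k}": str(v) for k, v in params.items()},
                    }
                )
                cand = (-score, n_nonzero, key)
                if best is None or cand < best[0]:
                    best = (cand, {"cutoff": cutoff, **params}, mdl, score)
            except Exception as exc:  # noqa: BLE001 - grids must survive bad configs
                rows.append(
                    {
                        "config": key,
                        "cutoff": cutoff,
                        "batch_mean_accuracy": np.nan,
                        "n_nonzero": np.nan,
                        "failed": True,
                        "error": str(exc),
                        **{f"param_{k}": str(v) for k, v in params.items()},
                    }
                )
    if best is None:
        raise RuntimeError("every grid configuration failed to fit")
    leaderboard = pd.DataFrame(rows).sort_values(
        ["batch_mean_accuracy", "n_nonzero", "config"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return GridSearchResult(
        best_config=best[1],
        best_model=best[2],
        best_score=best[3],
        leaderboard=leaderboard,
    )
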