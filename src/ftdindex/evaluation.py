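"""ROC analysis, fixed-specificity cutoffs, likelihood ratios and
leakage-safe cross-validated evaluation of the atrophy indices.

Scores follow the clinical convention of the indices: *lower* z means
*more* atrophy, i.e. more likely positive.  All ROC machinery negates the
score internally so that sklearn's higher-is-positive convention applies.

The headline operating point fixes specificity near 95% — under a normal
reference distribution the z-cutoff -1.65 — trading sensitivity for few
false positives, appropriate for a low-prevalence condition like FTD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import indices as idx
from . import normalization as norm
from .atlas_io import Cohort


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    lr_pos: float | None
    lr_neg: float | None

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "lr_pos": self.lr_pos,
                "lr_neg": self.lr_neg}


@dataclass
class EvaluationReport:
    """ROC/AUC and operating-point summary for one group comparison."""

    positive_group: tuple[str, ...]
    negative_group: tuple[str, ...]
    n_pos: int
    n_neg: int
    roc: pd.DataFrame                       # columns fpr, tpr, threshold (z-scale)
    auc: float
    operating_point: OperatingPoint
    folds: list[dict] = field(default_factory=list)
    stratum: str | None = None

    def to_dict(self) -> dict:
        return {
            "positive_group": list(self.positive_group),
            "negative_group": list(self.negative_group),
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "auc": self.auc,
            "operating_point": self.operating_point.to_dict(),
            "stratum": self.stratum,
            "n_folds": len(self.folds),
            "roc": {c: self.roc[c].tolist() for c in self.roc.columns},
        }


# ---------------------------------------------------------------------------
# core metrics

def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and trapezoidal AUC for lower-is-positive scores.

    ``labels`` are booleans/0-1 with 1 = positive class.  The returned
    thresholds are on the original (z) scale; the curve runs from (0,0)
    to (1,1) with non-decreasing fpr/tpr.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(y, -s, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": -thr})
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


def sens_spec_at_cutoff(scores, labels, cutoff: float,
                        two_sided: bool = False) -> tuple[float, float]:
    """Sensitivity/specificity of the strict rule ``z < cutoff`` (or |z|>|cutoff|)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = idx.classify(s, cutoff, two_sided)
    sens = float(pred[y].mean()) if y.any() else math.nan
    spec = float((~pred[~y]).mean()) if (~y).any() else math.nan
    return sens, spec


def likelihood_ratios(sensitivity: float, specificity: float
                      ) -> tuple[float | None, float | None]:
    """Diagnostic likelihood ratios; ``None`` where the ratio is undefined.

    LR+ = sens/(1-spec) (undefined at spec=1); LR- = (1-sens)/spec
    (undefined at spec=0).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    lr_pos = None if specificity == 1.0 else sensitivity / (1.0 - specificity)
    lr_neg = None if specificity == 0.0 else (1.0 - sensitivity) / specificity
    return lr_pos, lr_neg


def cutoff_for_specificity(reference_scores, target_specificity: float = 0.95,
                           method: str = "parametric") -> float:
    """Cutoff achieving roughly the target specificity on reference scores.

    ``parametric`` (default) assumes a normal reference and returns
    ``mean + sd * Phi^-1(1 - target)`` — for standardized scores and
    target 0.95 this is z = -1.6449, the -1.65 rule.  ``empirical``
    returns the largest cutoff such that the fraction of reference scores
    at or above it is >= target (an order statistic of the reference).
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValueError("target specificity must lie strictly in (0, 1)")
    x = np.asarray(list(reference_scores), dtype=float)
    if method == "parametric":
        return float(x.mean() + x.std(ddof=1) * stats.norm.ppf(1 - target_specificity))
    if method == "empirical":
        if x.size < 20:
            raise ValueError(f"need >= 20 reference scores, got {x.size}")
        xs = np.sort(x)
        # classification is strict (z < cutoff): at cutoff = k-th order
        # statistic, exactly k-1 reference scores fall below it (no ties)
        k = int(np.floor(x.size * (1 - target_specificity)))  # allowed below
        return float(xs[k])
    raise ValueError(f"unknown method {method!r}")


def optimal_cutoff(scores, labels) -> float:
    """Cutoff maximizing (sensitivity+specificity)/2 for ``z < cutoff``.

    Candidates are midpoints between adjacent distinct scores plus the
    open ends; ties go to the more specific (smaller) cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    u = np.unique(s)
    candidates = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    best = (-np.inf, -np.inf, math.nan)   # (balanced acc, specificity, cutoff)
    for c in candidates:
        sens, spec = sens_spec_at_cutoff(s, y, c)
        key = ((sens + spec) / 2.0, spec)
        # strictly better balanced accuracy, or equal with higher specificity
        if key > (best[0], best[1]):
            best = (key[0], key[1], float(c))
    return best[2]


# ---------------------------------------------------------------------------
# cohort-level evaluation

def evaluate_scores(scores: pd.Series, labels, positive_group, negative_group,
                    cutoff: float = idx.DEFAULT_CUTOFF, two_sided: bool = False,
                    stratum: str | None = None) -> EvaluationReport:
    """Bundle ROC, AUC and the fixed-cutoff operating point into a report."""
    y = np.asarray(labels).astype(bool)
    curve, auc = roc_auc(np.asarray(scores, dtype=float), y)
    sens, spec = sens_spec_at_cutoff(scores, y, cutoff, two_sided)
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return EvaluationReport(
        positive_group=tuple(positive_group), negative_group=tuple(negative_group),
        n_pos=int(y.sum()), n_neg=int((~y).sum()),
        roc=curve, auc=auc,
        operating_point=OperatingPoint(cutoff, sens, spec, lr_pos, lr_neg),
        stratum=stratum)


def stratify_age(cohort: Cohort, threshold: float = 70.0) -> tuple[Cohort, Cohort]:
    """Split into (age < threshold, age >= threshold) sub-cohorts."""
    below = cohort.data["age"].to_numpy(dtype=float) < threshold
    return cohort.subset(below), cohort.subset(~below)


def crossvalidate(cohort: Cohort, index_type: str, *,
                  positive_group: Sequence[str] = ("FTD",),
                  negative_group: Sequence[str] = idx.NON_FTD,
                  k: int = 10, seed: int = 0,
                  covariates: Sequence[str] = norm.DEFAULT_COVARIATES,
                  reference_group: Sequence[str] = idx.NON_FTD,
                  cutoff: float = idx.DEFAULT_CUTOFF,
                  two_sided: bool | None = None,
                  **fit_kwargs) -> EvaluationReport:
    """k-fold cross-validated evaluation with no training/test leakage.

    Folds are stratified by diagnosis label so that rare groups appear in
    every training set.  Per fold, the normalization model, the region
    weights and the z calibration are all fitted on the training folds
    only, then applied to the held-out fold; held-out z-scores are pooled
    across folds and metrics computed once on the pool.  Reproducible
    from ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = cohort.data
    strata = df["diagnosis"].to_numpy()
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_z = np.full(len(df), np.nan)
    folds: list[dict] = []
    for fold_id, (tr, te) in enumerate(splitter.split(np.zeros(len(df)), strata)):
        train = cohort.subset(np.isin(np.arange(len(df)), tr))
        test = cohort.subset(np.isin(np.arange(len(df)), te))
        if not train.mask(positive_group).any() or not train.mask(("AD",)).any():
            raise ValueError(
                f"fold {fold_id}: training folds lack FTD or AD subjects; "
                "use fewer folds or a larger cohort")
        nm = norm.fit_normalization(train, reference_group, covariates)
        model = idx.fit_index(apply_normalization_quiet(nm, train), index_type,
                              reference_group=reference_group, cutoff=cutoff,
                              two_sided=two_sided, **fit_kwargs)
        test_scores = idx.score_cohort(model, apply_normalization_quiet(nm, test))
        pooled_z[te] = test_scores["z"].to_numpy()
        folds.append({
            "fold": fold_id,
            "test_ids": df.iloc[te]["subject_id"].tolist(),
            "mu": model.mu, "sigma": model.sigma,
            "weights": dict(model.weights),
            "reference_tiv": nm.reference_tiv,
        })
    assert not np.isnan(pooled_z).any()

    eval_mask = cohort.mask(positive_group) | cohort.mask(negative_group)
    y = cohort.mask(positive_group)[eval_mask]
    report = evaluate_scores(pd.Series(pooled_z[eval_mask]), y,
                             positive_group, negative_group, cutoff=cutoff,
                             two_sided=bool(two_sided) if two_sided is not None
                             else (index_type == "ASI"))
    report.folds = folds
    return report


def apply_normalization_quiet(model, cohort):
    """apply_normalization without the flooring warning (CV folds may floor)."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return norm.apply_normalization(model, cohort)
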