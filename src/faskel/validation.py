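"""Matched-pair leave-two-out cross-validation and permutation significance.

Each cross-validation fold holds out one matched pair — a patient and their
age/sex-matched control — and trains on all remaining subjects, so the test
set never differs from the training population in the matching covariates.
A cohort of n pairs yields exactly n folds, and every subject is a test case
exactly once; accuracy is the number of correctly classified test subjects
over the total number of subjects.

Significance is assessed by rerunning the full cross-validation on cohorts
with permuted group labels. The default scheme flips the patient/control
assignment independently within each matched pair (the exchangeable unit of
the matched design); a pooled scheme that reassigns all subjects to two
equal-sized groups is also provided. The p-value is the proportion of
permutations with a *strictly greater* metric than observed; an add-one
(b+1)/(m+1) estimator is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import CONTROL, PATIENT, SVMConfig, solve_svc_dual
from .imaging import compute_common_mask, vectorize
from .synthetic import Cohort, MatchedPair

logger = logging.getLogger("faskel")

__all__ = [
    "Fold",
    "ClassificationReport",
    "PermutationResult",
    "make_folds",
    "run_lto_cv",
    "classification_metrics",
    "permutation_pvalue",
    "permutation_test",
    "permutation_test_all",
]

METRICS = ("accuracy", "sensitivity", "specificity")
SCHEMES = ("within_pair", "pooled")


@dataclass
class Fold:
    """One leave-two-out split: a held-out matched pair vs the rest."""

    test_pair: MatchedPair
    train_ids: list[str]

    def __post_init__(self) -> None:
        test = {self.test_pair.patient.subject_id, self.test_pair.control.subject_id}
        if test & set(self.train_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class ClassificationReport:
    """Per-subject predictions and the derived proportion metrics.

    accuracy = (patients correct + controls correct) / (n_patients + n_controls)
    sensitivity = patients correct / n_patients
    specificity = controls correct / n_controls
    """

    per_subject: pd.DataFrame  # subject_id, true_label, predicted_label, decision_value
    patients_correct: int
    controls_correct: int
    n_patients: int
    n_controls: int

    @classmethod
    def from_counts(
        cls,
        patients_correct: int,
        controls_correct: int,
        n_patients: int,
        n_controls: int,
        per_subject: pd.DataFrame | None = None,
    ) -> "ClassificationReport":
        if per_subject is None:
            per_subject = pd.DataFrame(
                columns=["subject_id", "true_label", "predicted_label", "decision_value"]
            )
        return cls(per_subject, patients_correct, controls_correct, n_patients, n_controls)

    @property
    def accuracy(self) -> float:
        return (self.patients_correct + self.controls_correct) / (
            self.n_patients + self.n_controls
        )

    @property
    def sensitivity(self) -> float:
        return self.patients_correct / self.n_patients

    @property
    def specificity(self) -> float:
        return self.controls_correct / self.n_controls

    def metric(self, name: str) -> float:
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)

    def percent(self, name: str) -> float:
        """Metric as a percentage rounded to 2 decimals (reporting format)."""
        return round(100.0 * self.metric(name), 2)

    def summary(self) -> dict:
        return {
            "accuracy_pct": self.percent("accuracy"),
            "sensitivity_pct": self.percent("sensitivity"),
            "specificity_pct": self.percent("specificity"),
            "patients_correct": self.patients_correct,
            "controls_correct": self.controls_correct,
            "n_patients": self.n_patients,
            "n_controls": self.n_controls,
        }


def classification_metrics(
    patients_correct: int, controls_correct: int, n_patients: int, n_controls: int
) -> ClassificationReport:
    """Report built from confusion counts alone (no per-subject rows)."""
    return ClassificationReport.from_counts(
        patients_correct, controls_correct, n_patients, n_controls
    )


def make_folds(cohort: Cohort) -> list[Fold]:
    """One fold per matched pair; the folds' test sets partition the cohort."""
    if cohort.n_pairs < 2:
        raise ValueError("need at least 2 matched pairs for leave-two-out CV")
    all_ids = [s.subject_id for s in cohort.subjects]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate subject ids in cohort")
    folds = []
    for pair in cohort.pairs:
        test = {pair.patient.subject_id, pair.control.subject_id}
        folds.append(Fold(test_pair=pair, train_ids=[i for i in all_ids if i not in test]))
    return folds


def _cohort_arrays(cohort: Cohort, svm_config: SVMConfig):
    """Features over the common mask plus labels, pair index and Gram matrix."""
    subjects = cohort.subjects
    ids = [s.subject_id for s in subjects]
    mask = compute_common_mask([s.image for s in subjects])
    fm = vectorize([s.image for s in subjects], mask, ids)
    y = np.array([PATIENT if s.label == "patient" else CONTROL for s in subjects], dtype=float)
    pair_idx = np.repeat(np.arange(cohort.n_pairs), 2)
    K = fm.values @ fm.values.T
    return fm, y, pair_idx, ids, K


def _cv_decisions(
    K: np.ndarray, y: np.ndarray, pair_idx: np.ndarray, svm_config: SVMConfig
) -> np.ndarray:
    """Out-of-fold decision values for every subject, training per fold on the
    Gram submatrix with the held-out pair removed."""
    n = y.size
    decisions = np.empty(n)
    for p in np.unique(pair_idx):
        test = pair_idx == p
        train = ~test
        y_tr = y[train]
        if np.all(y_tr == y_tr[0]):
            raise ValueError("a fold's training set contains a single class")
        alpha, b, _ = solve_svc_dual(
            K[np.ix_(train, train)], y_tr, svm_config.C, svm_config.tolerance, svm_config.max_iter
        )
        decisions[test] = K[np.ix_(test, train)] @ (alpha * y_tr) + b
    return decisions


def _report_from_decisions(
    ids: list[str], y: np.ndarray, decisions: np.ndarray
) -> ClassificationReport:
    pred = np.where(decisions > 0, PATIENT, CONTROL)  # ties go to control
    is_pat = y == PATIENT
    per_subject = pd.DataFrame(
        {
            "subject_id": ids,
            "true_label": np.where(is_pat, "patient", "control"),
            "predicted_label": np.where(pred == PATIENT, "patient", "control"),
            "decision_value": decisions,
        }
    )
    return ClassificationReport(
        per_subject=per_subject,
        patients_correct=int(np.sum(is_pat & (pred == PATIENT))),
        controls_correct=int(np.sum(~is_pat & (pred == CONTROL))),
        n_patients=int(is_pat.sum()),
        n_controls=int((~is_pat).sum()),
    )


def run_lto_cv(cohort: Cohort, svm_config: SVMConfig | None = None) -> ClassificationReport:
    """Leave-two-out cross-validation over all matched pairs."""
    svm_config = svm_config or SVMConfig()
    if svm_config.mean_center:
        return _run_lto_cv_centered(cohort, svm_config)
    fm, y, pair_idx, ids, K = _cohort_arrays(cohort, svm_config)
    decisions = _cv_decisions(K, y, pair_idx, svm_config)
    return _report_from_decisions(ids, y, decisions)


def _run_lto_cv_centered(cohort: Cohort, svm_config: SVMConfig) -> ClassificationReport:
    # centering uses training-fold means only, so the Gram matrix cannot be
    # shared across folds; explicit per-fold feature handling instead
    from .classifier import decision_value, train_linear_svm

    fm, y, pair_idx, ids, _ = _cohort_arrays(cohort, svm_config)
    decisions = np.empty(y.size)
    for p in np.unique(pair_idx):
        test = pair_idx == p
        train = ~test
        model = train_linear_svm(fm.values[train], y[train], svm_config)
        decisions[test] = decision_value(model, fm.values[test])
    return _report_from_decisions(ids, y, decisions)


@dataclass
class PermutationResult:
    """Observed metric, its permutation null and the resulting p-value."""

    metric: str
    observed: float
    null_distribution: np.ndarray
    n_perm: int
    p_value: float
    seed: int
    scheme: str = "within_pair"
    add_one: bool = False


def permutation_pvalue(observed: float, null: np.ndarray, add_one: bool = False) -> float:
    """Proportion of permuted metrics strictly greater than the observed one.

    With ``add_one`` the (b+1)/(m+1) estimator counts ties and the observed
    labeling itself, guaranteeing p > 0.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if add_one:
        return (int(np.sum(null >= observed)) + 1) / (null.size + 1)
    return int(np.sum(null > observed)) / null.size


def _permute_labels(
    y: np.ndarray, pair_idx: np.ndarray, scheme: str, rng: np.random.Generator
) -> np.ndarray:
    if scheme == "within_pair":
        flips = rng.random(pair_idx.max() + 1) < 0.5
        y_new = y.copy()
        for p in np.flatnonzero(flips):
            y_new[pair_idx == p] *= -1
        return y_new
    if scheme == "pooled":
        return y[rng.permutation(y.size)]
    raise ValueError(f"unknown permutation scheme {scheme!r}; choose from {SCHEMES}")


def permutation_test_all(
    cohort: Cohort,
    svm_config: SVMConfig | None = None,
    n_perm: int = 1000,
    scheme: str = "within_pair",
    seed: int = 0,
    add_one: bool = False,
) -> dict[str, PermutationResult]:
    """Permutation nulls for accuracy, sensitivity and specificity at once.

    Every permutation relabels the subjects and reruns the *entire*
    cross-validation, so the null reflects the full pipeline. All three
    metrics are recorded from the same permutation runs.
    """
    svm_config = svm_config or SVMConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}; choose from {SCHEMES}")
    fm, y, pair_idx, ids, K = _cohort_arrays(cohort, svm_config)
    observed = _report_from_decisions(ids, y, _cv_decisions(K, y, pair_idx, svm_config))
    rng = np.random.default_rng(seed)
    nulls = {m: np.empty(n_perm) for m in METRICS}
    for k in range(n_perm):
        y_perm = _permute_labels(y, pair_idx, scheme, rng)
        rep = _report_from_decisions(ids, y_perm, _cv_decisions(K, y_perm, pair_idx, svm_config))
        for m in METRICS:
            nulls[m][k] = rep.metric(m)
    out = {}
    for m in METRICS:
        out[m] = PermutationResult(
            metric=m,
            observed=observed.metric(m),
            null_distribution=nulls[m],
            n_perm=n_perm,
            p_value=permutation_pvalue(observed.metric(m), nulls[m], add_one),
            seed=seed,
            scheme=scheme,
            add_one=add_one,
        )
    return out


def permutation_test(
    cohort: Cohort,
    svm_config: SVMConfig | None = None,
    metric: str = "accuracy",
    n_perm: int = 1000,
    scheme: str = "within_pair",
    seed: int = 0,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation significance of a single cross-validation metric."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    return permutation_test_all(cohort, svm_config, n_perm, scheme, seed, add_one)[metric]
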