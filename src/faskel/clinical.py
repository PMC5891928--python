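"""Associations between classifier behaviour and clinical variables.

Three complementary analyses probe whether symptom severity (PANSS
subscales) or antipsychotic dose (chlorpromazine equivalents) drive the
classifier or the FA data themselves:

* a pooled-variance two-sample t-test comparing correctly vs incorrectly
  classified patients on each clinical variable;
* Pearson correlation between the Platt posterior probabilities and the
  clinical variables;
* linear-kernel ridge regression predicting each continuous clinical
  variable from the voxel pattern, evaluated out-of-sample by
  leave-one-out over patients and summarized as a Pearson r.

Missing clinical values are dropped pairwise, so degrees of freedom track
the usable sample per variable (e.g. df = n - 3 for a correlation over
patients when one dose value is missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import PATIENT, platt_fit, platt_prob
from .imaging import compute_common_mask, vectorize
from .synthetic import Cohort
from .validation import ClassificationReport

logger = logging.getLogger("faskel")

__all__ = [
    "AssociationResult",
    "KRRConfig",
    "KRRModel",
    "ttest_correct_vs_incorrect",
    "correlate_prob_clinical",
    "krr_fit",
    "krr_predict",
    "krr_cv_predict",
    "clinical_association_table",
    "CLINICAL_VARIABLES",
]

CLINICAL_VARIABLES = ("panss_pos", "panss_neg", "panss_gen", "panss_total", "cpz")


@dataclass
class AssociationResult:
    """A single association test: statistic, df, two-sided p."""

    variable: str
    stat_name: str  # 't' or 'r'
    statistic: float
    df: int
    p_value: float


def ttest_correct_vs_incorrect(
    report: ClassificationReport, clinical_values: pd.Series, variable: str = ""
) -> AssociationResult:
    """Pooled-variance Student t comparing correctly vs incorrectly
    classified subjects on one clinical variable (two-sided; df = n1+n2-2).

    ``clinical_values`` is indexed by subject id; subjects absent from it or
    with missing values are dropped.
    """
    per = report.per_subject
    merged = per.set_index("subject_id").join(clinical_values.rename("value"), how="inner")
    merged = merged.dropna(subset=["value"])
    correct = merged["true_label"] == merged["predicted_label"]
    a = merged.loc[correct, "value"].to_numpy(dtype=float)
    b = merged.loc[~correct, "value"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both correct and incorrect groups must be nonempty")
    res = stats.ttest_ind(a, b, equal_var=True)
    return AssociationResult(
        variable=variable or str(clinical_values.name or ""),
        stat_name="t",
        statistic=float(res.statistic),
        df=a.size + b.size - 2,
        p_value=float(res.pvalue),
    )


def correlate_prob_clinical(
    platt_probs: pd.Series, clinical_values: pd.Series, variable: str = ""
) -> AssociationResult:
    """Pearson correlation (two-sided p via the t transform) between Platt
    posteriors and a clinical variable, with pairwise deletion of missing
    values; df = complete pairs - 2."""
    joined = pd.concat(
        [platt_probs.rename("p"), clinical_values.rename("value")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 complete pairs")
    x = joined["p"].to_numpy(dtype=float)
    y = joined["value"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(
        variable=variable or str(clinical_values.name or ""),
        stat_name="r",
        statistic=float(r),
        df=len(joined) - 2,
        p_value=float(p),
    )


@dataclass
class KRRConfig:
    """Linear-kernel ridge regression controls.

    ``ridge`` is the regularization strength on the trace-normalized linear
    kernel (Gram matrix divided by its mean diagonal element), so a given
    value means a comparable amount of shrinkage regardless of mask size or
    FA scale. The default 0.1 is deliberately light: heavy shrinkage drives
    out-of-fold predictions toward the training-fold mean, whose
    leave-one-out anti-correlation with the held-out value would bias the
    prediction-vs-observation correlation negative under the null.
    """

    ridge: float = 0.1
    kernel: str = "linear"
    normalize_kernel: bool = True

    def __post_init__(self) -> None:
        if self.ridge <= 0:
            raise ValueError("ridge must be > 0")
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")


@dataclass
class KRRModel:
    alpha: np.ndarray  # (K + ridge I)^-1 y
    train_features: np.ndarray
    config: KRRConfig
    kernel_scale: float = 1.0


def krr_fit(features: np.ndarray, targets: np.ndarray, config: KRRConfig | None = None) -> KRRModel:
    """Closed-form kernel ridge fit: alpha = (K + ridge I)^-1 y."""
    config = config or KRRConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if X.shape[0] != y.size or y.size == 0:
        raise ValueError("one target per training subject required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and targets must be finite")
    K = X @ X.T
    scale = 1.0
    if config.normalize_kernel:
        mean_diag = float(np.trace(K)) / y.size
        if mean_diag > 0:
            scale = mean_diag
    K = K / scale
    alpha = np.linalg.solve(K + config.ridge * np.eye(y.size), y)
    return KRRModel(alpha=alpha, train_features=X, config=config, kernel_scale=scale)


def krr_predict(model: KRRModel, x: np.ndarray) -> float | np.ndarray:
    """Prediction sum_i alpha_i k(x_i, x) with the (normalized) linear kernel."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.train_features.shape[1]:
        raise ValueError("feature length mismatch")
    pred = (X @ model.train_features.T / model.kernel_scale) @ model.alpha
    return float(pred[0]) if single else pred


def krr_cv_predict(
    cohort: Cohort, variable: str, config: KRRConfig | None = None
) -> tuple[pd.Series, AssociationResult]:
    """Leave-one-out prediction of a clinical variable from patients' FA.

    The clinical variables exist for patients only, so cross-validation runs
    over patients with a non-missing value; performance is the Pearson r
    between out-of-sample predictions and observations.
    """
    if variable not in CLINICAL_VARIABLES:
        raise ValueError(f"unknown clinical variable {variable!r}")
    config = config or KRRConfig()
    patients = cohort.patients
    values = np.array([getattr(s, variable) for s in patients], dtype=float)
    usable = np.isfinite(values)
    if usable.sum() < 3:
        raise ValueError(f"fewer than 3 patients with non-missing {variable}")
    subjects = [s for s, u in zip(patients, usable) if u]
    y = values[usable]
    mask = compute_common_mask([s.image for s in cohort.subjects])
    fm = vectorize([s.image for s in subjects], mask, [s.subject_id for s in subjects])
    X = fm.values
    preds = np.empty(y.size)
    for i in range(y.size):
        tr = np.arange(y.size) != i
        # center features and target on the training fold: the raw FA kernel
        # is dominated by its constant component, which would otherwise make
        # every held-out prediction track the left-out training mean
        x_mean = X[tr].mean(axis=0)
        y_mean = y[tr].mean()
        model = krr_fit(X[tr] - x_mean, y[tr] - y_mean, config)
        preds[i] = y_mean + krr_predict(model, X[i] - x_mean)
    pred_series = pd.Series(preds, index=[s.subject_id for s in subjects], name=f"{variable}_pred")
    r, p = stats.pearsonr(preds, y)
    assoc = AssociationResult(
        variable=variable, stat_name="r", statistic=float(r), df=y.size - 2, p_value=float(p)
    )
    return pred_series, assoc


def clinical_association_table(
    cohort: Cohort, report: ClassificationReport, krr_config: KRRConfig | None = None
) -> pd.DataFrame:
    """Tidy table of all three clinical analyses over the PANSS/dose battery.

    Platt scaling is fit on the pooled out-of-fold decision values (each
    subject's decision value comes from the fold where it was a test case),
    then the patient posteriors are correlated with each variable. No
    multiple-testing correction is applied across the battery.
    """
    table = cohort.to_frame().set_index("subject_id")
    per = report.per_subject.set_index("subject_id")
    y = np.where(per["true_label"] == "patient", PATIENT, -1)
    params = platt_fit(per["decision_value"].to_numpy(), y)
    probs = pd.Series(
        platt_prob(params, per["decision_value"].to_numpy()), index=per.index, name="platt_prob"
    )
    patient_ids = table.index[table["label"] == "patient"]
    rows = []
    for var in CLINICAL_VARIABLES:
        vals = table.loc[patient_ids, var]
        try:
            rows.append(("ttest_correct_vs_incorrect", ttest_correct_vs_incorrect(report, vals, var)))
        except ValueError as exc:  # e.g. every patient classified correctly
            logger.warning("t-test skipped for %s: %s", var, exc)
        try:
            rows.append(("platt_prob_correlation", correlate_prob_clinical(probs.loc[patient_ids], vals, var)))
        except ValueError as exc:
            logger.warning("correlation skipped for %s: %s", var, exc)
        try:
            _, res_k = krr_cv_predict(cohort, var, krr_config)
            rows.append(("krr_loo_prediction", res_k))
        except ValueError as exc:
            logger.warning("KRR skipped for %s: %s", var, exc)
    return pd.DataFrame(
        [
            dict(
                analysis=kind,
                variable=r.variable,
                stat_name=r.stat_name,
                statistic=r.statistic,
                df=r.df,
                p_value=r.p_value,
            )
            for kind, r in rows
        ]
    )
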