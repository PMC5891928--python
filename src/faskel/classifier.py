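"""Linear soft-margin SVM for voxel patterns, and Platt probability scaling.

The classifier minimizes (1/2)||w||^2 + C * sum_i max(0, 1 - y_i (w.x_i + b))
with labels y in {-1 (control), +1 (patient)}. Because skeleton voxels vastly
outnumber subjects, the problem is solved in the dual on the subjects-sized
Gram matrix with a most-violating-pair SMO scheme (the working-set strategy
of kernel SVM toolboxes); the primal weight vector is reconstructed as
w = sum_i alpha_i y_i x_i afterwards.

Platt scaling maps decision values f to posterior probabilities
p(patient | f) = 1 / (1 + exp(A f + B)) by maximizing the Bernoulli
likelihood with Platt's smoothed targets, via a damped Newton iteration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging import CommonMask, FeatureMatrix, VoxelImage, devectorize

logger = logging.getLogger("faskel")

__all__ = [
    "SVMConfig",
    "SVMModel",
    "ConvergenceError",
    "train_linear_svm",
    "decision_value",
    "predict_label",
    "weight_map",
    "PlattParams",
    "platt_fit",
    "platt_prob",
    "save_model",
]

PATIENT, CONTROL = 1, -1


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit exhausts its iteration budget."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (after {n_iter} iterations)")
        self.n_iter = n_iter


@dataclass
class SVMConfig:
    """Soft-margin cost and solver controls.

    ``C`` is kept at 1 throughout the analyses: with far more voxels than
    subjects the solution is insensitive to C over a wide range, and a fixed
    out-of-the-box value avoids nested cross-validation. ``mean_center``
    optionally centers features using training-fold statistics only.
    """

    C: float = 1.0
    tolerance: float = 1e-6
    max_iter: int = 10_000
    mean_center: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.tolerance <= 0 or self.max_iter < 1:
            raise ValueError("invalid solver controls")


@dataclass
class SVMModel:
    """A trained linear SVM: dual multipliers plus the primal hyperplane."""

    w: np.ndarray | None
    b: float
    dual_coefs: np.ndarray  # alpha_i in [0, C]
    labels: np.ndarray  # y_i in {-1, +1}
    train_ids: list[str]
    config: SVMConfig
    feature_means: np.ndarray | None = None  # set when mean_center is on
    n_iter: int = 0


def solve_svc_dual(
    K: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tolerance: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float, int]:
    """SMO on the C-SVM dual given a precomputed Gram matrix.

    Minimizes (1/2) a'Qa - 1'a with Q_ij = y_i y_j K_ij subject to
    0 <= a <= C and y'a = 0, selecting the maximal violating pair each
    iteration (the classic first-order working-set rule). Returns
    (alpha, bias, iterations). The stopping rule bounds the KKT violation,
    which also bounds the duality gap of the reconstructed primal.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be +/-1")
    if np.all(y == y[0]):
        raise ValueError("training labels contain a single class")
    Q = K * np.outer(y, y)
    qd = np.diag(Q).copy()
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of the dual objective at alpha = 0
    tau = 1e-12
    it = 0
    while True:
        # I_up: alpha can increase along +y; I_low: can decrease
        minus_yG = -y * G
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        m_up = np.where(up, minus_yG, -np.inf)
        m_low = np.where(low, minus_yG, np.inf)
        i = int(np.argmax(m_up))
        j = int(np.argmin(m_low))
        gap = m_up[i] - m_low[j]
        if gap <= tolerance:
            break
        if it >= max_iter:
            raise ConvergenceError(
                f"SVM dual solver did not reach tolerance {tolerance:g}; gap {gap:.3g}",
                it,
            )
        it += 1
        a_i, a_j = alpha[i], alpha[j]
        if y[i] != y[j]:
            quad = qd[i] + qd[j] + 2.0 * Q[i, j]
            delta = (-G[i] - G[j]) / max(quad, tau)
            diff = a_i - a_j
            a_i += delta
            a_j += delta
            if diff > 0:
                if a_j < 0:
                    a_j, a_i = 0.0, diff
                if a_i > C:
                    a_i, a_j = C, C - diff
            else:
                if a_i < 0:
                    a_i, a_j = 0.0, -diff
                if a_j > C:
                    a_j, a_i = C, C + diff
        else:
            quad = qd[i] + qd[j] - 2.0 * Q[i, j]
            delta = (G[i] - G[j]) / max(quad, tau)
            s = a_i + a_j
            a_i -= delta
            a_j += delta
            if s > C:
                if a_i > C:
                    a_i, a_j = C, s - C
                elif a_j > C:
                    a_j, a_i = C, s - C
            else:
                if a_j < 0:
                    a_j, a_i = 0.0, s
                elif a_i < 0:
                    a_i, a_j = 0.0, s
        d_i, d_j = a_i - alpha[i], a_j - alpha[j]
        alpha[i], alpha[j] = a_i, a_j
        G += Q[:, i] * d_i + Q[:, j] * d_j
    # bias from the KKT conditions: -y_t G_t = b for free support vectors
    free = (alpha > 0) & (alpha < C)
    if free.any():
        b = float(np.mean((-y * G)[free]))
    else:
        b = float((m_up[i] + m_low[j]) / 2.0)
    return alpha, b, it


def train_linear_svm(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    config: SVMConfig | None = None,
    gram: np.ndarray | None = None,
) -> SVMModel:
    """Fit the linear SVM on a subjects-by-voxels matrix.

    ``labels`` uses +1 for patients and -1 for controls. A precomputed Gram
    matrix may be supplied to amortize kernel computation across
    cross-validation folds; it must equal X @ X.T of the (uncentered)
    features.
    """
    config = config or SVMConfig()
    if isinstance(features, FeatureMatrix):
        X = features.values
        ids = list(features.subject_ids)
    else:
        X = np.asarray(features, dtype=float)
        ids = [f"s{i}" for i in range(X.shape[0])]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = np.asarray(labels, dtype=float)
    if y.size != X.shape[0]:
        raise ValueError("one label per subject required")
    means = None
    if config.mean_center:
        means = X.mean(axis=0)
        X = X - means
        gram = None  # centering invalidates a precomputed Gram matrix
    K = gram if gram is not None else X @ X.T
    alpha, b, n_iter = solve_svc_dual(K, y, config.C, config.tolerance, config.max_iter)
    w = X.T @ (alpha * y)
    return SVMModel(
        w=w,
        b=b,
        dual_coefs=alpha,
        labels=y,
        train_ids=ids,
        config=config,
        feature_means=means,
        n_iter=n_iter,
    )


def decision_value(model: SVMModel, x: np.ndarray) -> float | np.ndarray:
    """Signed distance surrogate f = w.x + b; sign(f) is the predicted class."""
    x = np.asarray(x, dtype=float)
    if model.w is None:
        raise ValueError("model has no primal weights")
    if x.shape[-1] != model.w.size:
        raise ValueError(f"feature length {x.shape[-1]} != weight length {model.w.size}")
    if model.feature_means is not None:
        x = x - model.feature_means
    f = x @ model.w + model.b
    return float(f) if np.ndim(f) == 0 else f


def predict_label(f: float | np.ndarray) -> int | np.ndarray:
    """Label from a decision value; the tie f = 0 goes to the control class."""
    return np.where(np.asarray(f) > 0, PATIENT, CONTROL)[()]


def weight_map(model: SVMModel, mask: CommonMask) -> VoxelImage:
    """Render the primal weight vector as a voxel image (zero off the mask).

    Positive weights are evidence for the patient class, so a region where
    reduced FA characterizes patients carries negative weights.
    """
    if model.w is None or model.w.size != mask.n_voxels:
        raise ValueError("model weight length does not match the mask")
    return devectorize(model.w, mask)


@dataclass
class PlattParams:
    """Sigmoid parameters of p(f) = 1 / (1 + exp(A f + B))."""

    A: float
    B: float


def platt_fit(
    decision_values: Sequence[float],
    labels: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> PlattParams:
    """Fit the Platt sigmoid by damped Newton iteration.

    Targets are the smoothed frequencies t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2), which regularize the maximum-likelihood fit against
    degenerate separable inputs.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if f.size != y.size or f.size == 0:
        raise ValueError("decision values and labels must align and be nonempty")
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    sigma = 1e-12  # Hessian damping

    def objective(a: float, b: float) -> float:
        z = a * f + b
        # stable: t*z + log(1 + exp(-z)) for z >= 0, (t-1)*z + log(1+exp(z)) else
        return float(
            np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)), (t - 1) * z + np.log1p(np.exp(z))))
        )

    obj = objective(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p  # dF/dz per point
        d2 = p * (1 - p)
        g_a = float(np.dot(f, d1))
        g_b = float(np.sum(d1))
        if abs(g_a) < tol and abs(g_b) < tol:
            return PlattParams(A, B)
        h11 = float(np.dot(f * f, d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h12 = float(np.dot(f, d2))
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g_a - h12 * g_b) / det
        dB = -(-h12 * g_a + h11 * g_b) / det
        step = 1.0
        while step >= 1e-10:
            new_obj = objective(A + step * dA, B + step * dB)
            if new_obj < obj + 1e-4 * step * (g_a * dA + g_b * dB):
                A, B = A + step * dA, B + step * dB
                obj = new_obj
                break
            step /= 2.0
        else:
            # no descent step found: at numerical convergence this is benign
            if abs(g_a) < 1e-5 and abs(g_b) < 1e-5:
                return PlattParams(A, B)
            raise ConvergenceError("Platt line search failed", 0)
    raise ConvergenceError("Platt scaling did not converge", max_iter)


def platt_prob(params: PlattParams, f: float | np.ndarray) -> float | np.ndarray:
    """Posterior probability of the patient class for decision value(s) f."""
    z = params.A * np.asarray(f, dtype=float) + params.B
    p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
    return float(p) if np.ndim(p) == 0 else p


def save_model(model: SVMModel, mask: CommonMask, outdir, stem: str = "svm") -> None:
    """Serialize a model as a NIfTI weight map plus JSON scalar metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weight_map(model, mask).save(outdir / f"{stem}_weights.nii.gz")
    meta = dict(
        bias=model.b,
        C=model.config.C,
        tolerance=model.config.tolerance,
        mean_center=model.config.mean_center,
        n_iter=model.n_iter,
        train_ids=model.train_ids,
        dual_coefs=model.dual_coefs.tolist(),
        labels=model.labels.tolist(),
    )
    (outdir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
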