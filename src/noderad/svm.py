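"""Soft-margin Gaussian-kernel SVM trained by Sequential Minimal
Optimization, with Platt scaling for probability outputs.

The dual problem

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

is solved by the simplified SMO scheme: sweep the working index i over
all samples, pick the partner j at random (seeded), solve the
two-variable subproblem analytically, and clip to the box.  Sweeps
continue until ``max_passes`` consecutive sweeps change nothing at KKT
tolerance ``tol``.  The kernel is k(x, y) = exp(-||x - y||^2 / (2
sigma^2)), parameterized by the width sigma.

Probabilities come from Platt's sigmoid p(y=1|s) = 1 / (1 + exp(A s +
B)) fitted on the training decision scores by regularized maximum
likelihood with smoothed targets (Newton iterations with backtracking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import ValidationError

__all__ = [
    "SVMConfig",
    "TrainedSVM",
    "gaussian_kernel",
    "kernel_matrix",
    "smo_train",
    "decision_function",
    "platt_calibrate",
    "predict_probability",
    "dual_objective",
]


@dataclass
class SVMConfig:
    C: float = 1.0
    sigma: float = 1.0
    tol: float = 1e-3
    max_passes: int = 5
    max_iter: int = 2_000_000  # hard cap on pair updates
    seed: int = 0

    def validate(self) -> None:
        if self.C <= 0 or self.sigma <= 0 or self.tol <= 0:
            raise ValidationError("C, sigma and tol must be > 0")


@dataclass
class TrainedSVM:
    support_vectors: np.ndarray  # (n_sv, d)
    dual_coef: np.ndarray  # alpha_i * y_i, length n_sv
    bias: float
    sigma: float
    C: float
    platt_a: float = 0.0
    platt_b: float = 0.0
    dual_objective_value: float = 0.0
    # full training-set multipliers, kept for KKT audits (not serialized)
    alpha_full: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "sigma": self.sigma,
            "C": self.C,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedSVM":
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            sigma=float(d["sigma"]),
            C=float(d["C"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
        )


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """exp(-||x - y||^2 / (2 sigma^2)); symmetric, k(x, x) = 1."""
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("kernel arguments must have equal length")
    d2 = float(((x - y) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def dual_objective(alpha: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def smo_train(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> TrainedSVM:
    """Train the soft-margin Gaussian SVM by simplified SMO.

    ``y`` must be in {-1, +1} with both classes present.  Deterministic
    for a fixed ``config.seed``.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be (n, d) with one label per row")
    if not set(np.unique(y)) <= {-1.0, 1.0} or len(np.unique(y)) < 2:
        raise ValidationError("labels must be in {-1,+1} with both classes present")

    n = len(y)
    C, tol = config.C, config.tol
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    K = kernel_matrix(X, X, config.sigma)
    alpha = np.zeros(n)
    b = 0.0
    # error cache: E_i = f(x_i) - y_i, maintained incrementally
    E = -y.copy()

    passes = 0
    iters = 0
    while passes < config.max_passes and iters < config.max_iter:
        num_changed = 0
        for i in range(n):
            Ei = E[i]
            r = Ei * y[i]
            if not ((r < -tol and alpha[i] < C) or (r > tol and alpha[i] > 0)):
                continue
            j = int(rng.integers(0, n - 1))
            if j >= i:
                j += 1
            iters += 1
            Ej = E[j]
            ai_old, aj_old = alpha[i], alpha[j]
            if y[i] != y[j]:
                L = max(0.0, aj_old - ai_old)
                H = min(C, C + aj_old - ai_old)
            else:
                L = max(0.0, ai_old + aj_old - C)
                H = min(C, ai_old + aj_old)
            if L >= H:
                continue
            eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
            if eta >= 0:
                continue
            aj = aj_old - y[j] * (Ei - Ej) / eta
            aj = min(max(aj, L), H)
            if abs(aj - aj_old) < 1e-12:
                continue
            ai = ai_old + y[i] * y[j] * (aj_old - aj)
            # exact clipping of roundoff at the box boundary
            ai = min(max(ai, 0.0), C)
            b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
            b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
            if 0 < ai < C:
                b_new = b1
            elif 0 < aj < C:
                b_new = b2
            else:
                b_new = 0.5 * (b1 + b2)
            E += (
                y[i] * (ai - ai_old) * K[:, i]
                + y[j] * (aj - aj_old) * K[:, j]
                + (b_new - b)
            )
            alpha[i], alpha[j], b = ai, aj, b_new
            num_changed += 1
        passes = passes + 1 if num_changed == 0 else 0

    # Recompute the bias from the converged multipliers: with free
    # support vectors b is determined by their margin equations; with
    # all multipliers at bounds b is only box-constrained, and the last
    # working-pair update need not land inside the valid interval.
    g = (alpha * y) @ K
    free = (alpha > 1e-12) & (alpha < C - 1e-12)
    if free.any():
        b = float(np.mean(y[free] - g[free]))
    else:
        lowers = np.r_[
            (1.0 - g)[(y > 0) & (alpha <= 1e-12)],
            (-1.0 - g)[(y < 0) & (alpha >= C - 1e-12)],
        ]
        uppers = np.r_[
            (1.0 - g)[(y > 0) & (alpha >= C - 1e-12)],
            (-1.0 - g)[(y < 0) & (alpha <= 1e-12)],
        ]
        lo = lowers.max() if len(lowers) else -np.inf
        hi = uppers.min() if len(uppers) else np.inf
        if np.isfinite(lo) and np.isfinite(hi):
            b = 0.5 * (lo + hi)
        elif np.isfinite(lo):
            b = float(lo)
        elif np.isfinite(hi):
            b = float(hi)

    sv = alpha > 0
    return TrainedSVM(
        support_vectors=X[sv].copy(),
        dual_coef=(alpha * y)[sv],
        bias=b,
        sigma=config.sigma,
        C=C,
        dual_objective_value=dual_objective(alpha, y, K),
        alpha_full=alpha,
    )


def decision_function(model: TrainedSVM, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i k(x_i, x) + b for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.support_vectors.size and X.shape[1] != model.support_vectors.shape[1]:
        raise ValidationError("feature length mismatch with the trained model")
    if model.support_vectors.size == 0:
        return np.full(len(X), model.bias)
    K = kernel_matrix(X, model.support_vectors, model.sigma)
    return K @ model.dual_coef + model.bias


def platt_calibrate(
    scores: np.ndarray, labels: np.ndarray, max_iter: int = 100
) -> tuple[float, float]:
    """Fit Platt's sigmoid A, B on decision scores and {-1,+1} labels.

    Uses the smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)
    and a Newton method with backtracking on the cross-entropy
    objective.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels > 0
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("Platt calibration needs both classes")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))

    def objective(A: float, B: float) -> float:
        z = A * scores + B
        # stable cross-entropy: t*log(1+e^-z .. ) formulation
        return float(
            np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)), (t - 1) * z + np.log1p(np.exp(z))))
        )

    f_old = objective(A, B)
    for _ in range(max_iter):
        z = A * scores + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p  # dl/dz
        d2 = p * (1 - p)
        g_a = float((scores * d1).sum())
        g_b = float(d1.sum())
        if abs(g_a) < 1e-10 and abs(g_b) < 1e-10:
            break
        h_aa = float((scores * scores * d2).sum()) + 1e-12
        h_ab = float((scores * d2).sum())
        h_bb = float(d2.sum()) + 1e-12
        det = h_aa * h_bb - h_ab * h_ab
        if det <= 0:
            break
        dA = -(h_bb * g_a - h_ab * g_b) / det
        dB = -(-h_ab * g_a + h_aa * g_b) / det
        step = 1.0
        while step > 1e-10:
            f_new = objective(A + step * dA, B + step * dB)
            if f_new < f_old + 1e-12:
                A += step * dA
                B += step * dB
                f_old = f_new
                break
            step /= 2.0
        else:
            break
    return A, B


def predict_probability(model: TrainedSVM, X: np.ndarray) -> np.ndarray:
    """Calibrated P(malignant | x) = sigmoid of the decision score."""
    s = decision_function(model, X)
    z = model.platt_a * s + model.platt_b
    return np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
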