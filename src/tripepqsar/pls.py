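"""PLS1 regression with autoscaling, cross-validated Q2 and component choice.

The modeling conventions follow small-n chemometric practice: every variable
is autoscaled to unit variance, the response is mean-centered (not scaled),
Q2(c) = 1 - PRESS(c)/TSS with TSS taken about the mean of all samples, and
the optimal component count maximizes Q2 (ties broken toward the smaller
model).  The default cross-validation scheme is leave-one-out with the
scaling re-estimated inside each training fold; a "global" pre-scaling mode
is available for sensitivity analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import column_scaling, cv_press, pls1_paths

DEFAULT_MAX_COMPONENTS = 20


@dataclass(frozen=True)
class ScalingParams:
    """Per-variable mean / sd and response mean, fitted on training data."""

    x_mean: np.ndarray
    x_inv_sd: np.ndarray
    y_mean: float

    @property
    def constant_columns(self) -> np.ndarray:
        """Boolean mask of columns flagged as (near-)zero variance."""
        return self.x_inv_sd == 0.0

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) * self.x_inv_sd


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: 'loo' or seeded k-fold."""

    kind: str = "loo"
    k: int = 10
    seed: int = 0
    scaling_mode: str = "per-fold"

    def __post_init__(self):
        if self.kind not in ("loo", "kfold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k-fold CV needs k >= 2")
        if self.scaling_mode not in ("per-fold", "global"):
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")

    def fold_assignment(self, n: int) -> np.ndarray:
        if self.kind == "loo":
            return np.arange(n, dtype=np.int64)
        rng = np.random.default_rng(self.seed)
        folds = np.arange(n, dtype=np.int64) % self.k
        return rng.permutation(folds)


@dataclass
class ModelFit:
    """A fitted PLS model on the original (unscaled) variable space."""

    n_components: int
    coefficients: np.ndarray
    intercept: float
    r2: float
    scaling: ScalingParams
    q2: Optional[float] = None
    coef_scaled: np.ndarray = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coefficients

    def to_report(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "r2": float(self.r2),
            "q2": None if self.q2 is None else float(self.q2),
            "intercept": float(self.intercept),
            "coefficients": [float(c) for c in self.coefficients],
        }


def autoscale(X: np.ndarray, y: np.ndarray):
    """Autoscale X to zero mean / unit variance and center y.

    Near-constant columns (sd < 1e-12) are scaled to zeros rather than
    dividing by zero; the returned parameters reproduce the transformation
    on held-out data.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    mu, inv = column_scaling(X)
    params = ScalingParams(x_mean=mu, x_inv_sd=inv, y_mean=float(y.mean()))
    return params.apply(X), y - params.y_mean, params


def _component_cap(n: int, p: int, requested: int) -> int:
    return max(1, min(requested, n - 1, p))


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scaling: ScalingParams | None = None,
    q2: float | None = None,
) -> ModelFit:
    """Fit a PLS1 model with a fixed component count (deterministic NIPALS)."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} out of range 1..{min(n - 1, p)}"
        )
    if np.std(y) < 1e-12:
        raise ValueError("response has zero variance")
    if scaling is None:
        Xs, yc, scaling = autoscale(X, y)
    else:
        Xs, yc = scaling.apply(X), y - scaling.y_mean
    B = pls1_paths(Xs, yc, n_components)
    b_scaled = B[:, n_components - 1]
    coef = b_scaled * scaling.x_inv_sd
    intercept = scaling.y_mean - float(scaling.x_mean @ coef)
    resid = y - (intercept + X @ coef)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss
    return ModelFit(
        n_components=n_components, coefficients=coef, intercept=intercept,
        r2=r2, scaling=scaling, q2=q2, coef_scaled=b_scaled,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    scheme: CVScheme = CVScheme(),
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> np.ndarray:
    """Q2 per component count 1..max_components under the given scheme."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    fold_of = scheme.fold_assignment(n)
    n_folds = n if scheme.kind == "loo" else scheme.k
    counts = np.bincount(fold_of, minlength=n_folds)
    if (n - counts.max()) < 2:
        raise ValueError("a fold leaves fewer than 2 training samples")
    cmax = _component_cap(n - counts.max(), p, max_components)
    if scheme.scaling_mode == "per-fold":
        press = cv_press(X, y, fold_of, n_folds, cmax, True)
    else:
        Xs, yc, _ = autoscale(X, y)
        press = cv_press(Xs, yc, fold_of, n_folds, cmax, False)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss < 1e-12:
        raise ValueError("response has zero variance")
    return 1.0 - press / tss


def select_components(q2_curve) -> int:
    """Component count maximizing Q2; ties go to the smaller model."""
    q2_curve = np.asarray(q2_curve, dtype=float)
    if q2_curve.size == 0:
        raise ValueError("empty Q2 curve")
    return int(np.argmax(q2_curve)) + 1


def fit_with_cv(
    X: np.ndarray,
    y: np.ndarray,
    scheme: CVScheme = CVScheme(),
    max_components: int = DEFAULT_MAX_COMPONENTS,
):
    """Component search + final fit; returns (ModelFit, q2_curve)."""
    q2 = cross_validate(X, y, scheme, max_components)
    opt = select_components(q2)
    model = fit_pls(X, y, opt, q2=float(q2[opt - 1]))
    return model, q2
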