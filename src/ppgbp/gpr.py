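"""Exponential-kernel Gaussian-process regression for blood-pressure estimation.

The covariance between two feature vectors is k(x, x') = S² exp(−d/ℓ), with d
the Euclidean distance in standardised feature space, ℓ the kernel scale and
S the signal standard deviation.  Two initialisation statistics accompany the
kernel: ``xmax_range`` — the largest per-feature range of the training matrix,
which bounds the kernel-scale search interval [0.001, 1]×XMaxRange — and
``signal_std_init`` — the pooled standard deviation of all matrix entries.

Fine-tuning re-fits a model on new data with ℓ and S frozen at the pretrained
values (the shipped configuration uses ℓ = 11.9, S = 9.6); only the noise
level is re-estimated, by marginal-likelihood maximisation, which makes the
refit a cheap one-dimensional search instead of a full hyperparameter
optimisation.

One model is trained per target (SBP or DBP); the regressor predicts absolute
pressure in mmHg, later anchored to a cuff reading by the calibration module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

from .features import FEATURE_NAMES, FeatureMatrix

__all__ = [
    "PRETRAINED_KERNEL_SCALE",
    "PRETRAINED_SIGNAL_STD",
    "KernelParams",
    "GPRModel",
    "xmax_range",
    "kernel_scale_search_interval",
    "signal_std_init",
    "exp_kernel",
    "fit",
    "predict",
    "finetune",
    "save_model",
    "load_model",
]

# Shipped pretrained-configuration kernel constants.
PRETRAINED_KERNEL_SCALE = 11.9
PRETRAINED_SIGNAL_STD = 9.6

_JITTER_FRAC = 1e-8  # of signal variance, added to the kernel diagonal


@dataclass(frozen=True)
class KernelParams:
    """Exponential-kernel hyperparameters (all strictly positive)."""

    kernel_scale: float
    signal_std: float
    noise_std: float = 1.0

    def __post_init__(self) -> None:
        if min(self.kernel_scale, self.signal_std, self.noise_std) <= 0:
            raise ValueError("kernel parameters must be strictly positive")


def xmax_range(X: FeatureMatrix | np.ndarray) -> float:
    """Largest per-feature range: max over columns of (column max − column min)."""
    A = X.X if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    if A.size == 0:
        raise ValueError("empty feature matrix")
    return float(np.max(A.max(axis=0) - A.min(axis=0)))


def kernel_scale_search_interval(X: FeatureMatrix | np.ndarray) -> tuple[float, float]:
    """Kernel-scale search interval [0.001, 1] × XMaxRange."""
    r = xmax_range(X)
    return 0.001 * r, 1.0 * r


def signal_std_init(X: FeatureMatrix | np.ndarray) -> float:
    """Pooled standard deviation of all matrix entries.

    With μ the mean over every entry of the matrix and N the number of
    entries, S = sqrt(Σ|Xᵢ − μ|² / (N − 1)).
    """
    A = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    flat = A.ravel()
    if flat.size < 2:
        raise ValueError("need at least 2 entries")
    mu = float(np.mean(flat))
    return float(np.sqrt(np.sum(np.abs(flat - mu) ** 2) / (flat.size - 1)))


def exp_kernel(xi: np.ndarray, xj: np.ndarray, params: KernelParams) -> float:
    """k(xi, xj) = S² exp(−‖xi − xj‖ / ℓ)."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    d = float(np.linalg.norm(xi - xj))
    return params.signal_std**2 * float(np.exp(-d / params.kernel_scale))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, params: KernelParams) -> np.ndarray:
    D = cdist(A, B, metric="euclidean")
    return params.signal_std**2 * np.exp(-D / params.kernel_scale)


@dataclass
class GPRModel:
    """A fitted exponential-kernel GP for one target (SBP or DBP).

    Features are standardised by the training-set column mean/SD before any
    distance computation; the constants are stored with the model.  The
    training-kernel Cholesky factor and weight vector are cached so that
    prediction is a pair of triangular solves.
    """

    X_train: np.ndarray              # standardised training features
    y_train: np.ndarray
    params: KernelParams
    mean_const: float                # prior mean = training-response mean
    feat_mean: np.ndarray
    feat_std: np.ndarray
    target: str = "SBP"
    optimized: tuple[str, ...] = ()  # which hyperparameters the optimiser searched
    _L: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.feat_mean) / self.feat_std

    def _ensure_cache(self) -> None:
        if self._L is None:
            K = _kernel_matrix(self.X_train, self.X_train, self.params)
            K[np.diag_indices_from(K)] += (
                self.params.noise_std**2 + _JITTER_FRAC * self.params.signal_std**2
            )
            try:
                self._L = linalg.cholesky(K, lower=True)
            except linalg.LinAlgError as exc:
                raise ValueError("kernel matrix not positive definite after jitter") from exc
            self._alpha = linalg.cho_solve((self._L, True), self.y_train - self.mean_const)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    return mean, std


def _neg_log_marginal(Xs: np.ndarray, yc: np.ndarray, params: KernelParams) -> float:
    K = _kernel_matrix(Xs, Xs, params)
    K[np.diag_indices_from(K)] += params.noise_std**2 + _JITTER_FRAC * params.signal_std**2
    try:
        L = linalg.cholesky(K, lower=True)
    except linalg.LinAlgError:
        return np.inf
    alpha = linalg.cho_solve((L, True), yc)
    return float(0.5 * yc @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * len(yc) * np.log(2 * np.pi))


def fit(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    init: KernelParams | None = None,
    fix_kernel: bool = False,
    target: str = "SBP",
) -> GPRModel:
    """Fit the GP, optionally freezing the kernel at the given hyperparameters.

    With ``fix_kernel`` the kernel scale and signal SD are held exactly at the
    ``init`` values and only the noise SD is estimated by marginal-likelihood
    maximisation (plus the constant mean, set to the training-response mean).
    Otherwise all three hyperparameters are optimised, the kernel scale from
    the data-driven interval [0.001, 1]×XMaxRange and the signal SD from the
    pooled-entry standard deviation.
    """
    A = X.X if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if A.shape[0] != len(y):
        raise ValueError("row count of X must equal length of y")
    feat_mean, feat_std = _standardize_fit(A)
    Xs = (A - feat_mean) / feat_std
    mean_const = float(np.mean(y))
    yc = y - mean_const
    y_sd = float(np.std(yc, ddof=1)) if len(yc) > 1 else 1.0
    y_sd = max(y_sd, 1e-3)

    if init is None:
        lo, hi = kernel_scale_search_interval(Xs)
        init = KernelParams(
            kernel_scale=max(np.sqrt(lo * hi), 1e-6) if hi > 0 else 1.0,
            signal_std=max(signal_std_init(Xs), 1e-6) * y_sd,
            noise_std=0.1 * y_sd,
        )

    if fix_kernel:
        # 1-D search over the noise level only
        def nll(log_noise: np.ndarray) -> float:
            p = KernelParams(init.kernel_scale, init.signal_std, float(np.exp(log_noise[0])))
            return _neg_log_marginal(Xs, yc, p)

        res = optimize.minimize(
            nll, x0=[np.log(max(init.noise_std, 1e-3))], method="L-BFGS-B",
            bounds=[(np.log(1e-4 * y_sd), np.log(10 * y_sd))],
        )
        params = KernelParams(init.kernel_scale, init.signal_std, float(np.exp(res.x[0])))
        optimized = ("noise_std",)
    else:
        lo, hi = kernel_scale_search_interval(Xs)
        lo = max(lo, 1e-6)
        hi = max(hi, lo * 1000)

        def nll3(logp: np.ndarray) -> float:
            p = KernelParams(*np.exp(logp))
            return _neg_log_marginal(Xs, yc, p)

        res = optimize.minimize(
            nll3,
            x0=np.log([init.kernel_scale, init.signal_std, max(init.noise_std, 1e-3)]),
            method="L-BFGS-B",
            bounds=[
                (np.log(lo), np.log(hi)),
                (np.log(1e-3 * y_sd), np.log(100 * y_sd)),
                (np.log(1e-4 * y_sd), np.log(10 * y_sd)),
            ],
        )
        params = KernelParams(*np.exp(res.x))
        optimized = ("kernel_scale", "signal_std", "noise_std")

    model = GPRModel(
        X_train=Xs, y_train=y, params=params, mean_const=mean_const,
        feat_mean=feat_mean, feat_std=feat_std, target=target, optimized=optimized,
    )
    model._ensure_cache()
    return model


def predict(model: GPRModel, x_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GP posterior mean and predictive standard deviation at query rows.

    The predictive variance includes the noise term, so far from all training
    points the mean reverts to the training mean and the SD to
    sqrt(S² + noise²).  Accepts a single feature row or a 2-D block; returns
    arrays of matching length (scalars squeeze naturally via item()).
    """
    if model._L is None:
        model._ensure_cache()
    Xq = model.standardize(np.asarray(x_star, dtype=float))
    k_star = _kernel_matrix(Xq, model.X_train, model.params)
    mean = model.mean_const + k_star @ model._alpha
    v = linalg.solve_triangular(model._L, k_star.T, lower=True)
    var = (
        model.params.signal_std**2
        + model.params.noise_std**2
        - np.sum(v**2, axis=0)
    )
    return mean, np.sqrt(np.maximum(var, 0.0))


def predict_one(model: GPRModel, x_star: np.ndarray) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`predict`."""
    m, s = predict(model, x_star)
    return float(m[0]), float(s[0])


def finetune(pretrained: GPRModel, X_new: FeatureMatrix | np.ndarray, y_new: np.ndarray) -> GPRModel:
    """Re-train on new data with the pretrained kernel hyperparameters frozen.

    Equivalent by definition to ``fit(X_new, y_new, pretrained.params,
    fix_kernel=True)``.  The pretrained model is left untouched; with no new
    data it is returned unchanged.
    """
    A = X_new.X if isinstance(X_new, FeatureMatrix) else np.atleast_2d(np.asarray(X_new, dtype=float))
    if A.size == 0 or len(np.asarray(y_new)) == 0:
        return pretrained
    return fit(A, y_new, init=pretrained.params, fix_kernel=True, target=pretrained.target)


def save_model(model: GPRModel, path: str | Path) -> None:
    """Serialise a fitted model (hyperparameters, standardisation, training set) to JSON."""
    payload = {
        "target": model.target,
        "params": {
            "kernel_scale": model.params.kernel_scale,
            "signal_std": model.params.signal_std,
            "noise_std": model.params.noise_std,
        },
        "mean_const": model.mean_const,
        "feat_mean": model.feat_mean.tolist(),
        "feat_std": model.feat_std.tolist(),
        "X_train": model.X_train.tolist(),
        "y_train": model.y_train.tolist(),
        "feature_names": list(FEATURE_NAMES),
        "optimized": list(model.optimized),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> GPRModel:
    d = json.loads(Path(path).read_text())
    model = GPRModel(
        X_train=np.array(d["X_train"], dtype=float),
        y_train=np.array(d["y_train"], dtype=float),
        params=KernelParams(**d["params"]),
        mean_const=d["mean_const"],
        feat_mean=np.array(d["feat_mean"], dtype=float),
        feat_std=np.array(d["feat_std"], dtype=float),
        target=d["target"],
        optimized=tuple(d.get("optimized", ())),
    )
    model._ensure_cache()
    return model
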