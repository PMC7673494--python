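"""Suitability model zoo.

Three presence-only scorers (BIOCLIM percentile envelope, Domain/Gower
similarity, one-class SVM boundary) back the pseudo-absence ensemble,
and four presence/absence learners (binomial GLM, maximum-entropy Gibbs
model, RBF support-vector machine, backprop neural network) produce the
habitat suitability maps.

Every model exposes the same contract: ``predict(X)`` maps an
environment matrix over the training layers to scores in [0, 1],
deterministically once fitted; standardization constants are frozen at
fit time.  The SVM family is optimized by scikit-learn but the decision
functions are evaluated from the stored support vectors, so a model
round-trips losslessly through its JSON serialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .raster import RasterGrid, RasterStack

__all__ = [
    "SuitabilityModel",
    "TrainTestSplit",
    "fit_bioclim",
    "fit_domain",
    "fit_ocsvm",
    "fit_glm",
    "fit_maxent",
    "fit_svm",
    "fit_ann",
    "predict_raster",
    "save_model",
    "load_model",
    "stratified_split",
]

PRESENCE_ONLY_KINDS = ("bioclim", "domain", "ocsvm")
PRESENCE_ABSENCE_KINDS = ("glm", "maxent", "svm", "ann")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _canonical_order(X: np.ndarray, y: np.ndarray | None = None):
    """Sort training rows lexicographically so every fit is invariant to
    the order records arrive in (iterative optimizers see one canonical
    sequence)."""
    keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)]
    if y is not None:
        keys.insert(0, y)
    order = np.lexsort(keys)
    return (X[order], None if y is None else y[order])


@dataclass
class Standardizer:
    """Per-layer mean/sd frozen at fit time."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean, sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]))


@dataclass
class SuitabilityModel:
    """A fitted model: kind, training layers, parameters, standardizer."""

    kind: str
    layer_names: list[str]
    params: dict
    standardizer: Standardizer

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scores in [0, 1] for an (n, p) environment matrix (raw units)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        fn = _PREDICTORS[self.kind]
        return np.clip(fn(self, X), 0.0, 1.0)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def _jsonable(v):
            if isinstance(v, np.ndarray):
                return {"__array__": v.tolist()}
            if isinstance(v, (np.floating, np.integer)):
                return float(v)
            return v

        return {
            "kind": self.kind,
            "layer_names": self.layer_names,
            "params": {k: _jsonable(v) for k, v in self.params.items()},
            "standardization": self.standardizer.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SuitabilityModel":
        def _restore(v):
            if isinstance(v, dict) and "__array__" in v:
                return np.asarray(v["__array__"], dtype=float)
            return v

        return cls(
            kind=d["kind"],
            layer_names=list(d["layer_names"]),
            params={k: _restore(v) for k, v in d["params"].items()},
            standardizer=Standardizer.from_dict(d["standardization"]),
        )


def save_model(model: SuitabilityModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model.to_dict()))
    return path


def load_model(path: str | Path) -> SuitabilityModel:
    return SuitabilityModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


@dataclass
class TrainTestSplit:
    """Stratified 80/20 split of occurrence rows."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int


def stratified_split(
    labels: np.ndarray, fraction: float = 0.8, seed: int = 0
) -> TrainTestSplit:
    """Disjoint, exhaustive, label-stratified split; ``fraction`` to train."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size > 1 else idx.size
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return TrainTestSplit(
        np.sort(np.asarray(train)), np.sort(np.asarray(test)), fraction, seed
    )


# ---------------------------------------------------------------------------
# BIOCLIM
# ---------------------------------------------------------------------------


def fit_bioclim(X: np.ndarray, layer_names: Sequence[str]) -> SuitabilityModel:
    """Percentile-envelope model over the training presences.

    For variable j, ``p_j(x) = (#{t < x} + 0.5 #{t == x}) / n`` — the
    mid-rank fraction of training values at or below x — and the tail
    score is ``2 min(p_j, 1 - p_j)``.  The site score is the minimum
    tail score over variables, so the training median scores 1 and any
    site outside the envelope scores 0.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("BIOCLIM needs at least 5 presences")
    return SuitabilityModel(
        kind="bioclim",
        layer_names=list(layer_names),
        params={"train": np.sort(X, axis=0)},
        standardizer=Standardizer.fit(X),
    )


def _predict_bioclim(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    train = model.params["train"]  # (n_train, p), column-sorted
    n = train.shape[0]
    scores = np.empty(X.shape)
    for j in range(train.shape[1]):
        col = train[:, j]
        less = np.searchsorted(col, X[:, j], side="left")
        leq = np.searchsorted(col, X[:, j], side="right")
        p = (less + 0.5 * (leq - less)) / n
        scores[:, j] = 2.0 * np.minimum(p, 1.0 - p)
    return scores.min(axis=1)


# ---------------------------------------------------------------------------
# Domain (Gower)
# ---------------------------------------------------------------------------


def fit_domain(X: np.ndarray, layer_names: Sequence[str]) -> SuitabilityModel:
    """Gower-similarity model: score = max over training points of
    ``1 - mean_j |x_j - t_j| / range_j``.

    Variables with zero training range carry no distance information and
    are excluded with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Domain needs at least 2 presences")
    ranges = X.max(axis=0) - X.min(axis=0)
    keep = ranges > 0
    if not keep.any():
        raise ValueError("all variables have zero training range")
    if not keep.all():
        dropped = [n for n, k in zip(layer_names, keep) if not k]
        warnings.warn(f"Domain: zero-range variables excluded: {dropped}")
    return SuitabilityModel(
        kind="domain",
        layer_names=list(layer_names),
        params={"train": X, "ranges": ranges, "keep": keep.astype(float)},
        standardizer=Standardizer.fit(X),
    )


def _predict_domain(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    train = model.params["train"]
    ranges = model.params["ranges"]
    keep = model.params["keep"].astype(bool)
    T = train[:, keep]
    R = ranges[keep]
    out = np.empty(X.shape[0])
    Xk = X[:, keep]
    for i in range(X.shape[0]):
        d = np.abs(Xk[i] - T) / R
        out[i] = 1.0 - d.mean(axis=1).min()
    return out


# ---------------------------------------------------------------------------
# One-class SVM
# ---------------------------------------------------------------------------


def _rbf_decision(X: np.ndarray, sv: np.ndarray, dual: np.ndarray, b: float, gamma: float) -> np.ndarray:
    d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-gamma * d2) @ dual + b


def fit_ocsvm(
    X: np.ndarray,
    layer_names: Sequence[str],
    nu: float = 0.1,
    gamma: float | None = None,
) -> SuitabilityModel:
    """One-class RBF boundary around the presences.

    Raw decision values are min-max rescaled to [0, 1]; calibration uses
    the training presences until :func:`calibrate_ocsvm` widens it to
    the study-area cells.  At most about a ``nu`` fraction of training
    points fall outside the boundary.
    """
    from sklearn.svm import OneClassSVM

    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("one-class SVM needs at least 2 presences")
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    X, _ = _canonical_order(X)
    std = Standardizer.fit(X)
    Z = std.transform(X)
    if gamma is None:
        gamma = 1.0 / Z.shape[1]
    oc = OneClassSVM(nu=nu, gamma=gamma, kernel="rbf", tol=1e-8).fit(Z)
    sv = oc.support_vectors_
    dual = oc.dual_coef_.ravel()
    b = float(oc.intercept_[0])
    model = SuitabilityModel(
        kind="ocsvm",
        layer_names=list(layer_names),
        params={
            "sv": sv,
            "dual": dual,
            "intercept": b,
            "gamma": gamma,
            "dmin": 0.0,
            "dmax": 1.0,
        },
        standardizer=std,
    )
    d_train = _ocsvm_raw(model, X)
    model.params["dmin"] = float(d_train.min())
    model.params["dmax"] = float(d_train.max())
    return model


def _ocsvm_raw(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    Z = model.standardizer.transform(X)
    return _rbf_decision(
        Z,
        model.params["sv"],
        model.params["dual"],
        model.params["intercept"],
        model.params["gamma"],
    )


def calibrate_ocsvm(model: SuitabilityModel, X_background: np.ndarray) -> SuitabilityModel:
    """Reset the [0, 1] rescaling range from study-area cells."""
    d = _ocsvm_raw(model, np.asarray(X_background, dtype=float))
    model.params["dmin"] = float(d.min())
    model.params["dmax"] = float(d.max())
    return model


def _predict_ocsvm(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    d = _ocsvm_raw(model, X)
    lo, hi = model.params["dmin"], model.params["dmax"]
    if hi <= lo:
        return np.where(d >= 0, 1.0, 0.0)
    return (d - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# GLM (binomial logit by IRLS)
# ---------------------------------------------------------------------------


def _irls(X1: np.ndarray, y: np.ndarray, ridge: float = 0.0, tol: float = 1e-8, max_iter: int = 100):
    beta = np.zeros(X1.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X1 @ beta
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = X1.T @ (w[:, None] * X1)
        if ridge > 0:
            A = A + ridge * np.eye(A.shape[0])
        # lstsq: rank-deficient designs (constant columns) get the
        # minimum-norm solution instead of a crash
        new = np.linalg.lstsq(A, X1.T @ (w * z), rcond=None)[0]
        delta = np.max(np.abs(new - beta))
        beta = new
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
            return beta, False
        if delta < tol:
            converged = True
            break
    return beta, converged


def fit_glm(
    X: np.ndarray, y: np.ndarray, layer_names: Sequence[str]
) -> SuitabilityModel:
    """Binomial logit fitted by iteratively reweighted least squares.

    Convergence at max |delta coef| < 1e-8 or 100 iterations.  Perfect
    separation (diverging coefficients) is detected and refitted with a
    small ridge (lambda = 1e-6), recorded in the parameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("GLM needs both classes present")
    std = Standardizer.fit(X)
    Z = std.transform(X)
    X1 = np.column_stack([np.ones(len(Z)), Z])
    beta, converged = _irls(X1, y)
    separated = not converged or np.max(np.abs(beta)) > 1e3
    if separated:
        warnings.warn("GLM: possible perfect separation; ridge fallback (1e-6)")
        beta, _ = _irls(X1, y, ridge=1e-6)
    return SuitabilityModel(
        kind="glm",
        layer_names=list(layer_names),
        params={"beta": beta, "separated": bool(separated)},
        standardizer=std,
    )


def _predict_glm(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    Z = model.standardizer.transform(X)
    X1 = np.column_stack([np.ones(len(Z)), Z])
    return _sigmoid(X1 @ model.params["beta"])


# ---------------------------------------------------------------------------
# MaxEnt (penalized Gibbs over background)
# ---------------------------------------------------------------------------


def _maxent_features(Z: np.ndarray, features: Sequence[str]) -> np.ndarray:
    cols = []
    if "linear" in features:
        cols.append(Z)
    if "quadratic" in features:
        cols.append(Z**2)
    return np.hstack(cols)


def _maxent_nll(eta: np.ndarray, F_bg: np.ndarray, fbar: np.ndarray):
    """Smooth part of the objective: log Z(eta) - eta . fbar, and gradient."""
    u = F_bg @ eta
    umax = u.max()
    w = np.exp(u - umax)
    Zc = w.sum()
    logZ = umax + np.log(Zc / len(u))  # Z normalized per background point
    p = w / Zc
    grad = F_bg.T @ p - fbar
    return logZ - eta @ fbar, grad


def fit_maxent(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    layer_names: Sequence[str],
    features: Sequence[str] = ("linear", "quadratic"),
    beta: float = 0.05,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> SuitabilityModel:
    """Maximum-entropy Gibbs density fit by proximal gradient (ISTA).

    Maximizes the presence log-likelihood of ``exp(eta . f(x)) / Z``
    over the background with an L1 penalty ``beta`` per feature
    coefficient.  The continuous output is the logistic transform
    ``sigmoid(eta . f(x) + c)`` with ``c`` set so the mean score over
    training presences is 0.5 (a documented convention that pins the
    otherwise arbitrary density scale).
    """
    Xp = np.asarray(X_presence, dtype=float)
    Xb = np.asarray(X_background, dtype=float)
    if not (np.isfinite(Xp).all() and np.isfinite(Xb).all()):
        raise ValueError("non-finite feature values")
    std = Standardizer.fit(Xb)
    Fp = _maxent_features(std.transform(Xp), features)
    Fb = _maxent_features(std.transform(Xb), features)
    fbar = Fp.mean(axis=0)

    eta = np.zeros(Fb.shape[1])
    step = 1.0
    f_old, grad = _maxent_nll(eta, Fb, fbar)
    for _ in range(max_iter):
        # backtracking line search on the smooth part
        while True:
            cand = eta - step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * beta, 0.0)
            f_new, grad_new = _maxent_nll(cand, Fb, fbar)
            diff = cand - eta
            quad = f_old + grad @ diff + (diff @ diff) / (2 * step)
            if f_new <= quad + 1e-12 or step < 1e-10:
                break
            step *= 0.5
        if np.max(np.abs(cand - eta)) < tol:
            eta, f_old, grad = cand, f_new, grad_new
            break
        eta, f_old, grad = cand, f_new, grad_new
        step = min(step * 1.5, 10.0)

    # offset c: mean presence output 0.5 (bisection on a monotone function)
    up = Fp @ eta
    lo, hi = -up.max() - 50, -up.min() + 50
    for _ in range(200):
        c = 0.5 * (lo + hi)
        if _sigmoid(up + c).mean() < 0.5:
            lo = c
        else:
            hi = c
    return SuitabilityModel(
        kind="maxent",
        layer_names=list(layer_names),
        params={"eta": eta, "offset": float(c), "features": list(features), "beta": beta},
        standardizer=std,
    )


def _predict_maxent(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    F = _maxent_features(
        model.standardizer.transform(X), model.params["features"]
    )
    return _sigmoid(F @ model.params["eta"] + model.params["offset"])


# ---------------------------------------------------------------------------
# SVM (C-classification + Platt sigmoid)
# ---------------------------------------------------------------------------


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    layer_names: Sequence[str],
    C: float = 1.0,
    gamma: float | None = None,
) -> SuitabilityModel:
    """RBF C-SVM with a Platt-style sigmoid on the decision value."""
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM needs both classes present")
    X, y = _canonical_order(X, y)
    std = Standardizer.fit(X)
    Z = std.transform(X)
    if gamma is None:
        gamma = 1.0 / Z.shape[1]
    svc = SVC(C=C, gamma=gamma, kernel="rbf").fit(Z, y)
    assert int(svc.classes_[1]) == 1
    sv = svc.support_vectors_
    dual = svc.dual_coef_.ravel()
    b = float(svc.intercept_[0])
    d = _rbf_decision(Z, sv, dual, b, gamma)

    # Platt scaling: logistic fit of labels on the decision values
    def nll(ab):
        p = _sigmoid(ab[0] * d + ab[1])
        eps = 1e-12
        return -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead")
    a_platt, b_platt = res.x
    return SuitabilityModel(
        kind="svm",
        layer_names=list(layer_names),
        params={
            "sv": sv,
            "dual": dual,
            "intercept": b,
            "gamma": gamma,
            "platt_a": float(a_platt),
            "platt_b": float(b_platt),
        },
        standardizer=std,
    )


def _predict_svm(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    Z = model.standardizer.transform(X)
    d = _rbf_decision(
        Z,
        model.params["sv"],
        model.params["dual"],
        model.params["intercept"],
        model.params["gamma"],
    )
    return _sigmoid(model.params["platt_a"] * d + model.params["platt_b"])


# ---------------------------------------------------------------------------
# BP-ANN (single hidden layer, logistic activations)
# ---------------------------------------------------------------------------


def fit_ann(
    X: np.ndarray,
    y: np.ndarray,
    layer_names: Sequence[str],
    hidden: int = 8,
    learning_rate: float = 0.01,
    epochs: int = 500,
    seed: int = 0,
) -> SuitabilityModel:
    """Single-hidden-layer network trained by backpropagation on
    cross-entropy; weights are extracted so prediction is a pure numpy
    forward pass."""
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPClassifier

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ANN needs both classes present")
    X, y = _canonical_order(X, y)
    std = Standardizer.fit(X)
    Z = std.transform(X)
    net = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="adam",
        learning_rate_init=learning_rate,
        max_iter=epochs,
        random_state=seed,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Z, y)
    if net.n_iter_ >= epochs:
        warnings.warn(
            f"ANN: epoch budget ({epochs}) exhausted; final loss {net.loss_:.4g}"
        )
    return SuitabilityModel(
        kind="ann",
        layer_names=list(layer_names),
        params={
            "w0": net.coefs_[0],
            "b0": net.intercepts_[0],
            "w1": net.coefs_[1].ravel(),
            "b1": float(net.intercepts_[1][0]),
        },
        standardizer=std,
    )


def _predict_ann(model: SuitabilityModel, X: np.ndarray) -> np.ndarray:
    Z = model.standardizer.transform(X)
    h = _sigmoid(Z @ model.params["w0"] + model.params["b0"])
    return _sigmoid(h @ model.params["w1"] + model.params["b1"])


_PREDICTORS = {
    "bioclim": _predict_bioclim,
    "domain": _predict_domain,
    "ocsvm": _predict_ocsvm,
    "glm": _predict_glm,
    "maxent": _predict_maxent,
    "svm": _predict_svm,
    "ann": _predict_ann,
}


# ---------------------------------------------------------------------------
# Raster prediction
# ---------------------------------------------------------------------------


def predict_raster(model: SuitabilityModel, stack: RasterStack) -> RasterGrid:
    """Apply a fitted model cell-wise over the stack; nodata propagates."""
    missing = [n for n in model.layer_names if n not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks training layers {missing}")
    sub = stack.subset(model.layer_names)
    mask = sub.mask
    X = sub.env_matrix(mask)
    scores = model.predict(X)
    t = stack.template
    out = np.full(t.values.shape, t.nodata, dtype=float)
    out[mask] = scores
    return t.with_values(out, name=f"suitability_{model.kind}")
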