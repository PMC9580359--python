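"""Exact-design radial basis function network classifier.

One Gaussian hidden unit is centered on every (z-scored) training sample
and the output weights plus bias are solved from the linear system
[Phi | 1] [w; b] = y in a +/-1 label coding, so a consistent system
interpolates the training labels exactly — the defining property of the
exact design (Matlab's ``newrbe``). The decision is sign(F(x)) with

    F(x) = sum_i w_i exp(-||x - c_i||^2 / (2 sigma_i^2)) + b

and ties (score exactly 0) resolved to the positive class.

Two spread conventions are supported:

``sigma_mode="literal"`` (default)
    sigma_i = spread, the Gaussian standard deviation read directly off the
    kernel formula; the reference value is spread = 16 on z-scored features.
``sigma_mode="matlab"``
    newrbe's convention: the basis function falls to 0.5 at distance
    ``spread``, i.e. f(d) = exp(-(0.8326 d / spread)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, InvalidLabelsError, InvalidParameterError

__all__ = ["RBFNetwork", "rbf_kernel", "fit_rbfnn", "predict"]

#: newrbe's half-response constant: exp(-(0.8326...)^2) = 0.5
_MATLAB_B = np.sqrt(np.log(2.0))

DEFAULT_SPREAD = 16.0


def rbf_kernel(x: np.ndarray, c: np.ndarray, sigma: float) -> float:
    """Gaussian basis exp(-||x - c||^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ContractError(f"dimension mismatch: {x.shape} vs {c.shape}")
    d2 = float(np.sum((x - c) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def _sigma_from_spread(spread: float, sigma_mode: str) -> float:
    if spread <= 0:
        raise InvalidParameterError(f"spread must be positive, got {spread}")
    if sigma_mode == "literal":
        return float(spread)
    if sigma_mode == "matlab":
        # exp(-(b d / spread)^2) == exp(-d^2 / (2 sigma^2))
        return float(spread / (_MATLAB_B * np.sqrt(2.0)))
    raise InvalidParameterError(f"unknown sigma_mode {sigma_mode!r}")


@dataclass
class RBFNetwork:
    """Fitted exact-design RBF network (one center per training sample)."""

    centers: np.ndarray          # k x d, z-scored feature space
    weights: np.ndarray          # k
    bias: float
    spread: float
    sigma: float
    sigma_mode: str
    scaler_mean: np.ndarray      # d
    scaler_scale: np.ndarray     # d
    classes: np.ndarray          # [positive, negative] original labels

    @property
    def k(self) -> int:
        return len(self.centers)

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]


def _design_matrix(X: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (np.sum(X * X, axis=1)[:, None] + np.sum(centers * centers, axis=1)[None, :]
          - 2.0 * X @ centers.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * sigma * sigma))


def fit_rbfnn(features: np.ndarray, labels: np.ndarray,
              spread: float = DEFAULT_SPREAD,
              sigma_mode: str = "literal") -> RBFNetwork:
    """Fit the exact-design network on a training matrix (samples x features).

    Features are z-scored with training statistics (constant features get
    unit scale); every scaled sample becomes a center; weights and bias are
    solved jointly by least squares. Duplicate rows make the design matrix
    singular — the solve then falls back to the minimum-norm least-squares
    solution with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ContractError("features must be samples x dims matching labels")
    if len(X) < 2:
        raise InvalidLabelsError("need at least 2 training samples")
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidLabelsError(f"need exactly 2 classes, got {list(classes)}")
    sigma = _sigma_from_spread(spread, sigma_mode)

    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    # positive class = first class in sorted order, coded +1
    t = np.where(y == classes[0], 1.0, -1.0)

    if len(np.unique(Xs, axis=0)) < len(Xs):
        warnings.warn("duplicate training rows: singular design matrix, "
                      "solving in the least-squares sense",
                      RuntimeWarning, stacklevel=2)

    Phi = _design_matrix(Xs, Xs, sigma)
    A = np.hstack([Phi, np.ones((len(Xs), 1))])
    sol, *_ = np.linalg.lstsq(A, t, rcond=None)
    return RBFNetwork(
        centers=Xs, weights=sol[:-1], bias=float(sol[-1]),
        spread=float(spread), sigma=sigma, sigma_mode=sigma_mode,
        scaler_mean=mean, scaler_scale=scale, classes=classes,
    )


def decision_scores(net: RBFNetwork, features: np.ndarray) -> np.ndarray:
    """Raw network outputs F(x) for a samples x features matrix."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != net.n_features:
        raise ContractError(
            f"feature dimension {X.shape[1]} does not match network "
            f"dimension {net.n_features}")
    Xs = (X - net.scaler_mean) / net.scaler_scale
    return _design_matrix(Xs, net.centers, net.sigma) @ net.weights + net.bias


def predict(net: RBFNetwork, features: np.ndarray,
            return_scores: bool = False):
    """Class labels from sign(F(x)); score 0 goes to the positive class."""
    scores = decision_scores(net, features)
    labels = np.where(scores >= 0, net.classes[0], net.classes[1])
    if return_scores:
        return labels, scores
    return labels
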