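"""Common Spatial Patterns by whitening + joint diagonalization.

CSP finds spatial filters w maximizing the variance ratio between the two
classes: with per-class mean normalized covariances C0, C1 and composite
Cc = C0 + C1, whiten Cc (P Cc P' = I), eigendecompose the whitened
first-class covariance S0 = P C0 P' = B diag(lambda0) B', and take
W = B' P. Because S0 + S1 = I, the same B diagonalizes both classes with
complementary eigenvalues lambda0 + lambda1 = 1: the top rows of W are
maximally first-class-variant, the bottom rows maximally second-class-
variant. Features are the log of each retained component's variance
normalized by the summed variance of the retained components.

The fitted model keeps the full diagnostic chain (class covariances,
whitener, whitened matrices, shared eigenvectors and eigenvalues) so the
construction's identities can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .epochs import EpochSet
from .errors import ContractError, DegenerateTrialError, InvalidLabelsError, InvalidParameterError

__all__ = ["CSPModel", "normalized_covariance", "fit_csp", "logvar_features",
           "transform_features"]

#: ridge applied when the composite covariance is numerically rank-deficient
_RIDGE_EPS = 1e-8
_COND_LIMIT = 1e10


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized second-moment matrix C = X X' / trace(X X').

    The mean is not removed: band-passed EEG is zero-mean by construction,
    and the trace normalization equalizes trial-to-trial broadband power.
    """
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ContractError(f"trial must be channels x samples, got ndim={X.ndim}")
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise DegenerateTrialError("all-zero trial: covariance trace is zero")
    return C / tr


@dataclass
class CSPModel:
    """Fitted CSP projection for one grid cell.

    ``W`` has one spatial filter per row, ordered by descending eigenvalue
    of the whitened first-class covariance; ``selected_rows`` are the first
    and last ``m`` rows (duplicated when 2m exceeds the channel count).
    """

    W: np.ndarray
    m: int
    selected_rows: np.ndarray
    classes: np.ndarray
    class_covs: dict = field(repr=False)
    composite_cov: np.ndarray = field(repr=False)
    whitener: np.ndarray = field(repr=False)
    whitening_eigvals: np.ndarray = field(repr=False)
    whitening_eigvecs: np.ndarray = field(repr=False)
    S: dict = field(repr=False)
    B: np.ndarray = field(repr=False)
    eigvals: dict = field(repr=False)

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]

    @property
    def n_features(self) -> int:
        return len(self.selected_rows)


def fit_csp(cell_epochs: EpochSet, m: int) -> CSPModel:
    """Fit CSP on one cell's segments; retain ``m`` components per tail.

    Requires both classes with at least two trials each and
    ``1 <= m <= n_channels``. A numerically rank-deficient composite
    covariance is ridge-regularized with a warning.
    """
    classes = cell_epochs.classes
    if len(classes) != 2:
        raise InvalidLabelsError(f"need exactly 2 classes, got {list(classes)}")
    n_ch = cell_epochs.n_channels
    if not 1 <= m <= n_ch:
        raise InvalidParameterError(f"m must be in [1, {n_ch}], got {m}")

    class_covs = {}
    for cls in classes:
        trials = cell_epochs.data[cell_epochs.labels == cls]
        if len(trials) < 2:
            raise InvalidLabelsError(f"class {cls!r} has fewer than 2 trials")
        class_covs[cls] = np.mean([normalized_covariance(t) for t in trials], axis=0)

    Cc = class_covs[classes[0]] + class_covs[classes[1]]
    Cc = 0.5 * (Cc + Cc.T)
    if np.linalg.cond(Cc) > _COND_LIMIT:
        warnings.warn("composite covariance is rank-deficient; applying ridge",
                      RuntimeWarning, stacklevel=2)
        Cc = Cc + _RIDGE_EPS * np.trace(Cc) / n_ch * np.eye(n_ch)

    # whiten: P Cc P' = I
    lam_c, U = scipy.linalg.eigh(Cc)
    lam_c = np.clip(lam_c, _RIDGE_EPS * lam_c.max(), None)
    P = (lam_c ** -0.5)[:, None] * U.T

    S = {cls: P @ cov @ P.T for cls, cov in class_covs.items()}
    S0 = 0.5 * (S[classes[0]] + S[classes[0]].T)
    lam0, B = scipy.linalg.eigh(S0)
    # descending first-class eigenvalue; stable sort keeps ascending original
    # index on ties for determinism
    order = np.argsort(-lam0, kind="stable")
    B = B[:, order]
    lam0 = lam0[order]

    W = B.T @ P
    # sign convention: largest-magnitude entry of each filter positive
    signs = np.sign(W[np.arange(n_ch), np.argmax(np.abs(W), axis=1)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    B = B * signs[None, :]

    selected = np.concatenate([np.arange(m), np.arange(n_ch - m, n_ch)])
    eigvals = {classes[0]: lam0, classes[1]: 1.0 - lam0}
    return CSPModel(
        W=W, m=m, selected_rows=selected, classes=classes,
        class_covs=class_covs, composite_cov=Cc, whitener=P,
        whitening_eigvals=lam_c, whitening_eigvecs=U,
        S=S, B=B, eigvals=eigvals,
    )


def logvar_features(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Normalized log-variance features of one trial's selected components.

    f_p = log(var(Z_p) / sum_q var(Z_q)) over the 2m selected rows, with
    variance = mean square over samples (band-passed signals are zero-mean).
    All features are <= 0 and their exponentials sum to 1.
    """
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2 or X.shape[0] != model.n_channels:
        raise ContractError(
            f"trial must be {model.n_channels} x samples, got shape {X.shape}"
        )
    Z = model.W[model.selected_rows] @ X
    v = np.mean(Z * Z, axis=1)
    if np.any(v <= 0):
        raise DegenerateTrialError("zero-variance projected component")
    return np.log(v / v.sum())


def transform_features(model: CSPModel, epochs: EpochSet) -> np.ndarray:
    """Feature matrix (trials x 2m) for every trial of one cell's segments."""
    Z = np.einsum("fc,tcs->tfs", model.W[model.selected_rows], epochs.data)
    v = np.mean(Z * Z, axis=2)
    if np.any(v <= 0):
        raise DegenerateTrialError("zero-variance projected component")
    return np.log(v / v.sum(axis=1, keepdims=True))
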