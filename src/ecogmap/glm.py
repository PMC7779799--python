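"""Binomial GLM (logit link) combining band-power features to predict ESM
eloquence, with repeated stratified k-fold cross-validation.

The combiner is a plain maximum-likelihood logistic regression fitted by
iteratively reweighted least squares: the dependent variable is the ESM
category (eloquent / non-eloquent) and the predictors are the normalized
power changes of the chosen frequency bands, so each coefficient is the
log-odds of eloquence per unit power change.  Under complete or
quasi-separation (or non-convergence) the fit falls back to a small ridge
penalty on the slopes and flags it.  Cross-validation is stratified 10-fold,
repeated 20 times with random partitions; each electrode's out-of-fold
probabilities are averaged across repeats before a single AUROC is scored
(per-repeat AUROC averaging is available via ``PipelineConfig``).

Features are z-scored with training-fold statistics before fitting; in the
unpenalized case predictions are invariant to this affine rescaling, and it
stabilizes the ridge fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import child_seed
from .roc import auroc_value

logger = logging.getLogger("ecogmap")

_MAX_ITER = 100
_TOL = 1e-10
_RIDGE_FALLBACK = 1e-4
_SEPARATION_COEF = 30.0  # |slope| on z-scored features signalling separation


class FitError(ValueError):
    """Logistic fit impossible (single class, too few rows, bad shapes)."""


@dataclass
class CombinerModel:
    """Fitted band combiner.

    ``coef`` is ``[intercept, slope_per_band...]`` on the *standardized*
    feature scale; ``feature_means``/``feature_sds`` map raw features onto
    it, so :meth:`predict` consumes raw normalized power changes.
    """

    bands: tuple[str, ...]
    coef: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    converged: bool
    ridge_used: bool

    def linear_predictor(self, X) -> np.ndarray:
        X = _as_matrix(X, self.bands)
        Z = (X - self.feature_means) / self.feature_sds
        return self.coef[0] + Z @ self.coef[1:]

    def predict(self, X) -> np.ndarray:
        """Predicted probability of eloquence, in (0, 1)."""
        return _sigmoid(self.linear_predictor(X))

    @property
    def raw_coef(self) -> np.ndarray:
        """Coefficients on the raw feature scale (log-odds per unit
        normalized power change)."""
        slopes = self.coef[1:] / self.feature_sds
        intercept = self.coef[0] - float(slopes @ self.feature_means)
        return np.concatenate([[intercept], slopes])


def _sigmoid(eta):
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _as_matrix(X, bands=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X[list(bands)] if bands is not None else X
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def _irls(Z: np.ndarray, y: np.ndarray, ridge: float):
    """Newton/IRLS for logistic log-likelihood with an optional ridge penalty
    on the slopes.  Returns (coef, converged)."""
    n, p = Z.shape
    A = np.column_stack([np.ones(n), Z])
    pen = np.zeros(p + 1)
    pen[1:] = ridge
    prev = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta = np.zeros(p + 1)
    beta[0] = np.log(prev / (1 - prev))

    def negll(b):
        eta = A @ b
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta)
                     + 0.5 * np.sum(pen * b * b))

    obj = negll(beta)
    for _ in range(_MAX_ITER):
        eta = A @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = A.T @ (y - mu) - pen * beta
        hess = (A.T * w) @ A + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            cand_obj = negll(cand)
            if cand_obj <= obj + 1e-14:
                break
            t *= 0.5
        else:
            return beta, False
        delta = np.max(np.abs(t * step))
        beta, obj = cand, cand_obj
        if delta < _TOL:
            return beta, True
    return beta, False


def fit_glm(features, labels, bands: tuple[str, ...] | None = None,
            min_rows: int = 10) -> CombinerModel:
    """Maximum-likelihood logistic fit of a band set.

    ``features`` is an electrode-by-band matrix (or a DataFrame restricted by
    ``bands``); ``labels`` the boolean ESM category.  Deterministic given the
    data; falls back to a small ridge penalty (1e-4 on the slopes) under
    separation or non-convergence, flagging ``ridge_used``.
    """
    X = _as_matrix(features, bands)
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise FitError("features and labels disagree on the number of rows")
    if X.shape[0] < min_rows:
        raise FitError(f"need at least {min_rows} electrodes, got {X.shape[0]}")
    if y.min() == y.max():
        raise FitError("labels contain a single class")
    if bands is None:
        bands = (tuple(features.columns) if isinstance(features, pd.DataFrame)
                 else tuple(f"x{i}" for i in range(X.shape[1])))
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds
    coef, converged = _irls(Z, y, ridge=0.0)
    ridge_used = False
    if not converged or np.max(np.abs(coef[1:]), initial=0.0) > _SEPARATION_COEF:
        coef, converged = _irls(Z, y, ridge=_RIDGE_FALLBACK)
        ridge_used = True
    return CombinerModel(bands=tuple(bands), coef=coef, feature_means=means,
                         feature_sds=sds, converged=converged,
                         ridge_used=ridge_used)


def stratified_folds(labels: np.ndarray, k: int, rng) -> np.ndarray:
    """Random stratified partition: fold id per row, class proportions
    preserved per fold."""
    y = np.asarray(labels, dtype=bool)
    folds = np.empty(len(y), dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def crossval_predict(features, labels, bands: tuple[str, ...] | None = None,
                     k: int = 10, repeats: int = 20, seed: int = 0,
                     return_per_repeat: bool = False):
    """Out-of-fold predicted probabilities from repeated stratified k-fold CV.

    Every electrode's prediction comes from a model whose training folds did
    not contain it; probabilities are averaged across repeats.  Deterministic
    given ``seed``.
    """
    X = _as_matrix(features, bands)
    y = np.asarray(labels, dtype=bool).ravel()
    n = len(y)
    if k > n:
        raise FitError(f"k = {k} exceeds the number of electrodes ({n})")
    n_min = min(int(y.sum()), int((~y).sum()))
    if n_min == 0:
        raise FitError("labels contain a single class")
    if k > n_min:
        raise FitError(
            f"k = {k} exceeds the minority class count ({n_min}); "
            f"stratified folds would be empty")
    # Pooled out-of-fold AUROC is pessimistically biased for weak models:
    # a fold holding an extra positive was trained at a lower prevalence, so
    # its members get systematically lower predictions.  Re-anchoring every
    # fold model's intercept to the overall prevalence (one constant per CV
    # run) removes that fold-composition artifact without touching ranks
    # within a fold or the slopes.
    ref_logit = float(np.log(y.mean() / (1.0 - y.mean())))
    acc = np.zeros((repeats, n))
    for r in range(repeats):
        rng = np.random.default_rng(child_seed(seed, "cv", r))
        folds = stratified_folds(y, k, rng)
        for f in range(k):
            test = folds == f
            train = ~test
            model = fit_glm(X[train], y[train], bands=bands, min_rows=2)
            p_train = y[train].mean()
            model.coef[0] += ref_logit - float(
                np.log(p_train / (1.0 - p_train)))
            acc[r, test] = model.predict(X[test])
    if return_per_repeat:
        return acc
    return acc.mean(axis=0)


def model_auroc(probabilities, labels) -> float:
    """AUROC of out-of-fold probabilities against the ESM ground truth."""
    return auroc_value(probabilities, labels)


def crossval_auroc(features, labels, bands=None, k: int = 10,
                   repeats: int = 20, seed: int = 0,
                   repeat_averaging: str = "probabilities") -> float:
    """Cross-validated AUROC of one band set.

    ``repeat_averaging="probabilities"`` scores one AUROC on the
    repeat-averaged probabilities; ``"auroc"`` averages per-repeat AUROCs.
    """
    if repeat_averaging == "probabilities":
        prob = crossval_predict(features, labels, bands, k, repeats, seed)
        return model_auroc(prob, labels)
    if repeat_averaging == "auroc":
        per = crossval_predict(features, labels, bands, k, repeats, seed,
                               return_per_repeat=True)
        y = np.asarray(labels, dtype=bool).ravel()
        return float(np.mean([auroc_value(p, y) for p in per]))
    raise FitError(f"unknown repeat_averaging {repeat_averaging!r}")
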