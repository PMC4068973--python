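"""Maximum-likelihood logistic regression scored by its log likelihood (LLV).

The model is the standard logit: the probability that sample *i* is a tumor
sample is

    p_i = exp(b0 + b1 x_i1 + ... + bn x_in) / (1 + exp(...))

and a fitted model is scored by its natural log likelihood value

    LLV = sum_i [ y_i ln p_i + (1 - y_i) ln(1 - p_i) ]  <=  0,

larger (closer to zero) being better. The fit is Newton–Raphson on
internally standardised predictors (coefficients are reported on the
original scale), with step-halving so the likelihood never decreases.

Small panels on small samples separate perfectly rather often; uncapped MLE
then diverges. Any standardised coefficient exceeding ``BETA_CAP`` (30, i.e.
odds ratios beyond e^30 per SD) is clamped, the fit is flagged
``separated``, and the LLV is evaluated at the clamped coefficients — close
to zero, so searches still prefer separating panels, without overflow.
Probabilities are clipped to ``[1e-12, 1 - 1e-12]`` when evaluating the LLV
so it is always finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LogitFit", "fit_lm", "llv", "predict_prob", "BETA_CAP"]

#: cap on |coefficient| for standardised predictors; hit => separation flag
BETA_CAP = 30.0

#: probability clip bounds for LLV evaluation
PROB_CLIP = 1e-12

_SCORE_TOL = 1e-8
_MAX_ITER = 100


@dataclass
class LogitFit:
    """A fitted logit model.

    ``beta0``/``betas`` are on the original predictor scale; ``beta0_std``/
    ``betas_std`` on the internally standardised scale (used by the search's
    small-coefficient replacement heuristic, where scale-free magnitudes are
    comparable across predictors).
    """

    beta0: float
    betas: np.ndarray
    llv: float
    converged: bool
    separated: bool = False
    rank_deficient: bool = False
    n_iter: int = 0
    beta0_std: float = 0.0
    betas_std: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_predictors(self) -> int:
        return len(self.betas)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(_sigmoid(eta), PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fit_lm(X: np.ndarray, y: np.ndarray) -> LogitFit:
    """Fit a logit model by maximum likelihood (Newton–Raphson).

    ``X`` is samples-by-predictors (zero predictors fits the intercept-only
    model); ``y`` is the binary tumor/normal vector. Both classes must be
    present. A rank-deficient design (e.g. duplicated predictor columns from
    panel resolution) is handled with a pseudo-inverse Newton step and
    flagged rather than rejected.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n_samples, n_pred = X.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if y.shape != (n_samples,):
        raise ValueError("y length does not match X rows")
    if not np.isfinite(X).all():
        raise ValueError("predictors must be finite")
    classes = np.unique(y)
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("y must be binary (0/1)")
    if len(classes) < 2:
        raise ValueError("both classes must be present in y")

    # standardise predictors; constant columns stay at zero and are flagged
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = np.hstack([np.ones((n_samples, 1)), (X - mu) / sd_safe])

    beta = np.zeros(n_pred + 1)
    ll = _bernoulli_loglik(Z @ beta, y)
    converged = False
    separated = False
    rank_deficient = bool(degenerate.any())
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = Z @ beta
        p = _sigmoid(eta)
        score = Z.T @ (y - p)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-10, None)
        H = Z.T @ (Z * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(H) @ score
            rank_deficient = True
        if not np.isfinite(step).all():
            step = np.linalg.pinv(H) @ score
            rank_deficient = True
        # step-halving: the log likelihood must never decrease
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _bernoulli_loglik(Z @ candidate, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = _bernoulli_loglik(Z @ beta, y)
        if np.max(np.abs(beta)) > BETA_CAP:
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            ll = _bernoulli_loglik(Z @ beta, y)
            separated = True
            break

    # separation can also end with a converged score at saturated
    # probabilities before any coefficient reaches the cap: every sample
    # fitted essentially perfectly means the true MLE is at infinity
    if not separated and n_pred > 0:
        p_hat = _sigmoid(Z @ beta)
        if np.all(np.abs(p_hat - y) < 1e-6):
            separated = True

    beta = np.where(np.concatenate([[False], degenerate]), 0.0, beta)
    betas_std = beta[1:].copy()
    beta0_std = float(beta[0])
    betas_orig = betas_std / sd_safe
    beta0_orig = beta0_std - float(np.sum(betas_std * mu / sd_safe))
    return LogitFit(
        beta0=beta0_orig,
        betas=betas_orig,
        llv=ll,
        converged=converged,
        separated=separated,
        rank_deficient=rank_deficient,
        n_iter=it,
        beta0_std=beta0_std,
        betas_std=betas_std,
    )


def predict_prob(fit: LogitFit, X: np.ndarray) -> np.ndarray:
    """Tumor probability for each row of ``X`` under the fitted model."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return _sigmoid(fit.beta0 + X @ fit.betas)


def llv(fit: LogitFit, X: np.ndarray, y: np.ndarray) -> float:
    """Natural log likelihood of ``fit`` on (``X``, ``y``), always finite, <= 0.

    Computed as a sum of log-Bernoulli terms (never via the probability
    product) with probabilities clipped away from 0 and 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    return _bernoulli_loglik(fit.beta0 + X @ fit.betas, y)
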