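"""Penalized conditional log-likelihood for 1:m matched data.

With exactly one case per stratum, conditioning on the number of cases
turns each stratum's contribution into a softmax over its members:

    P(case is row j* | one case in stratum i) =
        exp(eta_{i j*}) / sum_j exp(eta_{ij}),

which algebraically eliminates the stratum intercepts alpha_i — adding a
constant to every linear predictor within a stratum leaves all
conditional probabilities unchanged.  This module provides the
per-stratum probabilities, the log-likelihood with analytic gradient and
Hessian, and a ridge-penalized Newton maximizer used by the CLR, tree
and forest fitters alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matched_data import MatchedDataset

__all__ = [
    "PenaltyConfig",
    "CLRFit",
    "stratum_cond_prob",
    "stratum_probs",
    "cond_loglik",
    "fit_clr",
    "fit_clr_model",
]

#: Default ridge weight; just large enough to keep the optimum finite
#: under perfect within-stratum separation.
DEFAULT_LAMBDA = 1e-20

#: Divergence guard on the log-odds scale.
COEF_CAP = 50.0


@dataclass(frozen=True)
class PenaltyConfig:
    """Ridge penalty (lambda/2)*||masked coefficients||^2.

    ``mask`` selects which coefficients are penalized (all by default).
    lambda = 0 reduces the objective to the plain conditional
    log-likelihood.
    """

    lam: float = DEFAULT_LAMBDA
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("ridge weight must be nonnegative")

    def mask_vector(self, d: int) -> np.ndarray:
        if self.mask is None:
            return np.ones(d)
        m = np.asarray(self.mask, dtype=float)
        if m.shape != (d,):
            raise ValueError("penalty mask length does not match design")
        return m


@dataclass
class CLRFit:
    """Result of a penalized conditional-logistic fit."""

    coef: np.ndarray
    loglik: float               # penalized objective at the solution
    cond_loglik: float          # unpenalized conditional log-likelihood
    converged: bool
    n_iter: int
    grad_norm: float
    beta_index: int | None = None
    gamma_hat: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def beta_hat(self) -> float | None:
        if self.beta_index is None:
            return None
        return float(self.coef[self.beta_index])


# ----------------------------------------------------------------------
# Likelihood primitives
# ----------------------------------------------------------------------

def stratum_cond_prob(eta: np.ndarray, case_index: int) -> float:
    """Conditional probability that ``case_index`` is the stratum's case.

    Computed as a max-shifted softmax for overflow safety.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.size < 2:
        raise ValueError("a stratum needs at least 2 members")
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    e = np.exp(eta - eta.max())
    return float(e[case_index] / e.sum())


def stratum_probs(data: MatchedDataset, eta: np.ndarray) -> np.ndarray:
    """Per-stratum conditional probability of the observed case.

    Vectorized over strata via grouped reductions.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    starts = data.stratum_starts
    shifted = eta - np.repeat(np.maximum.reduceat(eta, starts), data.m)
    e = np.exp(shifted)
    denom = np.add.reduceat(e, starts)
    return e[data.case_rows] / denom


def cond_loglik(data: MatchedDataset, eta: np.ndarray) -> float:
    """Conditional log-likelihood: sum of log per-stratum case probabilities.

    -inf when some stratum assigns its case probability zero (possible
    only for extreme trial iterates during optimization).
    """
    with np.errstate(divide="ignore"):
        return float(np.log(stratum_probs(data, eta)).sum())


def _softmax_rows(data: MatchedDataset, eta: np.ndarray) -> np.ndarray:
    """Within-stratum softmax over all rows (membership probabilities)."""
    starts = data.stratum_starts
    shifted = eta - np.repeat(np.maximum.reduceat(eta, starts), data.m)
    e = np.exp(shifted)
    return e / np.repeat(np.add.reduceat(e, starts), data.m)


# ----------------------------------------------------------------------
# Penalized Newton fit
# ----------------------------------------------------------------------

def fit_clr(
    data: MatchedDataset,
    design: np.ndarray,
    penalty: PenaltyConfig | None = None,
    offset: np.ndarray | None = None,
    init: np.ndarray | None = None,
    max_iter: int = 100,
    tol_obj: float = 1e-10,
    tol_grad: float = 1e-8,
) -> CLRFit:
    """Maximize the ridge-penalized conditional log-likelihood.

    Full Newton iterations with analytic gradient and Hessian and
    step-halving; the ridge is added to the Hessian diagonal.  The design
    may be an arbitrary column matrix (exposure plus linear covariates for
    CLR, or terminal-node indicators for a tree).  Coefficients of columns
    that are constant within every stratum carry no conditional-likelihood
    information and are shrunk to ~0 by the ridge.

    Returns the last iterate flagged unconverged if ``max_iter`` is
    exhausted; raises on a singular Hessian when ``lam == 0``.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != data.n_rows:
        X = X.reshape(data.n_rows, -1)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in design matrix")
    n_rows, d = X.shape
    penalty = penalty or PenaltyConfig()
    lam_vec = penalty.lam * penalty.mask_vector(d)
    off = np.zeros(n_rows) if offset is None else np.asarray(offset, dtype=float)

    theta = np.zeros(d) if init is None else np.asarray(init, dtype=float).copy()
    starts = data.stratum_starts

    def objective(th):
        eta = X @ th + off
        return cond_loglik(data, eta) - 0.5 * np.dot(lam_vec * th, th)

    obj = objective(theta)
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ theta + off
        p = _softmax_rows(data, eta)
        grad = X.T @ (data.y - p) - lam_vec * theta
        grad_norm = float(np.abs(grad).max())
        if grad_norm < tol_grad:
            converged = True
            break
        Xp = X * p[:, None]
        S = np.add.reduceat(Xp, starts, axis=0)        # per-stratum E[X]
        H = Xp.T @ X - S.T @ S                          # Fisher information
        H[np.diag_indices_from(H)] += lam_vec
        # With a near-zero ridge the information matrix can be numerically
        # singular along flat directions (a stratum-constant column, or a
        # common shift of a full set of indicator columns).  The
        # minimum-norm least-squares step zeroes those directions instead
        # of polluting them with round-off.
        if penalty.lam < 1e-8:
            step = np.linalg.lstsq(H, grad, rcond=1e-9)[0]
        else:
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                if penalty.lam == 0:
                    raise np.linalg.LinAlgError(
                        "singular Hessian; refit with a positive ridge weight"
                    ) from None
                step = np.linalg.lstsq(H, grad, rcond=1e-9)[0]
        if not np.isfinite(step).all() or np.abs(step).max() > 100.0:
            step = np.linalg.lstsq(H, grad, rcond=1e-6)[0]
        # step-halving line search: objective must not decrease
        new_obj = -np.inf
        for _ in range(30):
            cand = theta + step
            new_obj = objective(cand)
            if new_obj >= obj - 1e-12:
                break
            step *= 0.5
        if new_obj < obj - 1e-12:
            converged = grad_norm < 1e-4
            break
        theta = theta + step
        if np.abs(theta).max() > COEF_CAP:
            theta = np.clip(theta, -COEF_CAP, COEF_CAP)
            obj = objective(theta)
            converged = False
            break
        rel = abs(new_obj - obj) / (abs(obj) + 1e-300)
        obj = new_obj
        if rel < tol_obj:
            eta = X @ theta + off
            p = _softmax_rows(data, eta)
            grad = X.T @ (data.y - p) - lam_vec * theta
            grad_norm = float(np.abs(grad).max())
            converged = True
            break

    final_cll = cond_loglik(data, X @ theta + off)
    return CLRFit(
        coef=theta,
        loglik=final_cll - 0.5 * float(np.dot(lam_vec * theta, theta)),
        cond_loglik=final_cll,
        converged=converged,
        n_iter=it,
        grad_norm=grad_norm,
    )


def clr_design(data: MatchedDataset, exposure: bool = True) -> tuple[np.ndarray, int | None]:
    """Design matrix [x | Z] for the linear CLR model (or [Z] without exposure)."""
    if exposure:
        if data.x is None:
            raise ValueError("dataset has no exposure column")
        return np.column_stack([data.x, data.Z]), 0
    return data.Z.copy(), None


def fit_clr_model(
    data: MatchedDataset,
    exposure: bool = True,
    covariates: bool = True,
    penalty: PenaltyConfig | None = None,
    **kwargs,
) -> CLRFit:
    """Fit the linear conditional logistic regression model.

    ``exposure=True, covariates=True`` fits the standard CLR with a
    dedicated exposure effect beta and linear covariate effects gamma;
    ``covariates=False`` gives the exposure-only model CLR0.
    """
    if exposure and covariates:
        X, bi = clr_design(data, exposure=True)
    elif exposure:
        if data.x is None:
            raise ValueError("dataset has no exposure column")
        X, bi = data.x.reshape(-1, 1), 0
    elif covariates:
        X, bi = data.Z.copy(), None
    else:
        raise ValueError("nothing to fit")
    fit = fit_clr(data, X, penalty=penalty, **kwargs)
    fit.beta_index = bi
    if covariates:
        fit.gamma_hat = fit.coef[1:] if exposure else fit.coef.copy()
    return fit
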