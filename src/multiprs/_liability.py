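"""Numeric mapping from liability-threshold effects to logistic-scale effects.

A liability-threshold model with latent L = alpha*(x - E[x]) + e, Var(L) = 1,
and case status 1{L > t} with t = Phi^-1(1 - prevalence) induces a case
probability curve P(case | x) = Phi((alpha*(x - E[x]) - t) / s), where
s = sqrt(1 - alpha^2 Var(x)) is the conditional residual sd.  The
logistic-regression slope that a marginal fit of status on x converges to is
the maximiser of the expected Bernoulli log-likelihood under that curve; it
has no closed form, so it is computed here by weighted Newton iteration over
a discretised distribution of x.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def expected_logistic_fit(
    x: np.ndarray, weights: np.ndarray, case_prob: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[float, float]:
    """Fit intercept and slope of a logistic curve to true case probabilities.

    Maximises sum_i w_i * [q_i log p_i + (1-q_i) log(1-p_i)] with
    p_i = expit(b0 + b1 x_i); this is the population target of a marginal
    logistic regression when x has the discretised distribution (x, weights).
    """
    x = np.asarray(x, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    q = np.asarray(case_prob, float)
    b0, b1 = 0.0, 0.0
    X = np.column_stack([np.ones_like(x), x])
    for _ in range(max_iter):
        eta = b0 + b1 * x
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (q - p))
        wvar = w * p * (1 - p)
        hess = X.T @ (X * wvar[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        b0 += step[0]
        b1 += step[1]
        if np.max(np.abs(step)) < tol:
            break
    return b0, b1


def liability_threshold(prevalence: float) -> float:
    """Threshold on a unit-variance liability giving the stated prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0,1), got {prevalence}")
    return float(norm.ppf(1.0 - prevalence))


def logistic_slope_from_liability(
    alpha: float,
    x_values: np.ndarray,
    x_weights: np.ndarray,
    prevalence: float,
    total_liability_var: float = 1.0,
) -> float:
    """Logistic-scale marginal slope implied by a liability slope ``alpha``.

    Parameters
    ----------
    alpha:
        Liability-scale regression slope of L on x (per unit of x).
    x_values, x_weights:
        Discretised distribution of the predictor (e.g. dosages 0/1/2 with
        Hardy-Weinberg weights, or a Gaussian quadrature grid for a PRS).
    prevalence:
        Population case fraction fixing the liability threshold.
    total_liability_var:
        Variance of the full liability; the conditional residual variance is
        total minus the variance explained by x.
    """
    x = np.asarray(x_values, float)
    w = np.asarray(x_weights, float)
    w = w / w.sum()
    mu = float(np.sum(w * x))
    var_x = float(np.sum(w * (x - mu) ** 2))
    s2 = total_liability_var - alpha**2 * var_x
    if s2 <= 0:
        raise ValueError("liability slope explains more variance than the total liability carries")
    t = liability_threshold(prevalence) * np.sqrt(total_liability_var)
    q = norm.sf((t - alpha * (x - mu)) / np.sqrt(s2))
    _, b1 = expected_logistic_fit(x, w, q)
    return float(b1)


def gaussian_grid(n_points: int = 201, span: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced grid with standard-normal weights, for continuous predictors."""
    x = np.linspace(-span, span, n_points)
    w = norm.pdf(x)
    return x, w / w.sum()
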