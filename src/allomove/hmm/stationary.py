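"""Stationary state probabilities and their covariate-response curves.

The stationary distribution solves delta Gamma = delta with probabilities
summing to one.  Plotted against the composite stress index it shows how
the long-run behavioural budget shifts with stress load; 95% confidence
bands come from the delta method, propagating the working-parameter
covariance through a numerical Jacobian of delta(c).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from allomove.hmm.params import HMMParameters

__all__ = ["stationary_distribution", "stationary_curves"]

log = logging.getLogger(__name__)


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Solve delta = delta Gamma, sum(delta) = 1 as a linear system.

    Raises for reducible or periodic chains (no unique stationary law).
    """
    tpm = np.asarray(tpm, dtype=float)
    N = tpm.shape[0]
    if tpm.shape != (N, N) or not np.allclose(tpm.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix must be square and row-stochastic")
    eigvals = np.linalg.eigvals(tpm)
    if np.sum(np.abs(eigvals - 1.0) < 1e-10) > 1 or np.any(
        (np.abs(np.abs(eigvals) - 1.0) < 1e-10) & (np.abs(eigvals - 1.0) > 1e-10)
    ):
        raise ValueError("chain is reducible or periodic; stationary law not unique")
    A = np.vstack([tpm.T - np.eye(N), np.ones(N)])
    b = np.zeros(N + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


def _delta_of_theta(structure, theta: np.ndarray, c: float) -> np.ndarray:
    return stationary_distribution(
        HMMParameters.unpack(structure, theta).transition_matrix(c)
    )


def stationary_curves(
    fit,
    c_grid: np.ndarray,
    level: float = 0.95,
    state_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """delta(c) per state over a covariate grid, with delta-method CIs.

    Returns a tidy frame with columns ``c``, ``state`` (model index,
    1-based), ``label``, ``delta``, ``lo``, ``hi``.  Without a fit
    covariance the CI columns are NaN (with a warning).
    """
    from allomove.hmm.decode import state_names

    params = fit.mle
    structure = params.structure
    theta = params.pack()
    labels = state_labels or state_names(params)
    z = norm.ppf(0.5 + level / 2.0)
    have_cov = fit.covariance is not None
    if not have_cov:
        log.warning("no covariance available; stationary curves without CIs")
    rows = []
    for c in np.asarray(c_grid, dtype=float):
        delta = _delta_of_theta(structure, theta, c)
        if have_cov:
            J = np.empty((delta.size, theta.size))
            for i in range(theta.size):
                h = 1e-6 * (1.0 + abs(theta[i]))
                up, dn = theta.copy(), theta.copy()
                up[i] += h
                dn[i] -= h
                J[:, i] = (
                    _delta_of_theta(structure, up, c) - _delta_of_theta(structure, dn, c)
                ) / (2.0 * h)
            var = np.einsum("ij,jk,ik->i", J, fit.covariance, J)
            se = np.sqrt(np.clip(var, 0.0, None))
        else:
            se = np.full(delta.size, np.nan)
        for k in range(delta.size):
            rows.append(
                {
                    "c": c,
                    "state": k + 1,
                    "label": labels[k],
                    "delta": delta[k],
                    "lo": np.clip(delta[k] - z * se[k], 0.0, 1.0),
                    "hi": np.clip(delta[k] + z * se[k], 0.0, 1.0),
                }
            )
    return pd.DataFrame(rows)
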