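"""Forward-algorithm log-likelihood with partial missingness.

The likelihood over all individuals is the product of per-series forward
recursions; each series uses its own covariate value, so its transition
matrix is constant in time.  A missing stream at time t simply contributes
a factor of one to that time's joint emission density, and a row with all
streams missing contributes only the transition structure — the mechanism
by which dive gaps and track gaps are absorbed without imputation.

Emission log-densities are computed vectorized in numpy per evaluation;
the sequential scan itself runs in a numba kernel (the optimizer calls the
likelihood tens of thousands of times during a fit).
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit
from scipy.special import gammaln, i0e

from allomove.hmm.params import GAMMA, HMMParameters
from allomove.hmm.series import ObservationSeries

__all__ = ["log_likelihood", "PackedData", "pack_data", "log_density_cube"]

log = logging.getLogger(__name__)


class PackedData:
    """Dense padded arrays for a batch of observation series.

    Per gamma stream: values (S, Tmax) with zeros jittered to half the
    minimum positive value (gamma support excludes 0), precomputed logs,
    and observation masks.  The turn stream keeps cos/sin precomputed.
    """

    def __init__(self, series: list[ObservationSeries]):
        if not series:
            raise ValueError("no observation series supplied")
        self.ids = [s.id for s in series]
        self.csi = np.array([s.csi for s in series], dtype=float)
        self.lengths = np.array([len(s) for s in series], dtype=np.int64)
        S, Tmax = len(series), int(self.lengths.max())
        self.n_series, self.t_max = S, Tmax
        self.values: dict[str, np.ndarray] = {}
        self.obs: dict[str, np.ndarray] = {}
        self.logx: dict[str, np.ndarray] = {}
        for name in ("step", "max_depth", "wiggles", "dist_shore"):
            x = np.full((S, Tmax), np.nan)
            for i, s in enumerate(series):
                x[i, : len(s)] = getattr(s, name)
            pos = x[np.isfinite(x) & (x > 0)]
            nz = np.isfinite(x) & (x == 0)
            if nz.any():
                jitter = 0.5 * (pos.min() if pos.size else 1.0)
                log.info("stream %s: %d zero values jittered to %g", name, nz.sum(), jitter)
                x[nz] = jitter
            self.obs[name] = np.isfinite(x)
            filled = np.where(self.obs[name], x, 1.0)
            self.values[name] = filled
            self.logx[name] = np.log(filled)
        turn = np.full((S, Tmax), np.nan)
        for i, s in enumerate(series):
            turn[i, : len(s)] = s.turn
        self.obs["turn"] = np.isfinite(turn)
        filled = np.where(self.obs["turn"], turn, 0.0)
        self.cos_turn = np.cos(filled)
        self.sin_turn = np.sin(filled)
        self.n_observations = int(sum(m.sum() for m in self.obs.values()))


def pack_data(series: list[ObservationSeries]) -> PackedData:
    return PackedData(series)


def log_density_cube(params: HMMParameters, data: PackedData) -> np.ndarray:
    """Joint emission log-density, shape (n_series, t_max, n_states).

    Missing streams contribute 0 (density factor 1); padded tail entries
    are irrelevant (the forward kernel stops at each series' length).
    """
    N = params.structure.n_states
    total = np.zeros((data.n_series, data.t_max, N))
    c = data.csi
    for e in params.structure.emissions:
        if e.family == GAMMA:
            name = e.stream
            eta = params.alpha0[name][None, :] + params.alpha1[name][None, :] * c[:, None]
            mean = np.exp(eta)  # (S, N)
            sd = np.exp(params.log_sd[name])[None, :]
            shape = mean**2 / sd**2
            scale = sd**2 / mean
            # logpdf = (a-1) ln x - x/scale - lgamma(a) - a ln scale
            const = -gammaln(shape) - shape * np.log(scale)  # (S, N)
            dens = (
                (shape[:, None, :] - 1.0) * data.logx[name][:, :, None]
                - data.values[name][:, :, None] / scale[:, None, :]
                + const[:, None, :]
            )
            total += np.where(data.obs[name][:, :, None], dens, 0.0)
        else:
            kappa = np.exp(params.turn_log_kappa)  # (N,)
            mu = params.turn_mean
            # log I0(k) = log i0e(k) + k avoids overflow for large kappa
            const = -np.log(2.0 * np.pi * i0e(kappa)) - kappa
            cosd = (
                data.cos_turn[:, :, None] * np.cos(mu)[None, None, :]
                + data.sin_turn[:, :, None] * np.sin(mu)[None, None, :]
            )
            dens = kappa[None, None, :] * cosd + const[None, None, :]
            total += np.where(data.obs["turn"][:, :, None], dens, 0.0)
    return total


@njit(cache=True)
def _forward_nll(logdens, tpm, delta, lengths):  # pragma: no cover - numba
    S, _, N = logdens.shape
    total = 0.0
    alpha = np.empty(N)
    anew = np.empty(N)
    for s in range(S):
        T = lengths[s]
        m = logdens[s, 0, 0]
        for j in range(1, N):
            if logdens[s, 0, j] > m:
                m = logdens[s, 0, j]
        csum = 0.0
        for j in range(N):
            alpha[j] = delta[s, j] * np.exp(logdens[s, 0, j] - m)
            csum += alpha[j]
        if csum <= 0.0 or not np.isfinite(csum):
            return -np.inf
        total += np.log(csum) + m
        for j in range(N):
            alpha[j] /= csum
        for t in range(1, T):
            m = logdens[s, t, 0]
            for j in range(1, N):
                if logdens[s, t, j] > m:
                    m = logdens[s, t, j]
            csum = 0.0
            for j in range(N):
                acc = 0.0
                for i in range(N):
                    acc += alpha[i] * tpm[s, i, j]
                anew[j] = acc * np.exp(logdens[s, t, j] - m)
                csum += anew[j]
            if csum <= 0.0 or not np.isfinite(csum):
                return -np.inf
            total += np.log(csum) + m
            for j in range(N):
                alpha[j] = anew[j] / csum
    return total


def _loglik_packed(params: HMMParameters, data: PackedData) -> float:
    N = params.structure.n_states
    theta_ok = all(
        np.all(np.isfinite(v))
        for v in (
            *params.alpha0.values(),
            *params.alpha1.values(),
            *params.log_sd.values(),
            params.beta0,
            params.beta1,
        )
    )
    if not theta_ok:
        return -np.inf
    logdens = log_density_cube(params, data)
    if not np.all(np.isfinite(logdens)):
        return -np.inf
    tpm = np.empty((data.n_series, N, N))
    delta = np.empty((data.n_series, N))
    try:
        for i, c in enumerate(data.csi):
            tpm[i] = params.transition_matrix(c)
            delta[i] = params.initial_distribution(c)
    except Exception:
        return -np.inf
    return float(
        _forward_nll(
            np.ascontiguousarray(logdens), tpm, delta, data.lengths
        )
    )


def log_likelihood(params: HMMParameters, data) -> float:
    """Total forward log-likelihood over a list of observation series.

    Returns ``-inf`` (never raises) on invalid parameters, so the value is
    safe to hand directly to an optimizer.
    """
    if isinstance(data, ObservationSeries):
        data = [data]
    packed = data if isinstance(data, PackedData) else pack_data(list(data))
    return _loglik_packed(params, packed)
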