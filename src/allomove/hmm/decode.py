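"""Viterbi decoding and behavioural state naming.

States are labelled post hoc by ordering on the fitted mean maximum dive
depth: the shallowest state is the non-diving "transiting" behaviour, and
for the three-state model the remaining two are "foraging_shallow" and
"foraging_deep".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from allomove.hmm.likelihood import log_density_cube, pack_data
from allomove.hmm.params import HMMParameters
from allomove.hmm.series import ObservationSeries

__all__ = ["DecodedTrack", "viterbi", "state_order_by_depth", "state_names"]

_THREE_STATE_NAMES = ("transiting", "foraging_shallow", "foraging_deep")


@dataclass
class DecodedTrack:
    """Most-likely state sequence for one individual."""

    id: str
    states: np.ndarray  # 1-based state indices (model order)
    state_names: tuple[str, ...]  # name per model state, depth-ordered labels
    log_prob: float  # joint log-probability of the decoded path

    @property
    def named_states(self) -> list[str]:
        return [self.state_names[s - 1] for s in self.states]

    @property
    def activity_budget(self) -> dict[str, float]:
        """Fraction of decoded intervals spent in each (named) state."""
        total = len(self.states)
        return {
            name: float(np.sum(self.states == k + 1)) / total
            for k, name in enumerate(self.state_names)
        }


def state_order_by_depth(params: HMMParameters, c: float = 0.0) -> np.ndarray:
    """Model-state indices sorted shallowest-first on mean max depth."""
    N = params.structure.n_states
    if "max_depth" not in params.alpha0:
        return np.arange(N)
    depths = [params.emission_mean("max_depth", k, c) for k in range(N)]
    return np.argsort(depths, kind="stable")


def state_names(params: HMMParameters, c: float = 0.0) -> tuple[str, ...]:
    """Behaviour name for each model state (depth-ordered labels)."""
    N = params.structure.n_states
    order = state_order_by_depth(params, c)
    if N == 3:
        labels = _THREE_STATE_NAMES
    else:
        labels = tuple(f"state_{k + 1}" for k in range(N))
    names = [""] * N
    for rank, idx in enumerate(order):
        names[idx] = labels[rank]
    return tuple(names)


def viterbi(params: HMMParameters, series: ObservationSeries) -> DecodedTrack:
    """Most probable state path under Gamma(csi) and the emissions.

    Ties are broken toward the lowest state index (argmax keeps the first
    maximum).
    """
    packed = pack_data([series])
    logdens = log_density_cube(params, packed)[0, : len(series)]
    T, N = logdens.shape
    log_tpm = np.log(params.transition_matrix(series.csi))
    log_delta = np.log(params.initial_distribution(series.csi))
    score = np.empty((T, N))
    back = np.zeros((T, N), dtype=np.int64)
    score[0] = log_delta + logdens[0]
    for t in range(1, T):
        cand = score[t - 1][:, None] + log_tpm  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        score[t] = cand[back[t], np.arange(N)] + logdens[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(score[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return DecodedTrack(
        id=series.id,
        states=path + 1,
        state_names=state_names(params, series.csi),
        log_prob=float(score[-1].max()),
    )
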