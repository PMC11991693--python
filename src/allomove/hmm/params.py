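"""Model structure, working/natural parameter scales and link functions.

Working parameters (the unconstrained vector the optimizer sees) map to
natural parameters through:

* gamma streams: mean_i(c) = exp(alpha0_i + alpha1_i * c) (alpha1 present
  only when the stream carries the covariate), sd_i = exp(log_sd_i);
* turning angle (von Mises): mean angle unconstrained (wrapped), kappa =
  exp(log_kappa);
* transitions: multinomial logit with the diagonal as reference,
  Gamma_ij(c) = exp(beta0_ij + beta1_ij c) / (1 + sum_{k != i} exp(...)),
  Gamma_ii the remainder, so rows sum to one for every c;
* initial distribution: either an estimated shared simplex (N-1 logits
  against state 1) or the stationary distribution of Gamma(c).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmissionSpec",
    "ModelStructure",
    "HMMParameters",
    "DEFAULT_EMISSIONS",
    "transition_matrix",
]

GAMMA = "gamma"
VON_MISES = "von_mises"

STREAMS = ("step", "turn", "max_depth", "wiggles", "dist_shore")


@dataclass(frozen=True)
class EmissionSpec:
    """One data stream's emission family and covariate structure."""

    stream: str
    family: str
    covariate_on_mean: bool = False

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}")
        if self.family not in (GAMMA, VON_MISES):
            raise ValueError(f"unknown family {self.family!r}")
        if (self.stream == "turn") != (self.family == VON_MISES):
            raise ValueError("turn stream must (and only it may) use von Mises")
        if self.covariate_on_mean and self.family == VON_MISES:
            raise ValueError("covariate on the mean is only supported for gamma streams")


#: The published model structure: covariate on the means of step length,
#: maximum dive depth and distance to shore; wiggle mean and turning-angle
#: parameters covariate-free.
DEFAULT_EMISSIONS: tuple[EmissionSpec, ...] = (
    EmissionSpec("step", GAMMA, covariate_on_mean=True),
    EmissionSpec("turn", VON_MISES),
    EmissionSpec("max_depth", GAMMA, covariate_on_mean=True),
    EmissionSpec("wiggles", GAMMA),
    EmissionSpec("dist_shore", GAMMA, covariate_on_mean=True),
)


@dataclass(frozen=True)
class ModelStructure:
    """Number of states plus which parts of the model carry the covariate."""

    n_states: int
    emissions: tuple[EmissionSpec, ...] = DEFAULT_EMISSIONS
    transition_covariate: bool = True
    initial: str = "estimated"  # or "stationary"

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.initial not in ("estimated", "stationary"):
            raise ValueError("initial must be 'estimated' or 'stationary'")
        seen = [e.stream for e in self.emissions]
        if len(set(seen)) != len(seen):
            raise ValueError("duplicate stream in emissions")

    def without_covariate(self, on: str = "both") -> "ModelStructure":
        """Reduced structure with the covariate removed from parts of the model."""
        emissions = self.emissions
        transition = self.transition_covariate
        if on in ("emissions", "both"):
            emissions = tuple(
                EmissionSpec(e.stream, e.family, False) for e in emissions
            )
        if on in ("transitions", "both"):
            transition = False
        return ModelStructure(self.n_states, emissions, transition, self.initial)

    @property
    def n_params(self) -> int:
        N = self.n_states
        n = 0
        for e in self.emissions:
            if e.family == GAMMA:
                n += 2 * N + (N if e.covariate_on_mean else 0)
            else:
                n += 2 * N
        n += N * (N - 1) * (2 if self.transition_covariate else 1)
        if self.initial == "estimated":
            n += N - 1
        return n


def _softmax_rows(eta: np.ndarray) -> np.ndarray:
    """Row softmax of the logit matrix (diagonal already zeroed as reference)."""
    m = eta.max(axis=1, keepdims=True)
    ex = np.exp(eta - m)
    return ex / ex.sum(axis=1, keepdims=True)


@dataclass
class HMMParameters:
    """Full working-scale parameter set for one model structure.

    Arrays are keyed per stream; ``beta0``/``beta1`` are (N, N) with the
    diagonal unused (reference category of the multinomial logit).
    """

    structure: ModelStructure
    alpha0: dict[str, np.ndarray] = field(default_factory=dict)  # log-mean intercepts
    alpha1: dict[str, np.ndarray] = field(default_factory=dict)  # log-mean slopes
    log_sd: dict[str, np.ndarray] = field(default_factory=dict)
    turn_mean: np.ndarray | None = None
    turn_log_kappa: np.ndarray | None = None
    beta0: np.ndarray | None = None
    beta1: np.ndarray | None = None
    initial_logits: np.ndarray | None = None  # (N-1,) vs state 1

    # -- natural-scale accessors -------------------------------------------

    def emission_mean(self, stream: str, state: int, c: float = 0.0) -> float:
        """Gamma-stream mean for one state at covariate value ``c``."""
        spec = self._spec(stream)
        if spec.family != GAMMA:
            raise ValueError(f"{stream} is not a gamma stream")
        eta = self.alpha0[stream][state]
        if spec.covariate_on_mean:
            eta = eta + self.alpha1[stream][state] * c
        return float(np.exp(eta))

    def emission_sd(self, stream: str, state: int) -> float:
        return float(np.exp(self.log_sd[stream][state]))

    def gamma_shape_rate(self, stream: str, state: int, c: float = 0.0) -> tuple[float, float]:
        """(shape, rate) of the gamma emission, from its (mean, sd)."""
        mean = self.emission_mean(stream, state, c)
        sd = self.emission_sd(stream, state)
        shape = mean**2 / sd**2
        return shape, shape / mean

    def turn_kappa(self, state: int) -> float:
        return float(np.exp(self.turn_log_kappa[state]))

    def transition_matrix(self, c: float = 0.0) -> np.ndarray:
        return transition_matrix(self, c)

    def initial_distribution(self, c: float = 0.0) -> np.ndarray:
        """Initial state distribution (estimated simplex or stationary at c)."""
        if self.structure.initial == "stationary":
            from allomove.hmm.stationary import stationary_distribution

            return stationary_distribution(self.transition_matrix(c))
        N = self.structure.n_states
        logits = np.concatenate([[0.0], self.initial_logits])
        ex = np.exp(logits - logits.max())
        return ex / ex.sum()

    def _spec(self, stream: str) -> EmissionSpec:
        for e in self.structure.emissions:
            if e.stream == stream:
                return e
        raise KeyError(stream)

    # -- packing ------------------------------------------------------------

    def pack(self) -> np.ndarray:
        """Flatten to the working parameter vector (optimizer order)."""
        N = self.structure.n_states
        parts: list[np.ndarray] = []
        for e in self.structure.emissions:
            if e.family == GAMMA:
                parts.append(self.alpha0[e.stream])
                if e.covariate_on_mean:
                    parts.append(self.alpha1[e.stream])
                parts.append(self.log_sd[e.stream])
            else:
                parts.append(self.turn_mean)
                parts.append(self.turn_log_kappa)
        off = ~np.eye(N, dtype=bool)
        parts.append(self.beta0[off])
        if self.structure.transition_covariate:
            parts.append(self.beta1[off])
        if self.structure.initial == "estimated":
            parts.append(self.initial_logits)
        return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])

    @classmethod
    def unpack(cls, structure: ModelStructure, theta: np.ndarray) -> "HMMParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.size != structure.n_params:
            raise ValueError(
                f"expected {structure.n_params} working parameters, got {theta.size}"
            )
        N = structure.n_states
        p = cls(structure=structure)
        pos = 0

        def take(n: int) -> np.ndarray:
            nonlocal pos
            out = theta[pos : pos + n]
            pos += n
            return out.copy()

        for e in structure.emissions:
            if e.family == GAMMA:
                p.alpha0[e.stream] = take(N)
                if e.covariate_on_mean:
                    p.alpha1[e.stream] = take(N)
                else:
                    p.alpha1[e.stream] = np.zeros(N)
                p.log_sd[e.stream] = take(N)
            else:
                p.turn_mean = take(N)
                p.turn_log_kappa = take(N)
        p.beta0 = np.zeros((N, N))
        off = ~np.eye(N, dtype=bool)
        p.beta0[off] = take(N * (N - 1))
        p.beta1 = np.zeros((N, N))
        if structure.transition_covariate:
            p.beta1[off] = take(N * (N - 1))
        if structure.initial == "estimated":
            p.initial_logits = take(N - 1)
        else:
            p.initial_logits = np.zeros(N - 1)
        return p

    def permuted(self, order: np.ndarray | list[int]) -> "HMMParameters":
        """Relabel states so new state k is old state ``order[k]``.

        The likelihood is invariant to this relabelling.  The initial
        logits are re-expressed against the new reference state.
        """
        order = np.asarray(order, dtype=int)
        N = self.structure.n_states
        out = HMMParameters(structure=self.structure)
        for s, a in self.alpha0.items():
            out.alpha0[s] = a[order]
        for s, a in self.alpha1.items():
            out.alpha1[s] = a[order]
        for s, a in self.log_sd.items():
            out.log_sd[s] = a[order]
        if self.turn_mean is not None:
            out.turn_mean = self.turn_mean[order]
            out.turn_log_kappa = self.turn_log_kappa[order]
        out.beta0 = self.beta0[np.ix_(order, order)]
        out.beta1 = self.beta1[np.ix_(order, order)]
        logits = np.concatenate([[0.0], self.initial_logits])[order]
        out.initial_logits = logits[1:] - logits[0]
        return out

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_states": self.structure.n_states,
            "transition_covariate": self.structure.transition_covariate,
            "initial": self.structure.initial,
            "emissions": [
                {"stream": e.stream, "family": e.family, "covariate_on_mean": e.covariate_on_mean}
                for e in self.structure.emissions
            ],
            "alpha0": {k: v.tolist() for k, v in self.alpha0.items()},
            "alpha1": {k: v.tolist() for k, v in self.alpha1.items()},
            "log_sd": {k: v.tolist() for k, v in self.log_sd.items()},
            "beta0": self.beta0.tolist(),
            "beta1": self.beta1.tolist(),
            "initial_logits": self.initial_logits.tolist(),
        }
        if self.turn_mean is not None:
            d["turn_mean"] = self.turn_mean.tolist()
            d["turn_log_kappa"] = self.turn_log_kappa.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParameters":
        structure = ModelStructure(
            n_states=d["n_states"],
            emissions=tuple(EmissionSpec(**e) for e in d["emissions"]),
            transition_covariate=d["transition_covariate"],
            initial=d["initial"],
        )
        p = cls(structure=structure)
        p.alpha0 = {k: np.asarray(v, float) for k, v in d["alpha0"].items()}
        p.alpha1 = {k: np.asarray(v, float) for k, v in d["alpha1"].items()}
        p.log_sd = {k: np.asarray(v, float) for k, v in d["log_sd"].items()}
        p.beta0 = np.asarray(d["beta0"], float)
        p.beta1 = np.asarray(d["beta1"], float)
        p.initial_logits = np.asarray(d["initial_logits"], float)
        if "turn_mean" in d:
            p.turn_mean = np.asarray(d["turn_mean"], float)
            p.turn_log_kappa = np.asarray(d["turn_log_kappa"], float)
        return p

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HMMParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def transition_matrix(params: HMMParameters, c: float) -> np.ndarray:
    """Transition probability matrix Gamma(c) via the multinomial-logit link.

    Off-diagonal logits are beta0_ij + beta1_ij * c against the diagonal as
    reference; evaluated with max-shifting so large coefficients cannot
    overflow.  Rows sum to one exactly.
    """
    eta = params.beta0 + params.beta1 * c
    np.fill_diagonal(eta, 0.0)
    return _softmax_rows(eta)
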