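"""Discrete hidden Markov model coupling public opinion to policy intent.

The hidden state is the emergency-management agency's policy intent,
Q = (Continue, Change) with numeric codes (1, 0); the observations are the
public opinion states P = (Support, Neutral, Opposed) with numeric values
(1, 0.5, 0).  The model phi = (A, B, pi) comprises the initial state vector
pi, the state transition matrix A with a_ij = P(i_{t+1} = q_j | i_t = q_i),
and the emission matrix B with b_j(k) the probability of observing symbol k
from state j.

The case-study parameterization (:func:`default_spec`) starts with certain
policy continuation, pi = (1, 0); both intents persist with probability 0.7
(A rows (0.7, 0.3) / (0.3, 0.7)); a continuing (satisfied) regime emits
Support/Neutral/Opposed with probabilities (0.6, 0.3, 0.1) and a changing
(dissatisfied) regime with (0.1, 0.3, 0.6).  Its transition matrix is
symmetric, so the stationary distribution is (0.5, 0.5) and the long-run
mean observation value is 0.5 — a neutral 50% support rate.

Provided operations: trajectory sampling with small-ensemble averaging
(default 10 runs), scaled forward filtering of the policy-intent posterior
from an opinion sequence, and Baum-Welch (EM) parameter estimation with
random restarts and canonical state relabelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .concern import OpinionObservation

__all__ = [
    "HmmSpec",
    "Trajectory",
    "EnsembleSummary",
    "BaumWelchResult",
    "default_spec",
    "derive_seeds",
    "sample_trajectory",
    "simulate_ensemble",
    "forward_filter",
    "baum_welch",
    "fit_hmm",
    "canonical_relabel",
    "stationary_distribution",
    "expected_observation",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class HmmSpec:
    """A discrete HMM phi = (A, B, pi) with labelled, numerically coded states.

    Rows of A and B and the vector pi must each sum to 1 (within 1e-12) with
    non-negative entries.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    state_labels: tuple[str, ...] = ("Continue", "Change")
    state_codes: tuple[float, ...] = (1.0, 0.0)
    obs_labels: tuple[str, ...] = ("Support", "Neutral", "Opposed")
    obs_values: tuple[float, ...] = (1.0, 0.5, 0.0)

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        n, m = self.n_states, self.n_symbols
        if pi.shape != (n,) or A.shape != (n, n) or B.shape != (n, m):
            raise ValueError(
                f"inconsistent shapes: pi {pi.shape}, A {A.shape}, B {B.shape}"
            )
        for name, arr in (("pi", pi[None, :]), ("A", A), ("B", B)):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > _ROW_TOL):
                raise ValueError(f"rows of {name} must sum to 1")
        if len(self.state_codes) != n or len(self.obs_values) != m:
            raise ValueError("label/code lengths do not match matrix shapes")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_symbols(self) -> int:
        return len(self.obs_labels)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "pi": self.pi.tolist(),
                    "A": self.A.tolist(),
                    "B": self.B.tolist(),
                    "state_labels": list(self.state_labels),
                    "state_codes": list(self.state_codes),
                    "obs_labels": list(self.obs_labels),
                    "obs_values": list(self.obs_values),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            pi=np.array(d["pi"]),
            A=np.array(d["A"]),
            B=np.array(d["B"]),
            state_labels=tuple(d["state_labels"]),
            state_codes=tuple(d["state_codes"]),
            obs_labels=tuple(d["obs_labels"]),
            obs_values=tuple(d["obs_values"]),
        )


def default_spec() -> HmmSpec:
    """The opinion-policy consensus parameterization of the case study."""
    return HmmSpec(
        pi=np.array([1.0, 0.0]),
        A=np.array([[0.7, 0.3], [0.3, 0.7]]),
        B=np.array([[0.6, 0.3, 0.1], [0.1, 0.3, 0.6]]),
    )


@dataclass(frozen=True)
class Trajectory:
    """One simulated state/observation path of length T."""

    states: np.ndarray  # hidden-state indices, shape (T,)
    observations: np.ndarray  # observation symbol indices, shape (T,)
    spec: HmmSpec
    seed: int

    @property
    def T(self) -> int:
        return len(self.states)

    @property
    def state_codes(self) -> np.ndarray:
        """Numeric state codes (Continue=1, Change=0) along the path."""
        return np.asarray(self.spec.state_codes)[self.states]

    @property
    def observation_values(self) -> np.ndarray:
        """Numeric observation values (1 / 0.5 / 0) along the path."""
        return np.asarray(self.spec.obs_values)[self.observations]


@dataclass
class EnsembleSummary:
    """Per-time-step averages over repeated simulation runs."""

    n_runs: int
    T: int
    mean_observation: np.ndarray  # shape (T,)
    mean_state: np.ndarray  # shape (T,)
    seed: int


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent sub-seeds (< 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def sample_trajectory(spec: HmmSpec, T: int, seed: int = 0) -> Trajectory:
    """Sample one hidden path and its observations.

    i_1 ~ pi, i_{t+1} ~ A[i_t], o_t ~ B[i_t]; deterministic for a fixed
    seed.
    """
    if T < 1:
        raise ValueError(f"trajectory length must be >= 1, got {T}")
    rng = np.random.default_rng(seed)
    n, m = spec.n_states, spec.n_symbols
    # inverse-CDF sampling from precomputed row CDFs (fast and reproducible)
    cdf_pi = np.cumsum(spec.pi)
    cdf_A = np.cumsum(spec.A, axis=1)
    cdf_B = np.cumsum(spec.B, axis=1)
    u_state = rng.random(T)
    u_obs = rng.random(T)
    states = np.empty(T, dtype=int)
    states[0] = min(int(np.searchsorted(cdf_pi, u_state[0], side="right")), n - 1)
    for t in range(1, T):
        row = cdf_A[states[t - 1]]
        states[t] = min(int(np.searchsorted(row, u_state[t], side="right")), n - 1)
    obs = np.minimum(
        (u_obs[:, None] >= cdf_B[states]).sum(axis=1), m - 1
    ).astype(int)
    return Trajectory(states=states, observations=obs, spec=spec, seed=seed)


def simulate_ensemble(
    spec: HmmSpec, T: int, n_runs: int = 10, seed: int = 0
) -> EnsembleSummary:
    """Average numeric observations and state codes over repeated runs.

    The default of 10 runs mirrors the case study's small-ensemble
    averaging; per-run seeds are derived deterministically from ``seed``.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    seeds = derive_seeds(seed, n_runs)
    obs_sum = np.zeros(T)
    state_sum = np.zeros(T)
    for s in seeds:
        traj = sample_trajectory(spec, T, seed=s)
        obs_sum += traj.observation_values
        state_sum += traj.state_codes
    return EnsembleSummary(
        n_runs=n_runs,
        T=T,
        mean_observation=obs_sum / n_runs,
        mean_state=state_sum / n_runs,
        seed=seed,
    )


def _as_symbol_indices(
    spec: HmmSpec,
    observations: Sequence[float | OpinionObservation | str] | np.ndarray,
) -> np.ndarray:
    """Map observation values / labels / OpinionObservations to symbol indices."""
    value_to_idx = {round(v, 12): k for k, v in enumerate(spec.obs_values)}
    label_to_idx = {lab: k for k, lab in enumerate(spec.obs_labels)}
    idx = []
    for o in observations:
        if isinstance(o, OpinionObservation):
            o = o.state
        if isinstance(o, str):
            if o not in label_to_idx:
                raise ValueError(f"observation label {o!r} not in {spec.obs_labels}")
            idx.append(label_to_idx[o])
        else:
            key = round(float(o), 12)
            if key not in value_to_idx:
                raise ValueError(
                    f"observation value {o!r} not among {spec.obs_values}"
                )
            idx.append(value_to_idx[key])
    return np.asarray(idx, dtype=int)


def forward_filter(
    spec: HmmSpec,
    observations: Sequence[float | OpinionObservation | str] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Scaled forward recursion: per-step filtering posteriors and log-likelihood.

    Returns ``(posteriors, loglik)`` where ``posteriors[t]`` is
    P(i_{t+1} = . | o_1..o_{t+1}) (rows sum to 1) and ``loglik`` is
    log P(o_1..o_T).  Observations may be numeric values from
    ``spec.obs_values``, labels, or :class:`~opinionflow.concern.OpinionObservation`.
    """
    obs = _as_symbol_indices(spec, observations)
    if len(obs) == 0:
        raise ValueError("cannot filter an empty observation sequence")
    T, n = len(obs), spec.n_states
    post = np.empty((T, n))
    loglik = 0.0
    alpha = spec.pi * spec.B[:, obs[0]]
    for t in range(T):
        if t > 0:
            alpha = (post[t - 1] @ spec.A) * spec.B[:, obs[t]]
        c = alpha.sum()
        if c <= 0:
            raise ValueError(
                f"observation at step {t} has zero probability under the model"
            )
        post[t] = alpha / c
        loglik += float(np.log(c))
    return post, loglik


def _batch_forward_backward(
    spec: HmmSpec, obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward and backward passes for a (S, T) batch of sequences."""
    S, T = obs.shape
    n = spec.n_states
    alpha = np.empty((S, T, n))
    scales = np.empty((S, T))
    a = spec.pi[None, :] * spec.B[:, obs[:, 0]].T
    for t in range(T):
        if t > 0:
            a = (alpha[:, t - 1, :] @ spec.A) * spec.B[:, obs[:, t]].T
        c = a.sum(axis=1)
        if np.any(c <= 0):
            raise ValueError(f"zero-probability observation at step {t}")
        scales[:, t] = c
        alpha[:, t, :] = a / c[:, None]
    beta = np.empty((S, T, n))
    beta[:, -1, :] = 1.0
    for t in range(T - 2, -1, -1):
        eb = spec.B[:, obs[:, t + 1]].T * beta[:, t + 1, :]
        beta[:, t, :] = (eb @ spec.A.T) / scales[:, t + 1, None]
    return alpha, beta, scales


@dataclass
class BaumWelchResult:
    spec: HmmSpec
    log_likelihoods: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def baum_welch(
    init: HmmSpec,
    sequences: Sequence[Sequence[float]] | Sequence[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 200,
    update_pi: bool = True,
) -> BaumWelchResult:
    """Baum-Welch (EM) estimation of (A, B, pi) from observation sequences.

    The per-iteration total log-likelihood is non-decreasing (within 1e-9);
    iteration stops when its increase falls below ``tol`` or after
    ``max_iter`` rounds.  Raises ``ValueError`` if the initial emission
    matrix gives an observed symbol zero probability in every state, which
    EM cannot recover from.
    """
    if len(sequences) == 0:
        raise ValueError("Baum-Welch requires at least one sequence")
    obs_seqs = [_as_symbol_indices(init, seq) for seq in sequences]
    observed = set(int(s) for seq in obs_seqs for s in seq)
    dead = [k for k in observed if np.all(init.B[:, k] == 0)]
    if dead:
        raise ValueError(
            f"initial emission matrix gives observed symbols {dead} zero mass"
        )

    # group sequences by length so forward-backward vectorizes across them
    by_len: dict[int, list[np.ndarray]] = {}
    for obs in obs_seqs:
        by_len.setdefault(len(obs), []).append(obs)
    batches = [np.stack(group) for group in by_len.values()]

    spec = init
    history: list[float] = []
    converged = False
    n, m = init.n_states, init.n_symbols
    it = 0
    for it in range(1, max_iter + 1):
        pi_acc = np.zeros(n)
        trans_acc = np.zeros((n, n))
        emit_acc = np.zeros((n, m))
        total_ll = 0.0
        for obs in batches:  # obs shape (S, T)
            S, T = obs.shape
            alpha, beta, scales = _batch_forward_backward(spec, obs)
            total_ll += float(np.log(scales).sum())
            gamma = alpha * beta  # (S, T, n)
            gamma /= gamma.sum(axis=2, keepdims=True)
            pi_acc += gamma[:, 0, :].sum(axis=0)
            for t in range(T - 1):
                eb = spec.B[:, obs[:, t + 1]].T * beta[:, t + 1, :]
                eb /= scales[:, t + 1, None]
                trans_acc += spec.A * (alpha[:, t, :].T @ eb)
            for k in range(m):
                emit_acc[:, k] += gamma[obs == k].sum(axis=0)
        history.append(total_ll)
        if len(history) > 1:
            delta = history[-1] - history[-2]
            if delta < -1e-9:
                raise AssertionError("EM log-likelihood decreased")
            if delta < tol:
                converged = True
                break
        new_pi = pi_acc / pi_acc.sum() if update_pi else spec.pi
        row = trans_acc.sum(axis=1, keepdims=True)
        new_A = np.where(row > 0, trans_acc / np.where(row > 0, row, 1.0), spec.A)
        erow = emit_acc.sum(axis=1, keepdims=True)
        new_B = np.where(erow > 0, emit_acc / np.where(erow > 0, erow, 1.0), spec.B)
        spec = replace(spec, pi=new_pi, A=new_A, B=new_B)
    return BaumWelchResult(
        spec=spec, log_likelihoods=history, n_iter=it, converged=converged
    )


def canonical_relabel(spec: HmmSpec) -> HmmSpec:
    """Resolve EM label switching: the state emitting Support most is Continue.

    Reorders states so the state with the highest probability of the first
    observation symbol comes first; labels/codes keep canonical order.
    """
    order = np.argsort(-spec.B[:, 0], kind="stable")
    return replace(
        spec,
        pi=spec.pi[order],
        A=spec.A[np.ix_(order, order)],
        B=spec.B[order],
    )


def fit_hmm(
    sequences: Sequence[Sequence[float]],
    n_states: int = 2,
    n_symbols: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> BaumWelchResult:
    """Unsupervised fit: Baum-Welch from random initializations, best of 10.

    Restart initial parameters are Dirichlet-perturbed uniform rows; the
    winning fit (highest final log-likelihood) is canonically relabelled.
    """
    template = default_spec()
    if (n_states, n_symbols) != (template.n_states, template.n_symbols):
        raise ValueError("only the 2-state / 3-symbol opinion model is supported")
    rng = np.random.default_rng(seed)
    best: BaumWelchResult | None = None
    for _ in range(n_restarts):
        init = replace(
            template,
            pi=rng.dirichlet(np.ones(n_states) * 5),
            A=rng.dirichlet(np.ones(n_states) * 5, size=n_states),
            B=rng.dirichlet(np.ones(n_symbols) * 5, size=n_states),
        )
        res = baum_welch(init, sequences, tol=tol, max_iter=max_iter)
        if best is None or res.log_likelihoods[-1] > best.log_likelihoods[-1]:
            best = res
    assert best is not None
    best.spec = canonical_relabel(best.spec)
    return best


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic transition matrix."""
    A = np.asarray(A, dtype=float)
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


def expected_observation(spec: HmmSpec, t: int = 1) -> float:
    """Closed-form expected numeric observation value at step t (1-based).

    E[o_t] = pi A^{t-1} B v with v the numeric observation values; for the
    case-study parameterization E[o_1] = 0.75.
    """
    if t < 1:
        raise ValueError("t is 1-based and must be >= 1")
    state_dist = spec.pi @ np.linalg.matrix_power(spec.A, t - 1)
    return float(state_dist @ spec.B @ np.asarray(spec.obs_values))
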