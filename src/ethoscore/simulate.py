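"""Synthetic scored trials and noisy second-rater replicas.

The generator is an alternating-renewal / semi-Markov process: draw an
initial state from ``pi``, draw a bout length from that state's duration
distribution (exponential or gamma), transition according to ``P`` (zero
diagonal, so consecutive bouts always differ), and repeat until the trial
duration is filled; the final bout is clipped.  Point behaviors arrive as
independent homogeneous Poisson processes.  Everything is deterministic
given a seed.

A second rater is emulated by perturbing an existing trial: transition
instants are jittered (jointly — a boundary shared by two bouts moves
once, so the perturbed timeline remains a partition), bouts are mislabeled
with some probability, and point events are missed or spuriously inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import SchemaMismatchError
from .ethogram import Ethogram
from .timeline import Bout, PointOccurrence, ScoredTrial

__all__ = [
    "DurationDist",
    "BehaviorModel",
    "RaterNoise",
    "simulate_trial",
    "simulate_second_rater",
    "fst_like_model",
    "subject_seed",
]


@dataclass(frozen=True)
class DurationDist:
    """Bout-length distribution for one state behavior.

    ``kind`` is ``"exponential"`` (parameterized by ``mean``) or
    ``"gamma"`` (``shape`` and ``scale``; mean = shape * scale).
    """

    kind: str = "exponential"
    mean: float = 10.0
    shape: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "gamma"):
            raise ValueError(f"unknown duration distribution {self.kind!r}")
        if self.kind == "gamma":
            if self.shape is None or self.scale is None:
                raise ValueError("gamma distribution needs shape and scale")
            if self.shape <= 0 or self.scale <= 0:
                raise ValueError("gamma shape and scale must be > 0")
            object.__setattr__(self, "mean", self.shape * self.scale)
        if not self.mean > 0:
            raise ValueError("mean bout duration must be > 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "exponential":
            return float(rng.exponential(self.mean))
        return float(rng.gamma(self.shape, self.scale))


@dataclass(frozen=True)
class BehaviorModel:
    """Semi-Markov generative model over an ethogram's behaviors."""

    states: tuple[str, ...]
    durations: Mapping[str, DurationDist]
    transition: np.ndarray  # row-stochastic, zero diagonal
    initial: np.ndarray  # probability vector over states
    point_rates: Mapping[str, float] = field(default_factory=dict)  # events / second

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        P = np.asarray(self.transition, dtype=float)
        pi = np.asarray(self.initial, dtype=float)
        object.__setattr__(self, "transition", P)
        object.__setattr__(self, "initial", pi)
        k = len(self.states)
        if P.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}, got {P.shape}")
        if k > 1 and not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.abs(np.diag(P)) > 1e-12):
            raise ValueError("transition matrix diagonal must be zero")
        if pi.shape != (k,) or not np.isclose(pi.sum(), 1.0, atol=1e-9) or np.any(pi < 0):
            raise ValueError("initial distribution must be a length-k probability vector")
        for s in self.states:
            if s not in self.durations:
                raise ValueError(f"no duration distribution for state {s!r}")
        for name, lam in self.point_rates.items():
            if lam < 0:
                raise ValueError(f"point rate for {name!r} must be >= 0")

    def check_against(self, etho: Ethogram) -> None:
        state_names = {b.name for b in etho.state_behaviors}
        if set(self.states) != state_names:
            raise SchemaMismatchError(
                f"model states {sorted(self.states)} do not match ethogram state "
                f"behaviors {sorted(state_names)}"
            )
        point_names = {b.name for b in etho.point_behaviors}
        extra = set(self.point_rates) - point_names
        if extra:
            raise SchemaMismatchError(
                f"model point rates for non-point behavior(s): {sorted(extra)}"
            )


@dataclass(frozen=True)
class RaterNoise:
    """Parameters of the simulated second rater's errors.

    * ``jitter_sigma_s``: zero-mean Gaussian shift of each transition time
      (order-preserving, clamped to [0, T]).
    * ``mislabel_prob``: per-bout probability of relabeling to a uniformly
      random other state.
    * ``point_miss_prob``: per-occurrence deletion probability.
    * ``false_point_rate``: spurious point events per second.
    """

    jitter_sigma_s: float = 0.0
    mislabel_prob: float = 0.0
    point_miss_prob: float = 0.0
    false_point_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma_s < 0 or self.false_point_rate < 0:
            raise ValueError("jitter sigma and false-point rate must be >= 0")
        for p in (self.mislabel_prob, self.point_miss_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def subject_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    """Reproducible per-animal sub-stream: counter-based offset of one seed."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))


def simulate_trial(
    model: BehaviorModel,
    etho: Ethogram,
    duration_s: float,
    seed,
    *,
    subject_id: str = "sim",
    session_index: int = 1,
    trial_index: int = 1,
    rater_id: str = "sim",
) -> ScoredTrial:
    """Generate one fully covered trial from the semi-Markov model.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    Identical seeds produce identical trials.
    """
    model.check_against(etho)
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)

    k = len(model.states)
    state = int(rng.choice(k, p=model.initial))
    t = 0.0
    bouts: list[Bout] = []
    while t < duration_s:
        name = model.states[state]
        length = model.durations[name].draw(rng)
        end = min(t + length, duration_s)
        if end > t:
            bouts.append(Bout(name, t, end))
        t = t + length
        if t < duration_s and k > 1:
            state = int(rng.choice(k, p=model.transition[state]))
        elif k == 1:
            break  # single state: one bout covers everything
    if k == 1:
        bouts = [Bout(model.states[0], 0.0, duration_s)]

    points: list[PointOccurrence] = []
    for beh in etho.point_behaviors:
        lam = model.point_rates.get(beh.name, 0.0)
        if lam <= 0:
            continue
        n = int(rng.poisson(lam * duration_s))
        for tt in np.sort(rng.uniform(0.0, duration_s, size=n)):
            points.append(PointOccurrence(beh.name, float(tt)))
    points.sort(key=lambda p: p.t)

    return ScoredTrial(
        subject_id=subject_id,
        duration_s=float(duration_s),
        bouts=tuple(bouts),
        points=tuple(points),
        session_index=session_index,
        trial_index=trial_index,
        rater_id=rater_id,
    )


def simulate_second_rater(
    trial: ScoredTrial,
    noise: RaterNoise,
    *,
    point_behaviors: Sequence[str] | None = None,
    rater_id: str = "rater2",
) -> ScoredTrial:
    """Derive a noisy re-scoring of ``trial`` per the noise model.

    Boundary jitter moves each distinct transition instant once (shared
    boundaries stay shared), then the jittered instants are re-sorted and
    clamped to [0, T], so no overlaps or new gaps are introduced;
    zero-length bouts are dropped.  With all noise parameters at zero the
    output timeline equals the input.
    """
    rng = np.random.default_rng(noise.seed)
    T = trial.duration_s

    # jitter transition instants jointly: a boundary shared by consecutive
    # bouts appears once here, so it moves once and the partition survives
    uniq: list[float] = sorted({x for b in trial.bouts for x in (b.start, b.end)})
    pos = {x: i for i, x in enumerate(uniq)}
    if noise.jitter_sigma_s > 0 and uniq:
        jittered = np.asarray(uniq) + rng.normal(0.0, noise.jitter_sigma_s, size=len(uniq))
        jittered = np.clip(np.sort(jittered), 0.0, T)  # order-preserving
    else:
        jittered = np.asarray(uniq, dtype=float)

    new_bouts: list[Bout] = []
    for b in trial.bouts:
        s = float(jittered[pos[b.start]])
        e = float(jittered[pos[b.end]])
        if e > s:
            new_bouts.append(Bout(b.behavior, s, e))

    # --- mislabel bouts -----------------------------------------------------
    states = sorted({b.behavior for b in trial.bouts})
    if noise.mislabel_prob > 0 and len(states) > 1:
        relabeled = []
        for b in new_bouts:
            if rng.random() < noise.mislabel_prob:
                others = [s for s in states if s != b.behavior]
                b = replace(b, behavior=others[int(rng.integers(len(others)))])
            relabeled.append(b)
        new_bouts = relabeled

    # --- point events: misses and false insertions --------------------------
    new_points = [p for p in trial.points if rng.random() >= noise.point_miss_prob]
    if noise.false_point_rate > 0:
        if point_behaviors is None:
            point_behaviors = sorted({p.behavior for p in trial.points})
        if point_behaviors:
            n_fp = int(rng.poisson(noise.false_point_rate * T))
            for tt in rng.uniform(0.0, T, size=n_fp):
                name = point_behaviors[int(rng.integers(len(point_behaviors)))]
                new_points.append(PointOccurrence(name, float(tt)))
    new_points.sort(key=lambda p: p.t)

    return replace(
        trial, bouts=tuple(new_bouts), points=tuple(new_points), rater_id=rater_id
    )


def fst_like_model(
    mean_durations: Mapping[str, float] | None = None,
    head_shake_rate: float = 0.02,
) -> BehaviorModel:
    """Convenience 3-state model matching the built-in FST ethogram.

    Default mean bout durations: immobility 8 s, swimming 6 s, climbing
    4 s (exponential); transitions uniform over the other two states;
    head shakes at ``head_shake_rate`` per second.
    """
    means = {"immobility": 8.0, "swimming": 6.0, "climbing": 4.0}
    if mean_durations:
        means.update(mean_durations)
    states = ("immobility", "swimming", "climbing")
    P = (np.ones((3, 3)) - np.eye(3)) / 2.0
    pi = np.full(3, 1.0 / 3.0)
    return BehaviorModel(
        states=states,
        durations={s: DurationDist("exponential", means[s]) for s in states},
        transition=P,
        initial=pi,
        point_rates={"head_shake": head_shake_rate},
    )
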