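"""Synthetic ethogram cohorts with controlled statistical structure.

A semi-Markov generator standing in for recorded fly videos: it emits
alternating behavior bouts whose class (grooming vs. walk/stand), grooming
pole (anterior vs. posterior) and duration follow user-set laws, so each
quantification metric can be validated against known ground truth
independently of the dust model.  Records emulate classifier output for
dusted flies: 30 Hz label streams of ~50,000 frames, cohorts of >= 10 flies,
heavy-tailed bout durations, and a time-varying anterior -> posterior bias.

The anterior bias is a function of bout-start time; the logistic-decay
preset ``logistic_bias(t0, k)`` crosses 0.5 at t0, mimicking the grooming
progression, so its midpoint should be recoverable as the cohort crossover
time.  Within a run of same-pole grooming bouts the concrete label
alternates sweep <-> rub with probability 0.8 by default, mimicking the
sweep/leg-rub cycling of real grooming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .bouts import BoutDurationModel, EmpiricalBoutModel, LogNormalBoutModel
from .ethogram import Cohort, Ethogram

__all__ = [
    "SynthSpec",
    "constant_bias",
    "logistic_bias",
    "generate_cohort",
    "empirical_bout_sampler",
]


def constant_bias(c: float) -> Callable[[float], float]:
    """Anterior bias fixed at ``c`` for all times."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("bias must lie in [0, 1]")
    return lambda t: c


def logistic_bias(t0_s: float, k_per_s: float = 0.02) -> Callable[[float], float]:
    """Logistic decay 1 / (1 + exp(k (t - t0))): anterior-dominant early,
    posterior-dominant late, crossing 0.5 at ``t0_s`` seconds."""
    return lambda t: 1.0 / (1.0 + math.exp(k_per_s * (t - t0_s)))


@dataclass
class SynthSpec:
    """Parameters of one synthetic cohort.

    ``grooming_fraction`` is the probability that a bout is grooming rather
    than walk/stand (split equally); dusted flies spend most of the record
    grooming, hence the 0.9 default.  ``anterior_bias`` maps a bout's start
    time (seconds) to the probability that a grooming bout is anterior.
    """

    n_flies: int = 10
    run_frames: int = 50_000
    frame_rate_hz: float = 30.0
    anterior_bias: Callable[[float], float] = field(default_factory=lambda: constant_bias(0.5))
    grooming_fraction: float = 0.9
    alternation_p: float = 0.8
    bout_model: BoutDurationModel = field(default_factory=LogNormalBoutModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.run_frames < 1:
            raise ValueError("run_frames must be >= 1")
        if not 0.0 <= self.grooming_fraction <= 1.0:
            raise ValueError("grooming_fraction must lie in [0, 1]")
        if not 0.0 <= self.alternation_p <= 1.0:
            raise ValueError("alternation_p must lie in [0, 1]")


_SWEEP = {"anterior": "head_sweep", "posterior": "body_sweep"}
_RUB = {"anterior": "front_leg_rub", "posterior": "back_leg_rub"}


def _generate_fly(spec: SynthSpec, fly_id: str, rng: np.random.Generator) -> Ethogram:
    labels: list[np.ndarray] = []
    frames_done = 0
    prev_pole: str | None = None  # pole of the previous grooming bout, if contiguous
    prev_kind: str | None = None  # "sweep" or "rub"
    while frames_done < spec.run_frames:
        t_s = frames_done / spec.frame_rate_hz
        if rng.random() < spec.grooming_fraction:
            bias = float(spec.anterior_bias(t_s))
            if not 0.0 <= bias <= 1.0:
                raise ValueError(f"anterior_bias({t_s}) = {bias} outside [0, 1]")
            pole = "anterior" if rng.random() < bias else "posterior"
            if pole == prev_pole and prev_kind is not None:
                # within a class run, alternate sweep <-> rub most of the time
                flip = rng.random() < spec.alternation_p
                kind = ("rub" if prev_kind == "sweep" else "sweep") if flip else prev_kind
            else:
                kind = "sweep"
            if kind == "sweep":
                label = _SWEEP[pole]
                if pole == "posterior" and rng.random() < 0.5:
                    label = "wing_sweep"
            else:
                label = _RUB[pole]
            prev_pole, prev_kind = pole, kind
        else:
            label = "walk" if rng.random() < 0.5 else "stand"
            prev_pole = prev_kind = None
        dur = spec.bout_model.sample(label, rng, spec.frame_rate_hz)
        dur = min(dur, spec.run_frames - frames_done)
        labels.append(np.full(dur, label, dtype="U16"))
        frames_done += dur
    return Ethogram(fly_id, np.concatenate(labels), spec.frame_rate_hz)


def generate_cohort(spec: SynthSpec, group_name: str = "synthetic") -> Cohort:
    """Generate a cohort of independent synthetic flies; deterministic under
    ``spec.seed``."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_flies) % (2**31)
    ethograms = [
        _generate_fly(spec, f"fly_{i:02d}", np.random.default_rng(int(s)))
        for i, s in enumerate(seeds)
    ]
    return Cohort(ethograms, group_name=group_name)


def empirical_bout_sampler(
    durations: Mapping[str, Sequence[int]]
) -> EmpiricalBoutModel:
    """Bout-duration model resampling observed per-behavior frame counts."""
    return EmpiricalBoutModel(durations)
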