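"""Two-layer stochastic dust-competition model of grooming action selection.

The model abstracts a dust-covered fly as five competing body parts — head,
wings, abdomen, front legs, back legs — each carrying a dust load d(t).  Dust
deflects mechanosensory bristles, so each part's sensory drive is a noisy
readout of its load:

    a(t) ~ N(d(t), sigma(t)^2),   sigma(t) = d(t) / noise_divisor

with noise_divisor = 5 by default (a mean-to-SD ratio of 5, matching bristle
electrophysiology).  A winner-take-all layer grooms the part with the highest
drive for one bout.  Grooming moves dust: when a body surface wins, a fraction
``dr`` of its dust transfers to the legs that clean it (head -> front legs;
wings and abdomen -> back legs); when a leg pair wins (leg rubbing), a
fraction ``10*dr`` of its dust is shed from the fly entirely.  Because
removal is proportional to the current load, cleaning has diminishing
returns, and the gradual re-ranking of loads drives the stereotyped
anterior-to-posterior grooming progression.

Dust updates once per bout, not per frame; bout durations are drawn from a
:class:`~groomsim.bouts.BoutDurationModel` purely to render the winner
sequence onto the frame axis.  Simulated ethograms therefore contain grooming
labels only.

Wild-type defaults set initial dust proportional to bristle counts: head
1200, abdomen 600, wings 400, and 200 on each leg pair, with dr = 0.002
(0.2% per bout), which reproduces the progression speed of dusted flies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .bouts import BoutDurationModel, LogNormalBoutModel
from .ethogram import Cohort, Ethogram

__all__ = [
    "BODY_PARTS",
    "LEG_PARTS",
    "CLEANING_LEGS",
    "EMITTED_BEHAVIOR",
    "DustState",
    "SensoryActivity",
    "ModelParams",
    "Bout",
    "SimulationTrace",
    "sample_activity",
    "select_winner",
    "update_dust",
    "simulate",
    "run_cohort",
    "wild_type_dust",
]

BODY_PARTS: tuple[str, ...] = ("head", "wings", "abdomen", "front_legs", "back_legs")
LEG_PARTS: frozenset[str] = frozenset({"front_legs", "back_legs"})

#: Which leg pair cleans each body surface.
CLEANING_LEGS: dict[str, str] = {
    "head": "front_legs",
    "wings": "back_legs",
    "abdomen": "back_legs",
}

#: Behavior label emitted while a part is being groomed.
EMITTED_BEHAVIOR: dict[str, str] = {
    "head": "head_sweep",
    "wings": "wing_sweep",
    "abdomen": "body_sweep",
    "front_legs": "front_leg_rub",
    "back_legs": "back_leg_rub",
}


@dataclass(frozen=True)
class DustState:
    """Per-body-part dust load d(t), in arbitrary units (all entries >= 0)."""

    head: float = 0.0
    wings: float = 0.0
    abdomen: float = 0.0
    front_legs: float = 0.0
    back_legs: float = 0.0

    def __post_init__(self) -> None:
        for part in BODY_PARTS:
            if self[part] < 0:
                raise ValueError(f"negative dust on {part}: {self[part]}")

    def __getitem__(self, part: str) -> float:
        if part not in BODY_PARTS:
            raise KeyError(f"unknown body part {part!r}")
        return float(getattr(self, part))

    def as_dict(self) -> dict[str, float]:
        return {part: self[part] for part in BODY_PARTS}

    def as_array(self) -> np.ndarray:
        return np.array([self[part] for part in BODY_PARTS], dtype=float)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "DustState":
        unknown = set(mapping) - set(BODY_PARTS)
        if unknown:
            raise KeyError(f"unknown body parts: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @property
    def total(self) -> float:
        return float(sum(self.as_dict().values()))


def wild_type_dust() -> DustState:
    """Initial loads proportional to bristle counts (head 1200, abdomen 600,
    wings 400) with 200 on each leg pair."""
    return DustState(head=1200.0, wings=400.0, abdomen=600.0, front_legs=200.0, back_legs=200.0)


@dataclass(frozen=True)
class SensoryActivity:
    """One draw of per-part neural drive a(t) and its noise scale sigma(t)."""

    a: dict[str, float]
    sigma: dict[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.a[p] for p in BODY_PARTS], dtype=float)


@dataclass
class ModelParams:
    """Configuration of one simulation run.

    dr is the per-bout dust-removal fraction (legs discard at 10*dr, so
    dr <= 0.1); run_frames fixes the horizon, truncating the last bout.
    ``drive``, if given, replaces d(t) as the mean of a(t) with a
    user-supplied time series per part (seconds -> drive) and freezes dust
    updates — an external-stimulation mode mimicking optogenetic ramps.
    """

    initial_dust: DustState = field(default_factory=wild_type_dust)
    dr: float = 0.002
    noise_divisor: float = 5.0
    run_frames: int = 50_000
    frame_rate_hz: float = 30.0
    seed: int = 0
    bout_model: BoutDurationModel = field(default_factory=LogNormalBoutModel)
    drive: Mapping[str, Callable[[float], float]] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dr <= 0.1):
            raise ValueError(f"dr must lie in [0, 0.1] (10*dr <= 1), got {self.dr}")
        if self.noise_divisor <= 0:
            raise ValueError("noise_divisor must be positive")
        if self.run_frames < 1:
            raise ValueError("run_frames must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")


@dataclass(frozen=True)
class Bout:
    winner: str
    duration_frames: int
    dust_before: DustState


@dataclass
class SimulationTrace:
    """Bout-level record of one run: winners, durations, dust trajectory."""

    bouts: list[Bout]
    final_dust: DustState


# ---------------------------------------------------------------------------
# model primitives


def sample_activity(
    d: DustState,
    noise_divisor: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> SensoryActivity:
    """Draw sensory drive a ~ N(d, (d/noise_divisor)^2) independently per part.

    A part with no dust is silent: d = 0 gives sigma = 0 and a = 0 exactly.
    Negative draws are permitted for d > 0 (the normal is not truncated);
    only the argmax matters downstream.  With ``size`` set, each part's entry
    is a vector of ``size`` independent draws.
    """
    if noise_divisor <= 0:
        raise ValueError("noise_divisor must be positive")
    a: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for part in BODY_PARTS:
        loc = d[part]
        scale = loc / noise_divisor
        sigma[part] = scale
        draw = rng.normal(loc, scale, size=size)
        a[part] = float(draw) if size is None else draw
    return SensoryActivity(a=a, sigma=sigma)


def select_winner(a: SensoryActivity, rng: np.random.Generator) -> str:
    """Winner-take-all: the part with maximal drive; exact ties uniform."""
    vec = a.as_array()
    top = np.flatnonzero(vec == vec.max())
    idx = top[0] if top.size == 1 else top[rng.integers(top.size)]
    return BODY_PARTS[idx]


def update_dust(d: DustState, winner: str, dr: float) -> DustState:
    """Apply one bout's dust update.

    Leg winner (leg rubbing): the leg pair sheds 10*dr of its dust from the
    fly; everything else unchanged.  Body-surface winner: dr of its dust
    transfers, conserved, to its cleaning legs.
    """
    if winner not in BODY_PARTS:
        raise KeyError(f"unknown body part {winner!r}")
    if not (0.0 <= dr <= 0.1):
        raise ValueError(f"dr must lie in [0, 0.1], got {dr}")
    loads = d.as_dict()
    if winner in LEG_PARTS:
        loads[winner] = loads[winner] * (1.0 - 10.0 * dr)
    else:
        moved = loads[winner] * dr
        loads[winner] -= moved
        loads[CLEANING_LEGS[winner]] += moved
    return DustState.from_mapping(loads)


# ---------------------------------------------------------------------------
# full runs


def simulate(params: ModelParams) -> tuple[SimulationTrace, Ethogram]:
    """Run one fly: iterate draw-drive / pick-winner / render-bout / move-dust
    until the frame horizon is reached (the last bout is truncated).

    Identical params (including seed) give bit-identical outputs.  The RNG
    stream is consumed in a fixed order per bout: five activity draws, a
    tie-break only on exact ties, then the bout duration.
    """
    rng = np.random.default_rng(params.seed)
    d = params.initial_dust
    bouts: list[Bout] = []
    labels: list[np.ndarray] = []
    frames_done = 0
    while frames_done < params.run_frames:
        t_s = frames_done / params.frame_rate_hz
        if params.drive is not None:
            means = {p: float(params.drive[p](t_s)) if p in params.drive else 0.0
                     for p in BODY_PARTS}
            act = _activity_from_means(means, params.noise_divisor, rng)
        else:
            act = sample_activity(d, params.noise_divisor, rng)
        winner = select_winner(act, rng)
        dur = params.bout_model.sample(
            EMITTED_BEHAVIOR[winner], rng, params.frame_rate_hz
        )
        dur = min(dur, params.run_frames - frames_done)
        bouts.append(Bout(winner=winner, duration_frames=dur, dust_before=d))
        labels.append(np.full(dur, EMITTED_BEHAVIOR[winner], dtype="U16"))
        if params.drive is None:
            d = update_dust(d, winner, params.dr)
        frames_done += dur
    trace = SimulationTrace(bouts=bouts, final_dust=d)
    etho = Ethogram(
        fly_id=f"sim_{params.seed}",
        labels=np.concatenate(labels),
        frame_rate_hz=params.frame_rate_hz,
    )
    return trace, etho


def _activity_from_means(
    means: Mapping[str, float], noise_divisor: float, rng: np.random.Generator
) -> SensoryActivity:
    a: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for part in BODY_PARTS:
        loc = float(means[part])
        scale = abs(loc) / noise_divisor
        sigma[part] = scale
        a[part] = float(rng.normal(loc, scale))
    return SensoryActivity(a=a, sigma=sigma)


def run_cohort(
    params: ModelParams,
    n_flies: int,
    base_seed: int | None = None,
    group_name: str = "",
) -> Cohort:
    """Simulate ``n_flies`` independent flies with distinct derived seeds."""
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    base = params.seed if base_seed is None else base_seed
    seeds = np.random.SeedSequence(base).generate_state(n_flies) % (2**31)
    ethograms = []
    for i, s in enumerate(seeds):
        _, e = simulate(replace(params, seed=int(s)))
        e.fly_id = f"fly_{i:02d}"
        ethograms.append(e)
    return Cohort(ethograms, group_name=group_name)
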