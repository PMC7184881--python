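"""Frame-level behavior records (ethograms) and their coarse grooming classes.

An ethogram is a sequence of behavior labels, one per video frame at a fixed
frame rate, as produced by an automatic behavior classifier, by the dust-model
simulator, or by the synthetic generator.  Every label belongs to exactly one
coarse class used by the quantification layer:

* ``anterior``  — front-leg movements directed at the head: head sweeps and
  front-leg rubs;
* ``posterior`` — back-leg movements: body (abdomen) sweeps, wing sweeps and
  back-leg rubs;
* ``non_grooming`` — walking, standing, anything else.

Files are long-format delimited text with columns ``fly_id, frame, label``
(0-based frame indices, header row required).  Frame rate is metadata: label
files carry no timing, so it comes from a function argument or a sidecar
key-value config (``frame_rate_hz = 30``, plus optional ``alias.<token> =
<label>`` lines mapping a classifier's vocabulary onto ours).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIOR_LABELS",
    "ANTERIOR",
    "POSTERIOR",
    "NON_GROOMING",
    "COARSE_CLASS",
    "Ethogram",
    "Cohort",
    "coarse_classes",
    "read_ethograms",
    "write_ethograms",
    "read_config",
    "write_config",
]

#: Accepted behavior vocabulary.
BEHAVIOR_LABELS: tuple[str, ...] = (
    "head_sweep",
    "front_leg_rub",
    "body_sweep",
    "back_leg_rub",
    "wing_sweep",
    "walk",
    "stand",
    "other",
)

ANTERIOR = "anterior"
POSTERIOR = "posterior"
NON_GROOMING = "non_grooming"

#: Total map label -> coarse class; partitions the vocabulary.
COARSE_CLASS: dict[str, str] = {
    "head_sweep": ANTERIOR,
    "front_leg_rub": ANTERIOR,
    "body_sweep": POSTERIOR,
    "back_leg_rub": POSTERIOR,
    "wing_sweep": POSTERIOR,
    "walk": NON_GROOMING,
    "stand": NON_GROOMING,
    "other": NON_GROOMING,
}

# integer codes for fast vectorized metrics
_CLASS_CODE = {ANTERIOR: 0, POSTERIOR: 1, NON_GROOMING: 2}
_LABEL_CLASS_CODE = {lab: _CLASS_CODE[COARSE_CLASS[lab]] for lab in BEHAVIOR_LABELS}


@dataclass
class Ethogram:
    """One fly's frame-indexed behavior-label sequence at a fixed frame rate."""

    fly_id: str
    labels: np.ndarray
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U16")
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("ethogram must contain at least one frame")
        if not self.frame_rate_hz > 0:
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        unknown = set(np.unique(self.labels)) - set(BEHAVIOR_LABELS)
        if unknown:
            raise ValueError(f"unknown behavior labels: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def duration_minutes(self) -> float:
        return self.n_frames / self.frame_rate_hz / 60.0

    def coarse_classes(self) -> np.ndarray:
        """Per-frame coarse class names (anterior/posterior/non_grooming)."""
        code = self.coarse_codes()
        names = np.array([ANTERIOR, POSTERIOR, NON_GROOMING])
        return names[code]

    def coarse_codes(self) -> np.ndarray:
        """Per-frame coarse class as int8: 0 anterior, 1 posterior, 2 non-grooming."""
        out = np.empty(self.n_frames, dtype=np.int8)
        for lab, c in _LABEL_CLASS_CODE.items():
            out[self.labels == lab] = c
        return out

    def times_s(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate_hz


def coarse_classes(e: Ethogram) -> np.ndarray:
    """Functional alias for :meth:`Ethogram.coarse_classes`."""
    return e.coarse_classes()


@dataclass
class Cohort:
    """A group of ethograms recorded (or simulated) under one condition."""

    ethograms: list[Ethogram]
    group_name: str = ""

    def __post_init__(self) -> None:
        if not self.ethograms:
            raise ValueError("cohort must contain at least one ethogram")
        rates = {e.frame_rate_hz for e in self.ethograms}
        if len(rates) != 1:
            raise ValueError(f"mixed frame rates in cohort: {sorted(rates)}")
        ids = [e.fly_id for e in self.ethograms]
        if len(set(ids)) != len(ids):
            raise ValueError("fly_ids within a cohort must be unique")

    @property
    def frame_rate_hz(self) -> float:
        return self.ethograms[0].frame_rate_hz

    @property
    def fly_ids(self) -> list[str]:
        return [e.fly_id for e in self.ethograms]

    def __len__(self) -> int:
        return len(self.ethograms)

    def __iter__(self) -> Iterator[Ethogram]:
        return iter(self.ethograms)


# ---------------------------------------------------------------------------
# file I/O


def read_config(path: str | os.PathLike) -> dict[str, str]:
    """Read a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def write_config(mapping: Mapping[str, object], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in mapping.items():
            fh.write(f"{key} = {val}\n")


def _aliases_from_config(cfg: Mapping[str, str]) -> dict[str, str]:
    return {k[len("alias."):]: v for k, v in cfg.items() if k.startswith("alias.")}


def read_ethograms(
    path: str | os.PathLike,
    frame_rate_hz: float | None = None,
    aliases: Mapping[str, str] | None = None,
    config: str | os.PathLike | None = None,
    group_name: str = "",
    wide: bool = False,
) -> Cohort:
    """Read a delimited ethogram table into a :class:`Cohort`.

    Long format (default): columns ``fly_id, frame, label`` with a header row,
    0-based frame indices.  Wide format (``wide=True``): one column per fly,
    one row per frame, column headers are fly ids.

    Unknown label tokens raise unless an alias maps them onto the accepted
    vocabulary.  ``config`` names a sidecar key-value file providing
    ``frame_rate_hz`` and ``alias.*`` entries; explicit arguments win.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    alias_map: dict[str, str] = {}
    rate = frame_rate_hz
    if config is not None:
        cfg = read_config(config)
        alias_map.update(_aliases_from_config(cfg))
        if rate is None and "frame_rate_hz" in cfg:
            rate = float(cfg["frame_rate_hz"])
    if aliases:
        alias_map.update(aliases)
    if rate is None:
        rate = 30.0

    def clean(tokens: Iterable[str]) -> np.ndarray:
        arr = np.asarray([alias_map.get(t, t) for t in tokens], dtype="U16")
        unknown = set(np.unique(arr)) - set(BEHAVIOR_LABELS)
        if unknown:
            raise ValueError(
                f"unknown behavior labels {sorted(unknown)}; provide an alias mapping"
            )
        return arr

    ethograms: list[Ethogram] = []
    if wide:
        df = pd.read_csv(path, dtype=str)
        for col in df.columns:
            ethograms.append(Ethogram(str(col), clean(df[col].dropna()), rate))
    else:
        df = pd.read_csv(path, dtype={"fly_id": str, "frame": int, "label": str})
        missing = {"fly_id", "frame", "label"} - set(df.columns)
        if missing:
            raise ValueError(f"ethogram table missing columns: {sorted(missing)}")
        for fly_id, sub in df.groupby("fly_id", sort=False):
            sub = sub.sort_values("frame")
            frames = sub["frame"].to_numpy()
            if not np.array_equal(frames, np.arange(len(frames))):
                raise ValueError(
                    f"fly {fly_id}: frame indices must be contiguous 0-based"
                )
            ethograms.append(Ethogram(str(fly_id), clean(sub["label"]), rate))
    return Cohort(ethograms, group_name=group_name)


def write_ethograms(
    cohort: Cohort,
    path: str | os.PathLike,
    config_path: str | os.PathLike | None = None,
) -> None:
    """Write a cohort as a long-format CSV (``fly_id, frame, label``).

    Round-trips exactly through :func:`read_ethograms` (given the same frame
    rate, which ``config_path`` can record as a sidecar).
    """
    frames = [
        pd.DataFrame(
            {
                "fly_id": e.fly_id,
                "frame": np.arange(e.n_frames),
                "label": e.labels,
            }
        )
        for e in cohort
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if config_path is not None:
        write_config({"frame_rate_hz": cohort.frame_rate_hz}, config_path)
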