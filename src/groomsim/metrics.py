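"""Ethogram quantification: progression curves, A:P ratios, half-times.

The standard read-outs for the anterior-to-posterior grooming sequence:

* **behavior probabilities** — per fly, the fraction of frames in a sliding
  window spent in anterior grooming, posterior grooming, or walking, averaged
  across the cohort with SEM.  The dust-assay preset is a 32 s window every
  16 s; optogenetic assays use 5 s / 2.5 s and 10 s / 5 s.
* **A:P log ratio** — per fly and non-overlapping time bin,
  ``log10((F_A + 1) / (F_P + 1))`` where F_A and F_P are anterior and
  posterior grooming frame counts; fly-bins with no grooming at all are
  excluded from summaries.
* **anterior half-time** — when a fly has completed half of all the anterior
  grooming it will do in the record; a speed-of-progression statistic.
* **crossover time** — first window where cohort-mean posterior probability
  reaches the anterior probability.

Group comparisons are nonparametric throughout: Wilcoxon signed-rank for
paired samples, Wilcoxon rank-sum for independent samples, Kruskal-Wallis
with rank-sum post hoc for three or more groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ethogram import Cohort, Ethogram

__all__ = [
    "WindowSpec",
    "ProgressionProfile",
    "RatioSeries",
    "GroupComparison",
    "behavior_probabilities",
    "ap_log_ratio",
    "anterior_half_time",
    "crossover_time",
    "percent_time_grooming",
    "compare_groups",
]


@dataclass(frozen=True)
class WindowSpec:
    """A sliding window: width and step, both in seconds (step <= width)."""

    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        if self.step_s > self.window_s:
            raise ValueError("step_s must not exceed window_s")

    @classmethod
    def dust_assay(cls) -> "WindowSpec":
        return cls(32.0, 16.0)

    @classmethod
    def opto_short(cls) -> "WindowSpec":
        return cls(5.0, 2.5)

    @classmethod
    def opto_long(cls) -> "WindowSpec":
        return cls(10.0, 5.0)


@dataclass
class ProgressionProfile:
    """Cohort-level windowed behavior probabilities.

    ``anterior``, ``posterior`` and ``walk`` are (n_flies, n_windows)
    per-fly probability matrices; ``p_*`` / ``sem_*`` are cohort means and
    standard errors (SD with n-1 denominator over sqrt(n)).
    """

    times: np.ndarray  # window centers, seconds
    anterior: np.ndarray
    posterior: np.ndarray
    walk: np.ndarray
    fly_ids: list[str]
    window: WindowSpec

    @property
    def n_flies(self) -> int:
        return self.anterior.shape[0]

    def _mean(self, m: np.ndarray) -> np.ndarray:
        return m.mean(axis=0)

    def _sem(self, m: np.ndarray) -> np.ndarray:
        if self.n_flies < 2:
            return np.zeros(m.shape[1])
        return m.std(axis=0, ddof=1) / math.sqrt(self.n_flies)

    @property
    def p_anterior(self) -> np.ndarray:
        return self._mean(self.anterior)

    @property
    def p_posterior(self) -> np.ndarray:
        return self._mean(self.posterior)

    @property
    def p_walk(self) -> np.ndarray:
        return self._mean(self.walk)

    @property
    def sem_anterior(self) -> np.ndarray:
        return self._sem(self.anterior)

    @property
    def sem_posterior(self) -> np.ndarray:
        return self._sem(self.posterior)

    @property
    def sem_walk(self) -> np.ndarray:
        return self._sem(self.walk)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per window with means and SEMs."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "p_anterior": self.p_anterior,
                "sem_anterior": self.sem_anterior,
                "p_posterior": self.p_posterior,
                "sem_posterior": self.sem_posterior,
                "p_walk": self.p_walk,
                "sem_walk": self.sem_walk,
                "n_flies": self.n_flies,
            }
        )


@dataclass
class RatioSeries:
    """Per-fly, per-bin log10 A:P grooming ratios with an exclusion mask.

    ``values[i, j]`` is fly i's log10((F_A+1)/(F_P+1)) in bin j, NaN where
    the fly did no grooming in that bin (``excluded`` True there).
    """

    bin_edges: np.ndarray  # seconds, length n_bins + 1
    values: np.ndarray  # (n_flies, n_bins), NaN where excluded
    excluded: np.ndarray  # boolean, same shape
    fly_ids: list[str]

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def cohort_mean(self) -> np.ndarray:
        """Per-bin mean over flies with any grooming in the bin; NaN for
        bins every fly sat out."""
        out = np.full(self.values.shape[1], np.nan)
        counts = (~self.excluded).sum(axis=0)
        ok = counts > 0
        out[ok] = np.nansum(self.values[:, ok], axis=0) / counts[ok]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, fid in enumerate(self.fly_ids):
            for j, c in enumerate(self.bin_centers):
                rows.append(
                    {
                        "fly_id": fid,
                        "bin_center_s": c,
                        "log10_ap_ratio": self.values[i, j],
                        "excluded": bool(self.excluded[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _window_starts(n_frames: int, frame_rate_hz: float, w: WindowSpec) -> np.ndarray:
    """Start frames of full windows [t, t+window) stepping by step_s from 0;
    the final partial window is dropped."""
    win = int(round(w.window_s * frame_rate_hz))
    step = int(round(w.step_s * frame_rate_hz))
    if win > n_frames:
        raise ValueError("window longer than record")
    return np.arange(0, n_frames - win + 1, step), win


def behavior_probabilities(c: Cohort, w: WindowSpec) -> ProgressionProfile:
    """Sliding-window behavior probabilities per fly, summarized over a cohort.

    For each fly and window, the probability of a class is the fraction of the
    window's frames in that class (anterior grooming, posterior grooming, or
    walking).  Windows are half-open [t, t + window_s), stepping from t = 0.
    """
    n_frames = min(e.n_frames for e in c)
    starts, win = _window_starts(n_frames, c.frame_rate_hz, w)
    n_fly, n_win = len(c), len(starts)
    ant = np.empty((n_fly, n_win))
    post = np.empty((n_fly, n_win))
    walk = np.empty((n_fly, n_win))
    for i, e in enumerate(c):
        codes = e.coarse_codes()[:n_frames]
        is_walk = (e.labels[:n_frames] == "walk").astype(float)
        ca = np.concatenate([[0.0], np.cumsum(codes == 0)])
        cp = np.concatenate([[0.0], np.cumsum(codes == 1)])
        cw = np.concatenate([[0.0], np.cumsum(is_walk)])
        ant[i] = (ca[starts + win] - ca[starts]) / win
        post[i] = (cp[starts + win] - cp[starts]) / win
        walk[i] = (cw[starts + win] - cw[starts]) / win
    times = (starts + win / 2.0) / c.frame_rate_hz
    return ProgressionProfile(
        times=times, anterior=ant, posterior=post, walk=walk,
        fly_ids=c.fly_ids, window=w,
    )


def ap_log_ratio(c: Cohort, bin_s: float = 150.0) -> RatioSeries:
    """Binned log10 anterior:posterior grooming ratio per fly.

    value = log10((F_A + 1) / (F_P + 1)) over non-overlapping bins of
    ``bin_s`` seconds; a fly-bin with no grooming frames at all is excluded
    (masked) rather than scored.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_frames = min(e.n_frames for e in c)
    bin_frames = int(round(bin_s * c.frame_rate_hz))
    n_bins = n_frames // bin_frames
    if n_bins == 0:
        raise ValueError("bin longer than record")
    values = np.full((len(c), n_bins), np.nan)
    excluded = np.zeros((len(c), n_bins), dtype=bool)
    for i, e in enumerate(c):
        codes = e.coarse_codes()[: n_bins * bin_frames].reshape(n_bins, bin_frames)
        fa = (codes == 0).sum(axis=1)
        fp = (codes == 1).sum(axis=1)
        empty = (fa + fp) == 0
        excluded[i] = empty
        vals = np.log10((fa + 1.0) / (fp + 1.0))
        values[i] = np.where(empty, np.nan, vals)
    edges = np.arange(n_bins + 1) * bin_frames / c.frame_rate_hz
    return RatioSeries(bin_edges=edges, values=values, excluded=excluded, fly_ids=c.fly_ids)


def anterior_half_time(
    e: Ethogram, t_range_s: tuple[float, float] | None = None
) -> float:
    """Seconds until the fly completes half of its total anterior grooming.

    The denominator is the total anterior-grooming frame count in the
    analyzed record (optionally restricted to ``t_range_s``, e.g. a
    stimulation epoch); the half-target uses the ceiling at odd totals.
    """
    codes = e.coarse_codes()
    offset = 0
    if t_range_s is not None:
        lo = int(round(t_range_s[0] * e.frame_rate_hz))
        hi = int(round(t_range_s[1] * e.frame_rate_hz))
        codes = codes[lo:hi]
        offset = lo
    anterior = codes == 0
    total = int(anterior.sum())
    if total == 0:
        raise ValueError("no anterior grooming frames in the analyzed record")
    target = math.ceil(total / 2)
    idx = int(np.searchsorted(np.cumsum(anterior), target))
    return (offset + idx + 1) / e.frame_rate_hz


def crossover_time(p: ProgressionProfile) -> float | None:
    """Center time of the first window where cohort-mean posterior grooming
    probability reaches the anterior probability; None if it never does."""
    ant, post = p.p_anterior, p.p_posterior
    ok = np.isfinite(ant) & np.isfinite(post)
    hit = np.flatnonzero(ok & (post >= ant))
    return float(p.times[hit[0]]) if hit.size else None


def percent_time_grooming(e: Ethogram) -> float:
    """Percent of frames spent grooming (anterior or posterior)."""
    codes = e.coarse_codes()
    return 100.0 * float((codes != 2).mean())


@dataclass
class GroupComparison:
    """Report of a nonparametric group comparison."""

    test: str
    n: tuple[int, ...]
    statistic: float
    pvalue: float
    posthoc: list["GroupComparison"] = field(default_factory=list)
    pair: tuple[int, int] | None = None

    def summary(self) -> str:
        lines = [f"{self.test}: n={self.n}, statistic={self.statistic:.4g}, p={self.pvalue:.4g}"]
        for ph in self.posthoc:
            lines.append(f"  groups {ph.pair}: {ph.test} statistic={ph.statistic:.4g}, p={ph.pvalue:.4g}")
        return "\n".join(lines)


def compare_groups(
    *samples: Sequence[float],
    paired: bool = False,
    correction: str | None = None,
) -> GroupComparison:
    """Nonparametric comparison of two or more samples.

    Two samples: Wilcoxon signed-rank if ``paired`` (equal lengths required),
    else Wilcoxon rank-sum.  Three or more: Kruskal-Wallis with pairwise
    rank-sum post hoc (uncorrected by default; ``correction='bonferroni'``
    multiplies post hoc p-values by the number of pairs).
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for arr in arrays:
        if arr.size < 3:
            raise ValueError("each sample needs n >= 3")
    ns = tuple(int(a.size) for a in arrays)
    if len(arrays) == 2:
        a, b = arrays
        if paired:
            if a.size != b.size:
                raise ValueError("paired samples must have equal lengths")
            if np.array_equal(a, b):
                # zero differences everywhere: no evidence of a shift
                return GroupComparison("wilcoxon_signed_rank", ns, 0.0, 1.0)
            res = stats.wilcoxon(a, b)
            return GroupComparison("wilcoxon_signed_rank", ns, float(res.statistic), float(res.pvalue))
        res = stats.ranksums(a, b)
        return GroupComparison("wilcoxon_rank_sum", ns, float(res.statistic), float(res.pvalue))
    if paired:
        raise ValueError("paired comparison is defined for exactly two samples")
    res = stats.kruskal(*arrays)
    report = GroupComparison("kruskal_wallis", ns, float(res.statistic), float(res.pvalue))
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            sub = stats.ranksums(arrays[i], arrays[j])
            p = float(sub.pvalue)
            if correction == "bonferroni":
                p = min(1.0, p * n_pairs)
            report.posthoc.append(
                GroupComparison(
                    "wilcoxon_rank_sum", (ns[i], ns[j]), float(sub.statistic), p, pair=(i, j)
                )
            )
    return report
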