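"""Elevated O-maze and conditioned place preference scoring.

The elevated O-maze (EOM) test lasts 9 minutes, scored as open-arm time
percentage in three 3-minute blocks from frame-wise zone labels produced
by an upstream video tracker. Conditioned place preference (CPP) scores
are test-minus-pretest time in the drug-paired chamber of a two-chamber
(+ neutral zone) apparatus over 900-s sessions; group assignment for
conditioning is unbiased, balancing pretest chamber bias across groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZoneTrace",
    "CppTimes",
    "eom_block_times",
    "cpp_score",
    "cpp_assign_unbiased",
]

EOM_DURATION_S = 9 * 60
EOM_BLOCK_S = 3 * 60
CPP_SESSION_S = 900.0


@dataclass
class ZoneTrace:
    """Frame-wise zone labels for one EOM session."""

    fps: float
    zones: np.ndarray  # array of {"open", "closed"} strings
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones)
        bad = set(np.unique(self.zones)) - {"open", "closed"}
        if bad:
            raise ValueError(f"unknown zone labels: {sorted(bad)}")


@dataclass
class CppTimes:
    """Pretest and test chamber times (s) for one animal.

    ``pretest`` and ``test`` map chamber name -> seconds, covering the two
    pairing chambers plus the neutral zone; each session sums to 900 s up
    to frame quantization. ``paired`` names the drug-paired chamber.
    """

    pretest: dict[str, float]
    test: dict[str, float]
    paired: str

    def __post_init__(self) -> None:
        for name, times in (("pretest", self.pretest), ("test", self.test)):
            total = sum(times.values())
            if abs(total - CPP_SESSION_S) > 2.0:
                raise ValueError(f"{name} times sum to {total:.1f}s, expected {CPP_SESSION_S:.0f}s")
        if self.paired not in self.pretest or self.paired not in self.test:
            raise KeyError(f"paired chamber {self.paired!r} missing from session times")


def eom_block_times(trace: ZoneTrace) -> tuple[np.ndarray, bool]:
    """Open-arm time percentage in the three 3-minute blocks.

    Frames are attributed to blocks by half-open intervals on the frame
    timestamp (frame i occurs at i/fps seconds from maze placement), so
    the blocks are [0,180), [180,360), [360,540) s. Returns the three
    percentages and a flag that is True when the trace is short and the
    final block is partial (percentages are then computed over the frames
    present, not silently rescaled to a full block).
    """
    n = len(trace.zones)
    t = np.arange(n) / trace.fps
    expected = int(round(EOM_DURATION_S * trace.fps))
    partial = n < expected
    pct = np.full(3, np.nan)
    is_open = trace.zones == "open"
    for b in range(3):
        m = (t >= b * EOM_BLOCK_S) & (t < (b + 1) * EOM_BLOCK_S)
        if m.sum() > 0:
            pct[b] = 100.0 * is_open[m].sum() / m.sum()
    return pct, partial


def cpp_score(times: CppTimes) -> float:
    """CPP preference score in seconds.

    score = test time in the drug-paired chamber - pretest time in the
    same chamber. Positive scores indicate acquired preference for the
    paired chamber.
    """
    return float(times.test[times.paired] - times.pretest[times.paired])


def _two_group_exact(biases: np.ndarray) -> np.ndarray:
    """Exact balanced 2-partition minimizing |mean difference|.

    Meet-in-the-middle over the two halves of the index set; feasible up
    to ~22 animals. With equal group sizes, minimizing the group-mean
    difference is equivalent to minimizing |sum(group0) - total/2|.
    """
    n = len(biases)
    k = n // 2  # size of group 0 (group 1 gets the remainder)
    half1 = np.arange(n // 2)
    half2 = np.arange(n // 2, n)
    target = biases.sum() * k / n
    # enumerate subsets of each half grouped by size
    by_size2: dict[int, list[tuple[float, tuple[int, ...]]]] = {}
    for r in range(len(half2) + 1):
        by_size2[r] = sorted(
            (sum(biases[list(c)]), c) for c in itertools.combinations(half2, r)
        )
    best, best_sub = np.inf, None
    for r1 in range(len(half1) + 1):
        r2 = k - r1
        if r2 < 0 or r2 > len(half2):
            continue
        rows2 = by_size2[r2]
        sums2 = np.array([s for s, _ in rows2])
        for c1 in itertools.combinations(half1, r1):
            s1 = sum(biases[list(c1)])
            j = int(np.searchsorted(sums2, target - s1))
            for jj in (j - 1, j):
                if 0 <= jj < len(rows2):
                    gap = abs(s1 + rows2[jj][0] - target)
                    if gap < best - 1e-15:
                        best, best_sub = gap, tuple(c1) + rows2[jj][1]
    labels = np.ones(n, dtype=int)
    labels[list(best_sub)] = 0
    return labels


def _greedy_refine(biases: np.ndarray, n_groups: int) -> np.ndarray:
    """Greedy balanced assignment of sorted |bias| plus pairwise-swap
    refinement; used above the exact-search size limit."""
    n = len(biases)
    sizes = [n // n_groups + (1 if g < n % n_groups else 0) for g in range(n_groups)]
    order = np.argsort(-np.abs(biases))
    labels = np.full(n, -1, dtype=int)
    sums = np.zeros(n_groups)
    counts = [0] * n_groups
    for i in order:
        open_groups = [g for g in range(n_groups) if counts[g] < sizes[g]]
        g = min(open_groups, key=lambda g: abs(sums[g] + biases[i]))
        labels[i] = g
        sums[g] += biases[i]
        counts[g] += 1

    def spread() -> float:
        means = [sums[g] / counts[g] for g in range(n_groups)]
        return max(means) - min(means)

    improved = True
    while improved:
        improved = False
        for i in range(n):
            for j in range(i + 1, n):
                gi, gj = labels[i], labels[j]
                if gi == gj:
                    continue
                delta = biases[j] - biases[i]
                sums[gi] += delta
                sums[gj] -= delta
                old = labels[i], labels[j]
                labels[i], labels[j] = gj, gi
                # keep the swap only if it tightens the spread
                new_spread = spread()
                sums[gi] -= delta
                sums[gj] += delta
                labels[i], labels[j] = old
                if new_spread < spread() - 1e-12:
                    labels[i], labels[j] = gj, gi
                    sums[gi] += delta
                    sums[gj] -= delta
                    improved = True
    return labels


def cpp_assign_unbiased(
    pretest_scores: dict[str, float],
    n_groups: int = 2,
    pairing_chambers: tuple[str, str] = ("A", "B"),
) -> tuple[dict[str, int], dict[str, str], bool]:
    """Unbiased conditioning-group assignment from pretest biases.

    Partitions animals into ``n_groups`` balanced groups so that each
    group's mean pretest bias is as close as possible to the population
    mean (so that initial preference scores are near null in every
    group), then counterbalances the drug-paired chamber within each
    group by alternating assignment in bias order.

    For two groups and up to 22 animals the balanced partition minimizing
    the between-group mean difference is found exactly; larger problems
    (or more groups) use a deterministic greedy assignment with
    pairwise-swap refinement.

    Returns ``(group_of_animal, paired_chamber_of_animal, balanced)``
    where ``balanced`` is False when odd group sizes make exact chamber
    counterbalancing infeasible (best-effort alternation is still
    applied). Only labels are produced; no animal's data is altered.
    """
    animals = sorted(pretest_scores)
    if len(animals) < 2 * n_groups:
        raise ValueError("need at least 2 animals per group")
    biases = np.array([pretest_scores[a] for a in animals], float)
    if n_groups == 2 and len(animals) <= 22:
        labels = _two_group_exact(biases)
    else:
        labels = _greedy_refine(biases, n_groups)
    groups = {a: int(g) for a, g in zip(animals, labels)}
    paired: dict[str, str] = {}
    balanced = True
    for g in range(n_groups):
        members = sorted((a for a in animals if groups[a] == g), key=lambda a: pretest_scores[a])
        if len(members) % 2:
            balanced = False
        for i, a in enumerate(members):
            paired[a] = pairing_chambers[i % 2]
    return groups, paired, balanced
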