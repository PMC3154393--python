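"""Saturation and rarefaction analysis of phosphosite datasets.

Phosphoproteomics experiments never see every site in a sample; repeating an
experiment keeps revealing new ones.  These analyses quantify how close a
dataset is to exhausting what its workflow can see:

* :func:`replicate_saturation` — exact union-size curve over all subsets of
  technical replicates.
* :func:`pooled_rarefaction` — draw observations one at a time from the
  multiplicity-weighted pool, without replacement, tracking the number of
  unique sites discovered; a curve hugging the diagonal means every site was
  seen only once (no saturation), a curve bending above it means repeated
  sightings (approaching saturation).
* :func:`tail_novelty` — how much the last fraction of draws still adds.
* :func:`matched_unique_comparison` — are two pools differently saturated at
  matched sampling effort? (randomization test)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .io import PhosphoSite, SiteDataset

__all__ = [
    "ReplicateCurve",
    "SaturationCurve",
    "replicate_saturation",
    "pooled_rarefaction",
    "expected_unique",
    "tail_novelty",
    "matched_unique_comparison",
]


@dataclass
class ReplicateCurve:
    """Exact unique-site counts for every k-subset of R replicates.

    ``union_sizes[k]`` holds the union cardinality of each of the C(R, k)
    subsets of k replicates; ``means[k]`` their average.
    """

    n_replicates: int
    union_sizes: dict[int, list[int]]
    means: dict[int, float]

    @property
    def total_unique(self) -> int:
        return self.union_sizes[self.n_replicates][0]

    def to_rows(self) -> list[tuple[int, int]]:
        """(k, union size) rows, one per subset, for tabular output."""
        return [(k, u) for k in sorted(self.union_sizes) for u in self.union_sizes[k]]


@dataclass
class SaturationCurve:
    """Averaged rarefaction trajectory of a pooled dataset.

    ``x`` is the fraction of the observation pool drawn, ``y`` the fraction
    of unique sites discovered so far, averaged over ``n_repeats`` random
    draw orders.  Runs from (0, 0) to (1, 1).
    """

    x: np.ndarray
    y: np.ndarray
    n_repeats: int
    pool_size: int
    n_unique: int

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))

    def unique_at(self, fraction: float) -> float:
        """Mean unique-site count at a drawn fraction (linear interpolation)."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {fraction}")
        return float(np.interp(fraction, self.x, self.y)) * self.n_unique

    def to_rows(self) -> list[tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))


def replicate_saturation(replicates: Sequence[set[PhosphoSite]]) -> ReplicateCurve:
    """Union-size saturation over all subsets of replicate site sets.

    For each k = 1..R enumerates every k-subset of the R replicates and
    records the number of unique sites in its union — exact, no sampling.
    R is capped at 20 because the enumeration is exhaustive.
    """
    R = len(replicates)
    if R == 0:
        raise ValueError("need at least one replicate")
    if R > 20:
        raise ValueError(f"exhaustive subset enumeration capped at 20 replicates, got {R}")
    sets = [frozenset(s) for s in replicates]
    union_sizes: dict[int, list[int]] = {}
    means: dict[int, float] = {}
    for k in range(1, R + 1):
        sizes = [len(frozenset().union(*combo)) for combo in combinations(sets, k)]
        union_sizes[k] = sizes
        means[k] = sum(sizes) / len(sizes)
    return ReplicateCurve(R, union_sizes, means)


def _first_occurrence_curve(
    pool: np.ndarray, n_unique: int, eval_points: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unique-so-far counts at the given draw counts for one random order."""
    perm = rng.permutation(pool)
    # first position at which each site appears in this draw order
    _, first_idx = np.unique(perm, return_index=True)
    first_idx.sort()
    # unique count after k draws = number of first occurrences at index < k
    return np.searchsorted(first_idx, eval_points, side="left").astype(float)


def pooled_rarefaction(
    dataset: SiteDataset,
    n_repeats: int = 100,
    grid: int = 100,
    seed: int | np.random.Generator | None = None,
) -> SaturationCurve:
    """Rarefaction curve of a multiplicity-weighted observation pool.

    Each site contributes one pool entry per source reporting it.  Each
    repeat draws the whole pool in a fresh uniformly random order (i.e. a
    permutation — drawing *without* replacement until exhaustion) and records
    the number of distinct sites seen after each draw.  Curves are evaluated
    on a grid of ~``grid`` draw counts (every draw when the pool is small)
    and averaged across ``n_repeats`` orders.
    """
    if dataset.pool_size < 1:
        raise ValueError("dataset is empty")
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    N = dataset.pool_size
    mult = dataset.multiplicities()
    n_unique = len(mult)
    pool = np.repeat(np.arange(n_unique), list(mult.values()))

    step = max(1, math.ceil(N / grid))
    eval_points = np.arange(step, N + 1, step)
    if eval_points[-1] != N:
        eval_points = np.append(eval_points, N)

    acc = np.zeros(len(eval_points))
    for _ in range(n_repeats):
        acc += _first_occurrence_curve(pool, n_unique, eval_points, rng)
    mean_unique = acc / n_repeats

    x = np.concatenate([[0.0], eval_points / N])
    y = np.concatenate([[0.0], mean_unique / n_unique])
    return SaturationCurve(x=x, y=y, n_repeats=n_repeats, pool_size=N, n_unique=n_unique)


def expected_unique(multiplicities: Sequence[int], k: int) -> float:
    """Closed-form expected unique-site count after k pool draws.

    E[U(k)] = U - sum_s C(N - m_s, k) / C(N, k) for a pool of size
    N = sum(m_s): the probability that site s is still unseen after k draws
    without replacement is hypergeometric.
    """
    N = sum(multiplicities)
    if not 0 <= k <= N:
        raise ValueError(f"k must be in [0, {N}], got {k}")
    miss = sum(math.comb(N - m, k) / math.comb(N, k) for m in multiplicities)
    return len(multiplicities) - miss


def tail_novelty(
    source: SaturationCurve | SiteDataset,
    tail_fraction: float = 0.10,
    n_repeats: int = 100,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percent and absolute gain in unique sites over the final draws.

    Returns ``(percent_increase, new_sites)`` where
    ``percent_increase = 100 * (U(1) - U(1 - tail)) / U(1 - tail)`` on the
    averaged rarefaction curve.  Accepts either a precomputed curve (linear
    interpolation between grid points) or a dataset (exact evaluation at the
    two relevant draw counts).
    """
    if not 0.0 < tail_fraction < 1.0:
        raise ValueError(f"tail_fraction must be in (0, 1), got {tail_fraction}")
    if isinstance(source, SiteDataset):
        N = source.pool_size
        k_pre = round((1.0 - tail_fraction) * N)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        mult = source.multiplicities()
        pool = np.repeat(np.arange(len(mult)), list(mult.values()))
        pts = np.array([k_pre, N])
        acc = np.zeros(2)
        for _ in range(n_repeats):
            acc += _first_occurrence_curve(pool, len(mult), pts, rng)
        u_pre, u_full = acc / n_repeats
    else:
        u_pre = source.unique_at(1.0 - tail_fraction)
        u_full = source.unique_at(1.0)
    if u_pre == 0:
        raise ValueError("no unique sites before the tail; percent increase undefined")
    gain = u_full - u_pre
    return 100.0 * gain / u_pre, gain


def matched_unique_comparison(
    pool_a: SiteDataset,
    pool_b: SiteDataset,
    n_draws: int,
    n_trials: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Compare saturation of two pools at matched sampling effort.

    Draws ``n_draws`` observations without replacement from each pool,
    ``n_trials`` times, and counts unique sites.  Returns
    ``(mean_unique_a, mean_unique_b, p_value)`` where the p-value is the
    add-one randomization estimate of the probability that the comparison
    pool (b) yields as few unique sites as the focal pool (a) averages —
    i.e. that b looks as saturated as a.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    for name, pool in (("a", pool_a), ("b", pool_b)):
        if n_draws > pool.pool_size:
            raise ValueError(
                f"n_draws={n_draws} exceeds pool_{name} size {pool.pool_size}"
            )
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw_uniques(pool: SiteDataset) -> np.ndarray:
        mult = pool.multiplicities()
        arr = np.repeat(np.arange(len(mult)), list(mult.values()))
        out = np.empty(n_trials)
        for t in range(n_trials):
            sample = rng.choice(arr, size=n_draws, replace=False)
            out[t] = len(np.unique(sample))
        return out

    ua = draw_uniques(pool_a)
    ub = draw_uniques(pool_b)
    mean_a = float(ua.mean())
    mean_b = float(ub.mean())
    p = (1.0 + float(np.sum(ub <= mean_a))) / (1.0 + n_trials)
    return mean_a, mean_b, p
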