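"""Multi-run evaluation harness for the allocation algorithms.

The heuristic is cheap, so its practical use is "run many times, keep
the best".  This module reproduces that protocol: a *run* draws ``n``
independent seeded allocations and keeps the one with the highest
D-criterion; repeating runs shows the between-run variability of the
outcome.  Per-allocation seeds are derived from a master seed by a
counter-based scheme, so every allocation is individually reproducible
and runs are mutually independent.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .problem import AllocationProblem
from .rba import rba_allocate
from .sba import sba_allocate
from .scoring import ScoredAllocation

__all__ = [
    "ALGORITHMS",
    "allocation_seed",
    "best_of_n",
    "run_experiment",
    "run_until_stable",
    "ExperimentReport",
]

ALGORITHMS: dict[str, Callable[[AllocationProblem, int], ScoredAllocation]] = {
    "sba": sba_allocate,
    "rba": rba_allocate,
}


def allocation_seed(master_seed: int, index: int) -> int:
    """Derive the seed of allocation ``index`` from the master seed.

    Counter-based: hashes ``(master_seed, index)`` through a seed
    sequence, giving independent, individually reproducible streams.
    The result fits in 31 bits so it round-trips through any seed field.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _resolve(algorithm) -> Callable[[AllocationProblem, int], ScoredAllocation]:
    if callable(algorithm):
        return algorithm
    try:
        return ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {sorted(ALGORITHMS)}"
        ) from None


def best_of_n(
    problem: AllocationProblem,
    algorithm: str | Callable,
    n: int,
    seed: int,
    start_index: int = 0,
) -> ScoredAllocation:
    """Best of ``n`` independent allocations by D-criterion (ties keep the earliest).

    Allocation ``i`` uses the derived seed
    ``allocation_seed(seed, start_index + i)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    alloc = _resolve(algorithm)
    best: ScoredAllocation | None = None
    for i in range(n):
        cand = alloc(problem, allocation_seed(seed, start_index + i))
        if best is None or cand.d_score > best.d_score:
            best = cand
    return best


@dataclass
class ExperimentReport:
    """Scores from ``n_runs`` runs of ``n_alloc`` allocations each."""

    setting: str
    algorithm: str
    n_runs: int
    n_alloc: int
    seed: int
    scores: list[list[int]]
    run_bests: list[int]
    best_allocations: list[ScoredAllocation] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for run_scores, best in zip(self.scores, self.run_bests):
            if best != max(run_scores):
                raise ValueError("run best inconsistent with its run's scores")

    @property
    def all_scores(self) -> list[int]:
        return [s for run in self.scores for s in run]

    def fraction_at(self, reference: int) -> float:
        """Fraction of all allocations whose score equals ``reference``."""
        scores = self.all_scores
        return sum(1 for s in scores if s == reference) / len(scores)

    def fraction_runs_at_least(self, reference: int) -> float:
        """Fraction of runs whose best score is >= ``reference``."""
        return sum(1 for s in self.run_bests if s >= reference) / len(self.run_bests)

    @property
    def median_run_best(self) -> float:
        return statistics.median(self.run_bests)

    @property
    def n_confounded(self) -> int:
        return sum(1 for s in self.all_scores if s == 0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-allocation table: run, allocation index, seed, score."""
        rows = []
        for r, run_scores in enumerate(self.scores):
            for i, s in enumerate(run_scores):
                idx = r * self.n_alloc + i
                rows.append(
                    {
                        "setting": self.setting,
                        "algorithm": self.algorithm,
                        "run": r + 1,
                        "allocation": i + 1,
                        "seed": allocation_seed(self.seed, idx),
                        "d_score": s,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        """JSON-friendly summary with run-best quantiles."""
        bests = sorted(self.run_bests)
        q = lambda p: bests[min(len(bests) - 1, int(p * len(bests)))]
        return {
            "setting": self.setting,
            "algorithm": self.algorithm,
            "n_runs": self.n_runs,
            "n_alloc": self.n_alloc,
            "seed": self.seed,
            "n_confounded": self.n_confounded,
            "best_score": max(self.run_bests),
            "median_run_best": self.median_run_best,
            "run_best_quantiles": {
                "min": bests[0],
                "q25": q(0.25),
                "q75": q(0.75),
                "max": bests[-1],
            },
        }


def run_experiment(
    problem: AllocationProblem,
    algorithm: str | Callable,
    n_runs: int,
    n_alloc: int,
    seed: int,
    setting: str = "",
    keep_best_allocations: bool = False,
) -> ExperimentReport:
    """Run ``n_runs`` independent runs of ``n_alloc`` allocations each.

    Allocation ``i`` of run ``r`` uses the derived seed with counter
    ``r * n_alloc + i``, so the whole experiment is reproducible from
    ``seed`` and any allocation can be regenerated in isolation.
    """
    if n_runs < 1 or n_alloc < 1:
        raise ValueError("n_runs and n_alloc must be >= 1")
    alloc = _resolve(algorithm)
    name = algorithm if isinstance(algorithm, str) else getattr(algorithm, "__name__", "custom")
    scores: list[list[int]] = []
    run_bests: list[int] = []
    kept: list[ScoredAllocation] = []
    for r in range(n_runs):
        run_scores: list[int] = []
        best: ScoredAllocation | None = None
        for i in range(n_alloc):
            idx = r * n_alloc + i
            cand = alloc(problem, allocation_seed(seed, idx))
            run_scores.append(cand.d_score)
            if best is None or cand.d_score > best.d_score:
                best = cand
        scores.append(run_scores)
        run_bests.append(best.d_score)
        if keep_best_allocations:
            kept.append(best)
    return ExperimentReport(
        setting=setting,
        algorithm=name,
        n_runs=n_runs,
        n_alloc=n_alloc,
        seed=int(seed),
        scores=scores,
        run_bests=run_bests,
        best_allocations=kept if keep_best_allocations else None,
    )


def run_until_stable(
    problem: AllocationProblem,
    patience: int,
    seed: int,
    algorithm: str | Callable = "sba",
    trace: list[int] | None = None,
) -> ScoredAllocation:
    """Repeat allocations until ``patience`` consecutive non-improvements.

    The recommended stopping rule for problems too large to solve
    exhaustively: keep the incumbent best and stop once ``patience``
    successive allocations fail to beat it.  If ``trace`` is given, the
    incumbent score after each allocation is appended to it.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    alloc = _resolve(algorithm)
    incumbent = alloc(problem, allocation_seed(seed, 0))
    if trace is not None:
        trace.append(incumbent.d_score)
    streak = 0
    index = 1
    while streak < patience:
        cand = alloc(problem, allocation_seed(seed, index))
        index += 1
        if cand.d_score > incumbent.d_score:
            incumbent = cand
            streak = 0
        else:
            streak += 1
        if trace is not None:
            trace.append(incumbent.d_score)
    return incumbent
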