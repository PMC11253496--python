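"""Permutation approximation of the global-null distribution.

With only two analysis variables (the exposure pipeline and the binary
outcome), datasets mimicking the intersection null of all m strategy
hypotheses are obtained by randomly shuffling the *outcome* across
surgeries. Shuffling the outcome — rather than the exposure — leaves every
exposure-side stage untouched, which (a) preserves the dependence structure
between the m tests exactly and (b) lets one preprocessing pass serve all
permutations. One shared shuffle per permutation is applied to all
strategies jointly; strategies that drop surgeries see the shared permuted
outcome restricted to their own analysis set.
"""

from __future__ import annotations

from itertools import combinations
from dataclasses import dataclass
from math import comb

import numpy as np

from ._seeding import int_seed
from .dataset import SurgeryDataset
from .engine import GridEvaluator
from .errors import ConfigurationError, MinpverseError
from .grid import SpecificationGrid
from .adjust import PermutationNull

__all__ = [
    "PermutationPlan",
    "permute_outcome",
    "build_null",
    "exhaustive_relabeling_orderings",
]


@dataclass(frozen=True)
class PermutationPlan:
    """B outcome orderings (index permutations of 1..n), reproducible from
    (n, B, seed)."""

    orderings: np.ndarray  # (B, n) int
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.orderings)
        if arr.ndim != 2:
            raise ConfigurationError("orderings must be a (B, n) array")
        n = arr.shape[1]
        expect = np.arange(n)
        for b, row in enumerate(arr):
            if not np.array_equal(np.sort(row), expect):
                raise ConfigurationError(f"ordering {b} is not a bijection on 0..n-1")

    @property
    def B(self) -> int:
        return self.orderings.shape[0]

    @property
    def n(self) -> int:
        return self.orderings.shape[1]

    @classmethod
    def random(cls, n: int, B: int, seed: int | None = None) -> "PermutationPlan":
        if B < 1 or n < 1:
            raise ConfigurationError("need B >= 1 and n >= 1")
        rng = np.random.default_rng(seed)
        orderings = np.stack([rng.permutation(n) for _ in range(B)])
        return cls(orderings=orderings, seed=seed)


def exhaustive_relabeling_orderings(outcome: np.ndarray, limit: int = 200_000) -> np.ndarray:
    """One ordering per *distinct* relabeling of a binary outcome vector.

    For a 0/1 outcome with K ones among n there are C(n, K) distinct
    relabelings; shuffling beyond that only repeats them. Used to make the
    minP adjustment exact on toy problems.
    """
    outcome = np.asarray(outcome)
    if not np.isin(outcome, (0, 1)).all():
        raise ConfigurationError("exhaustive relabeling requires a 0/1 outcome")
    n = outcome.size
    ones = np.flatnonzero(outcome == 1)
    zeros = np.flatnonzero(outcome == 0)
    total = comb(n, len(ones))
    if total > limit:
        raise ConfigurationError(
            f"{total} distinct relabelings exceed the limit of {limit}"
        )
    orderings = np.empty((total, n), dtype=np.intp)
    for b, pos in enumerate(combinations(range(n), len(ones))):
        row = np.empty(n, dtype=np.intp)
        pos = np.array(pos, dtype=np.intp)
        rest = np.setdiff1d(np.arange(n), pos, assume_unique=True)
        row[pos] = ones  # these slots read original ones
        row[rest] = zeros
        orderings[b] = row
    return orderings


def permute_outcome(data: SurgeryDataset, ordering: np.ndarray) -> SurgeryDataset:
    """Reorder the outcome at surgery level; measurements stay untouched."""
    ordering = np.asarray(ordering)
    if ordering.shape != (data.n,):
        raise ConfigurationError(
            f"ordering has shape {ordering.shape}, expected ({data.n},)"
        )
    if not np.array_equal(np.sort(ordering), np.arange(data.n)):
        raise ConfigurationError("ordering is not a bijection on 0..n-1")
    return data.with_outcomes(data.outcome_vector[ordering])


def build_null(
    data: SurgeryDataset,
    grid: SpecificationGrid,
    B: int | None = None,
    seed: int = 0,
    *,
    orderings: np.ndarray | None = None,
    evaluator: GridEvaluator | None = None,
    cache: bool = True,
    max_failure_rate: float = 0.5,
) -> PermutationNull:
    """P-values of every strategy on B outcome-permuted datasets.

    The default (``cache=True``) reuses one outcome-blind preprocessing pass
    and re-runs only the coding + test stage per permutation; ``cache=False``
    re-executes the full grid on each permuted dataset (an order of magnitude
    slower, kept as the semantic reference). Both paths agree bitwise.

    ``orderings`` overrides the random plan (e.g. with
    :func:`exhaustive_relabeling_orderings`). A strategy that produced a raw
    p-value but fails on more than ``max_failure_rate`` of the permutations
    aborts the run with a diagnostic.
    """
    if orderings is None:
        if B is None or B < 1:
            raise ConfigurationError("need B >= 1 (or explicit orderings)")
        plan = PermutationPlan.random(data.n, B, seed=int_seed(seed, "permutation"))
    else:
        plan = PermutationPlan(orderings=np.asarray(orderings))

    if cache:
        ev = evaluator if evaluator is not None else GridEvaluator(data, grid, seed=seed)
        Y = ev.data.outcome_vector[plan.orderings]
        matrix, failures = ev.profiles_for_outcomes(Y)
        raw_failed = set(ev.raw_profile().failed)
    else:
        rows = []
        failures = [dict() for _ in grid.ids]
        for b in range(plan.B):
            profile = GridEvaluator(
                permute_outcome(data, plan.orderings[b]), grid, seed=seed
            ).raw_profile()
            rows.append(profile.p)
            for col, sid in enumerate(grid.ids):
                if sid in profile.failed:
                    failures[col][b] = profile.failed[sid]
        matrix = np.stack(rows)
        raw_failed = set(GridEvaluator(data, grid, seed=seed).raw_profile().failed)

    for col, sid in enumerate(grid.ids):
        if sid in raw_failed:
            continue  # failed outright; excluded from the family anyway
        rate = len(failures[col]) / plan.B
        if rate > max_failure_rate:
            example = next(iter(failures[col].values()))
            raise MinpverseError(
                f"strategy {sid!r} failed on {rate:.0%} of permutations "
                f"(e.g. {example}); the permutation null is unreliable"
            )
    return PermutationNull(matrix=matrix, strategy_ids=grid.ids, seed=seed)
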