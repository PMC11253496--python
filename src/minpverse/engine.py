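"""Execution of a specification grid on one dataset.

The 48 canonical strategies share only 16 distinct preprocessing paths
(missing-handling x surrogate x tuning x aggregation) and, within those,
only 8 distinct surrogate fits. :class:`GridEvaluator` computes each shared
stage exactly once and keys its randomness by the axis values involved, so
cached execution is bitwise-identical to running every strategy on its own.

Because no preprocessing stage reads the outcome, the evaluator can also
produce an entire permutation-null matrix by re-running only the coding +
test stage on permuted outcome vectors (see
:meth:`GridEvaluator.profiles_for_outcomes`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import assoc
from ._seeding import int_seed
from .dataset import PValueProfile, SurgeryDataset
from .errors import DegenerateDataError, StrategyFailedError
from .grid import SpecificationGrid, StrategySpec
from .pipeline import (
    aggregate_exposure,
    fit_surrogate,
    handle_missing,
    predict_exposure,
)

__all__ = ["GridEvaluator", "run_grid", "run_strategy"]


@dataclass
class _Exposure:
    """An exposure vector together with the positions (into the full
    surgery order) of the surgeries it retains."""

    values: np.ndarray
    keep: np.ndarray  # positions into data.surgery_ids
    excluded: tuple


class GridEvaluator:
    """One dataset + one grid, preprocessed once, testable many times.

    Parameters
    ----------
    data, grid:
        The dataset and the declared strategy set.
    seed:
        Master seed; every stochastic stage derives its own stream from it
        and the axis values it depends on.
    cutoffs:
        Clinical cut points (mmHg) for the binary and ternary codings.
    """

    def __init__(
        self,
        data: SurgeryDataset,
        grid: SpecificationGrid,
        seed: int = 0,
        cutoffs: tuple[float, float] = (200.0, 250.0),
    ) -> None:
        self.data = data
        self.grid = grid
        self.seed = int(seed)
        self.cutoffs = cutoffs
        self._exposures: dict[tuple, _Exposure] = {}
        self._preproc_failures: dict[tuple, str] = {}
        self._prepare()

    # -- preprocessing (outcome-blind) ------------------------------------

    def _prepare(self) -> None:
        data, seed = self.data, self.seed
        id_order = {sid: pos for pos, sid in enumerate(data.surgery_ids)}

        handled: dict[str, SurgeryDataset | str] = {}
        for mode in {s.missing_handling for s in self.grid}:
            try:
                handled[mode] = handle_missing(
                    data, mode, seed=int_seed(seed, "missing", mode)
                )
            except DegenerateDataError as err:
                handled[mode] = str(err)

        filled: dict[tuple, object] = {}
        for key in {
            (s.missing_handling, s.surrogate_model, s.tuning) for s in self.grid
        }:
            mode, surrogate, tuning = key
            base = handled[mode]
            if isinstance(base, str):
                filled[key] = f"missing-handling failed: {base}"
                continue
            train = base.measurements["pao2"].notna()
            try:
                fit = fit_surrogate(
                    base.measurements.loc[train, list(base.proxy_columns)],
                    base.measurements.loc[train, "pao2"].to_numpy(),
                    model_kind=surrogate,
                    tuning=tuning,
                    seed=int_seed(seed, "fit", mode, surrogate, tuning),
                )
                filled[key] = predict_exposure(fit, base)
            except (DegenerateDataError, StrategyFailedError) as err:
                filled[key] = f"surrogate stage failed: {err}"

        for pkey in {s.preprocessing_key for s in self.grid}:
            mode, surrogate, tuning, aggregation = pkey
            frame = filled[(mode, surrogate, tuning)]
            if isinstance(frame, str):
                self._preproc_failures[pkey] = frame
                continue
            try:
                exposure = aggregate_exposure(frame, aggregation)
            except DegenerateDataError as err:
                self._preproc_failures[pkey] = f"aggregation failed: {err}"
                continue
            kept_ids = exposure.values.index.to_numpy()
            kept_set = set(kept_ids)
            keep = np.array([id_order[sid] for sid in kept_ids], dtype=np.intp)
            excluded = tuple(sid for sid in data.surgery_ids if sid not in kept_set)
            self._exposures[pkey] = _Exposure(
                values=exposure.values.to_numpy(float), keep=keep, excluded=excluded
            )

    def exposure_for(self, spec: StrategySpec) -> _Exposure:
        """The cached exposure vector behind one strategy (testing hook)."""
        key = spec.preprocessing_key
        if key in self._preproc_failures:
            raise StrategyFailedError(self._preproc_failures[key])
        return self._exposures[key]

    # -- testing -----------------------------------------------------------

    def profiles_for_outcomes(
        self, outcomes: np.ndarray
    ) -> tuple[np.ndarray, list[dict[int, str]]]:
        """P-value matrix for many outcome vectors at once.

        ``outcomes`` has shape (B, n) aligned to ``data.surgery_ids``; the
        result has shape (B, m) in grid order with NaN for failures, plus
        one {row index -> reason} dict per strategy.
        """
        outcomes = np.asarray(outcomes)
        if outcomes.ndim != 2 or outcomes.shape[1] != self.data.n:
            raise ValueError(
                f"outcome matrix shape {outcomes.shape} does not match "
                f"n = {self.data.n}"
            )
        B = outcomes.shape[0]
        matrix = np.full((B, self.grid.m), np.nan)
        failures: list[dict[int, str]] = []
        sub_cache: dict[tuple, np.ndarray] = {}
        for col, spec in enumerate(self.grid):
            pkey = spec.preprocessing_key
            if pkey in self._preproc_failures:
                failures.append(
                    dict.fromkeys(range(B), self._preproc_failures[pkey])
                )
                continue
            exp = self._exposures[pkey]
            if pkey not in sub_cache:
                sub_cache[pkey] = np.ascontiguousarray(outcomes[:, exp.keep])
            p, fail = assoc.batch_pvalues(
                spec.exposure_coding_and_test,
                exp.values,
                sub_cache[pkey],
                cutoffs=self.cutoffs,
            )
            matrix[:, col] = p
            failures.append(fail)
        return matrix, failures

    def raw_profile(self) -> PValueProfile:
        """The m raw p-values of the grid on the dataset's true outcomes."""
        matrix, failures = self.profiles_for_outcomes(
            self.data.outcome_vector[None, :]
        )
        failed = {
            spec.id: fail[0]
            for spec, fail in zip(self.grid, failures)
            if 0 in fail
        }
        return PValueProfile(
            p=matrix[0], strategy_ids=self.grid.ids, failed=failed
        )


def run_grid(
    data: SurgeryDataset, grid: SpecificationGrid, seed: int = 0
) -> PValueProfile:
    """Run every strategy of ``grid`` on ``data``; pure in (data, grid, seed)."""
    return GridEvaluator(data, grid, seed=seed).raw_profile()


def run_strategy(data: SurgeryDataset, spec: StrategySpec, seed: int = 0) -> float:
    """Run a single strategy end to end and return its two-sided p-value.

    Raises :class:`StrategyFailedError` on degenerate input rather than
    returning a silent p-value. Identical (data, spec, seed) give an
    identical p-value, and the result equals the corresponding entry of
    :func:`run_grid` for any grid containing ``spec``.
    """
    profile = run_grid(data, SpecificationGrid((spec,)), seed=seed)
    if spec.id in profile.failed:
        raise StrategyFailedError(profile.failed[spec.id])
    return float(profile.p[0])
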