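"""Multiplicity adjustment of the strategy p-value profile.

A researcher who runs m analysis strategies and reports the smallest
p-value p_(1) is implicitly performing m tests. Three corrections are
offered:

* **minP** (recommended): p~_i is the probability, under the global null,
  that the *minimal* p-value over all m strategies is <= p_i. The global
  null is approximated by outcome permutation, so p~_i becomes the
  proportion of permutations whose minimal p-value is lower than or equal
  to p_i (ties count). Because the permutation distribution inherits the
  full dependence between strategies, minP is far less conservative than
  Bonferroni when the strategies largely agree, while still controlling the
  family-wise error rate in the weak sense.
* **Bonferroni**: p~_i = min(m p_i, 1); strong FWER control, ignores
  dependence.
* **Holm**: the standard step-down refinement. Included for completeness;
  for the smallest p-value it coincides exactly with Bonferroni, so it buys
  nothing when interest focuses on p_(1) — the report says so.

Failed strategies carry NaN and are excluded throughout; adjustments are
computed over the effective family (the strategies that produced p-values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataset import PValueProfile
from .errors import AlignmentError, ConfigurationError, DegenerateDataError
from .grid import SpecificationGrid

__all__ = [
    "PermutationNull",
    "AdjustmentResult",
    "adjust_minp",
    "adjust_bonferroni",
    "adjust_holm",
    "select_and_report",
    "Report",
]

METHOD_LABELS = {"minp": "minP", "bonferroni": "Bonferroni", "holm": "Holm"}


@dataclass
class PermutationNull:
    """B x m matrix of p-values from outcome-permuted datasets.

    Row b is the p-value profile of the b-th permuted dataset; the
    distribution of the per-row minima approximates the null distribution
    of the minimal p-value. NaN marks per-permutation strategy failures.
    """

    matrix: np.ndarray
    strategy_ids: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ConfigurationError("permutation matrix must be 2-D (B x m)")
        if self.matrix.shape[0] < 1:
            raise ConfigurationError("need at least one permutation (B >= 1)")
        if self.matrix.shape[1] != len(self.strategy_ids):
            raise AlignmentError(
                "permutation matrix columns do not match the strategy list"
            )
        ok = ~np.isnan(self.matrix)
        if np.any((self.matrix[ok] < 0) | (self.matrix[ok] > 1)):
            raise ConfigurationError("permutation p-values must lie in [0, 1]")

    @property
    def B(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def row_minima(self) -> np.ndarray:
        """Per-permutation minimal p-value over the non-failed strategies."""
        out = np.full(self.B, np.nan)
        valid = ~np.all(np.isnan(self.matrix), axis=1)
        out[valid] = np.nanmin(self.matrix[valid], axis=1)
        return out

    # -- persistence (CSV matrix + JSON sidecar) --------------------------

    def save(self, matrix_path: str | Path, sidecar_path: str | Path) -> None:
        pd.DataFrame(self.matrix, columns=list(self.strategy_ids)).to_csv(
            matrix_path, index=False
        )
        Path(sidecar_path).write_text(
            json.dumps(
                {
                    "B": self.B,
                    "seed": self.seed,
                    "strategy_ids": list(self.strategy_ids),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, matrix_path: str | Path, sidecar_path: str | Path) -> "PermutationNull":
        meta = json.loads(Path(sidecar_path).read_text())
        frame = pd.read_csv(matrix_path)
        if list(frame.columns) != list(meta["strategy_ids"]):
            raise AlignmentError("matrix columns disagree with the sidecar")
        return cls(
            matrix=frame.to_numpy(float),
            strategy_ids=tuple(meta["strategy_ids"]),
            seed=meta.get("seed"),
        )


@dataclass
class AdjustmentResult:
    """Adjusted p-values for one method, aligned to the raw profile."""

    raw: PValueProfile
    adjusted: np.ndarray
    method: str
    alpha: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjusted = np.asarray(self.adjusted, dtype=float)
        if self.adjusted.shape != self.raw.p.shape:
            raise AlignmentError("adjusted vector does not match the raw profile")

    @property
    def selected_index(self) -> int:
        """Index of the strategy with the smallest raw p-value (the one a
        selective reporter would publish)."""
        return self.raw.argmin

    @property
    def selected_raw(self) -> float:
        return self.raw.min_p

    @property
    def selected_adjusted(self) -> float:
        return float(self.adjusted[self.selected_index])

    @property
    def m_effective(self) -> int:
        return self.raw.m_effective

    def to_frame(self, grid: SpecificationGrid | None = None) -> pd.DataFrame:
        frame = self.raw.to_frame(grid)
        frame[f"p_{self.method}"] = self.adjusted
        return frame


def adjust_minp(
    raw: PValueProfile, null: PermutationNull, *, smoothed: bool = False
) -> AdjustmentResult:
    """Single-step minP adjustment from a permutation null.

    p~_i = #{b : min_l p_{b,l} <= p_i} / B. ``smoothed=True`` switches to
    the validity-preserving (count + 1) / (B + 1) variant that can never
    return an adjusted p-value of exactly zero.
    """
    if null.m != raw.m or null.strategy_ids != raw.strategy_ids:
        raise AlignmentError(
            "permutation null and raw profile disagree on the strategy set"
        )
    minima = null.row_minima
    minima = minima[~np.isnan(minima)]
    B = len(minima)
    if B == 0:
        raise DegenerateDataError("every permutation failed; no null distribution")
    sorted_minima = np.sort(minima)
    counts = np.searchsorted(sorted_minima, raw.p, side="right").astype(float)
    if smoothed:
        adjusted = (counts + 1.0) / (B + 1.0)
    else:
        adjusted = counts / B
    adjusted[np.isnan(raw.p)] = np.nan
    return AdjustmentResult(
        raw=raw, adjusted=adjusted, method="minp", extra={"B": B, "smoothed": smoothed}
    )


def adjust_bonferroni(raw: PValueProfile) -> AdjustmentResult:
    """p~_i = min(m_eff * p_i, 1) over the effective family."""
    m_eff = raw.m_effective
    if m_eff == 0:
        raise DegenerateDataError("all strategies failed; nothing to adjust")
    adjusted = np.minimum(raw.p * m_eff, 1.0)
    return AdjustmentResult(raw=raw, adjusted=adjusted, method="bonferroni")


def adjust_holm(raw: PValueProfile) -> AdjustmentResult:
    """Step-down Holm adjustment; its smallest adjusted p-value always
    equals Bonferroni's."""
    ok = ~np.isnan(raw.p)
    if not ok.any():
        raise DegenerateDataError("all strategies failed; nothing to adjust")
    adjusted = np.full(raw.m, np.nan)
    adjusted[ok] = multipletests(raw.p[ok], method="holm")[1]
    return AdjustmentResult(raw=raw, adjusted=adjusted, method="holm")


@dataclass
class Report:
    """The selective-reporting summary: what the winning strategy's p-value
    looks like before and after each multiplicity adjustment."""

    strategy_id: str
    axes: dict
    hypothesis_text: str
    raw_min: float
    alpha: float
    m: int
    m_effective: int
    adjusted_min: dict  # method -> adjusted p_(1)
    significant: dict  # method -> bool at alpha
    failed: dict  # strategy id -> reason

    def to_dict(self) -> dict:
        return {
            "selected_strategy": self.strategy_id,
            "axes": self.axes,
            "hypothesis": self.hypothesis_text,
            "raw_min_p": self.raw_min,
            "alpha": self.alpha,
            "m": self.m,
            "m_effective": self.m_effective,
            "adjusted_min_p": self.adjusted_min,
            "significant_at_alpha": self.significant,
            "failed_strategies": self.failed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [
            f"Smallest raw p-value: {self.raw_min:.4g} "
            f"(strategy {self.strategy_id!r}, "
            f"{self.m_effective}/{self.m} strategies produced p-values)",
            f"  {self.hypothesis_text}" if self.hypothesis_text else "",
            f"Significance level alpha = {self.alpha:g}",
        ]
        for method, value in self.adjusted_min.items():
            verdict = "significant" if self.significant[method] else "not significant"
            lines.append(
                f"  {METHOD_LABELS.get(method, method):>10}-adjusted p_(1) = "
                f"{value:.4g} -> {verdict}"
            )
        if {"holm", "bonferroni"} <= set(self.adjusted_min):
            lines.append(
                "  (Holm necessarily agrees with Bonferroni on the smallest "
                "p-value, so it adds no power for selective reporting.)"
            )
        if self.failed:
            lines.append(f"  Failed strategies: {len(self.failed)}")
        return "\n".join(line for line in lines if line)


def select_and_report(
    results: list[AdjustmentResult],
    grid: SpecificationGrid,
    alpha: float = 0.05,
) -> Report:
    """Combine per-method adjustments into the final selective report.

    All results must share the same raw profile. Significance follows the
    adjusted-p-value convention: reject iff p~ <= alpha (an adjusted
    p-value is the smallest level at which its test rejects).
    """
    if not results:
        raise ConfigurationError("need at least one adjustment result")
    raw = results[0].raw
    for res in results[1:]:
        if res.raw.strategy_ids != raw.strategy_ids or not np.array_equal(
            res.raw.p, raw.p, equal_nan=True
        ):
            raise AlignmentError("adjustment results come from different profiles")
    if raw.m_effective == 0:
        raise DegenerateDataError("all strategies failed; nothing to report")
    idx = raw.argmin
    spec = grid[idx]
    if spec.id != raw.strategy_ids[idx]:
        raise AlignmentError("grid does not match the profile's strategy order")
    adjusted_min = {r.method: float(r.adjusted[idx]) for r in results}
    significant = {m: bool(v <= alpha) for m, v in adjusted_min.items()}
    return Report(
        strategy_id=spec.id,
        axes=dict(zip(("missing_handling", "surrogate_model", "tuning",
                       "aggregation", "exposure_coding_and_test"), spec.axis_values)),
        hypothesis_text=spec.hypothesis_text,
        raw_min=raw.min_p,
        alpha=alpha,
        m=raw.m,
        m_effective=raw.m_effective,
        adjusted_min=adjusted_min,
        significant=significant,
        failed=dict(raw.failed),
    )
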