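"""Per-surgery dataset container and the raw p-value profile.

A :class:`SurgeryDataset` holds intra-operative measurements (one row per
timepoint: proxy vitals measured continuously, paO2 in mmHg observed only on
a sparse subset of timepoints) and one binary post-operative complication
outcome per surgery. The on-disk form is two CSV files with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MEASUREMENT_BASE_COLUMNS = ("surgery_id", "time", "pao2")
OUTCOME_COLUMNS = ("surgery_id", "outcome")


@dataclass
class SurgeryDataset:
    """Timestamped measurements plus one binary outcome per surgery.

    ``measurements`` columns: ``surgery_id``, ``time``, ``pao2`` (NaN where
    paO2 was not measured at that timepoint) and one or more ``proxy_*``
    columns (may contain NaN = missing proxy reading). ``outcomes`` columns:
    ``surgery_id``, ``outcome`` (0/1). Rows are kept in canonical order
    (sorted by surgery id, then time) so array views align across modules.
    """

    measurements: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        meas, out = self.measurements, self.outcomes
        for col in MEASUREMENT_BASE_COLUMNS:
            if col not in meas.columns:
                raise ConfigurationError(f"measurements lack column {col!r}")
        for col in OUTCOME_COLUMNS:
            if col not in out.columns:
                raise ConfigurationError(f"outcomes lack column {col!r}")
        if not self.proxy_columns:
            raise ConfigurationError("measurements need >=1 proxy_* column")
        if out["surgery_id"].duplicated().any():
            raise ConfigurationError("duplicate surgery_id in outcomes")
        if len(out) < 1:
            raise ConfigurationError("need at least one surgery")
        vals = out["outcome"].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ConfigurationError("outcome must be binary 0/1")
        pao2 = meas["pao2"].to_numpy(float)
        if np.any(pao2[~np.isnan(pao2)] <= 0):
            raise ConfigurationError("observed paO2 values must be positive")
        unknown = set(meas["surgery_id"]) - set(out["surgery_id"])
        if unknown:
            raise ConfigurationError(
                f"measurements reference surgeries without an outcome: "
                f"{sorted(unknown)[:5]}..."
            )
        # canonical ordering
        self.outcomes = out.sort_values("surgery_id", kind="stable").reset_index(
            drop=True
        )
        self.measurements = meas.sort_values(
            ["surgery_id", "time"], kind="stable"
        ).reset_index(drop=True)

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def surgery_ids(self) -> np.ndarray:
        return self.outcomes["surgery_id"].to_numpy()

    @property
    def proxy_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.measurements.columns if c.startswith("proxy_"))

    @property
    def k(self) -> int:
        return len(self.proxy_columns)

    @property
    def outcome_vector(self) -> np.ndarray:
        """Outcomes as int8, aligned to :attr:`surgery_ids` order."""
        return self.outcomes["outcome"].to_numpy(np.int8)

    def with_outcomes(self, values: np.ndarray) -> "SurgeryDataset":
        """A copy of the dataset with the outcome column replaced
        (measurements shared, not copied)."""
        values = np.asarray(values)
        if values.shape != (self.n,):
            raise ConfigurationError(
                f"outcome vector has shape {values.shape}, expected ({self.n},)"
            )
        out = self.outcomes.copy()
        out["outcome"] = values.astype(np.int8)
        return replace(self, outcomes=out)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, measurements_path: str | Path, outcomes_path: str | Path) -> None:
        self.measurements.to_csv(measurements_path, index=False)
        self.outcomes.to_csv(outcomes_path, index=False)

    @classmethod
    def from_csv(
        cls, measurements_path: str | Path, outcomes_path: str | Path
    ) -> "SurgeryDataset":
        return cls(
            measurements=pd.read_csv(measurements_path),
            outcomes=pd.read_csv(outcomes_path),
        )


@dataclass
class PValueProfile:
    """The m raw p-values produced by one run of a grid on one dataset.

    ``p`` is aligned to grid order; a strategy whose test could not be
    computed carries NaN in ``p`` and an entry in ``failed`` (id -> reason).
    """

    p: np.ndarray
    strategy_ids: tuple[str, ...]
    failed: dict[str, str]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.strategy_ids),):
            raise ConfigurationError(
                "p-value vector length does not match the strategy list"
            )
        ok = ~np.isnan(self.p)
        if np.any((self.p[ok] < 0) | (self.p[ok] > 1)):
            raise ConfigurationError("p-values must lie in [0, 1]")
        for sid in self.failed:
            if sid not in self.strategy_ids:
                raise ConfigurationError(f"failure flag for unknown id {sid!r}")

    @property
    def m(self) -> int:
        return len(self.strategy_ids)

    @property
    def m_effective(self) -> int:
        """Number of strategies that produced a p-value."""
        return int((~np.isnan(self.p)).sum())

    @property
    def min_p(self) -> float:
        if self.m_effective == 0:
            return float("nan")
        return float(np.nanmin(self.p))

    @property
    def argmin(self) -> int:
        if self.m_effective == 0:
            raise ConfigurationError("all strategies failed; no minimum")
        return int(np.nanargmin(self.p))

    def to_frame(self, grid=None) -> pd.DataFrame:
        """Tidy export: strategy id (plus axes when a grid is given) and raw p."""
        frame = pd.DataFrame({"strategy_id": list(self.strategy_ids)})
        if grid is not None:
            axes = grid.to_frame()
            if tuple(axes["strategy_id"]) != self.strategy_ids:
                from .errors import AlignmentError

                raise AlignmentError("profile and grid disagree on strategy order")
            frame = axes
        frame["p"] = self.p
        frame["failed"] = [self.failed.get(sid, "") for sid in self.strategy_ids]
        return frame
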