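"""Analysis strategies and the specification grid.

A *strategy* is one complete path through the analyst's decision tree for the
paO2 / post-operative-complication question: how to handle missing proxy
values, which surrogate model predicts unobserved paO2, whether its
hyperparameters are tuned, how per-surgery measurements are aggregated, and
how the aggregated exposure is coded and tested against the binary outcome.
The *grid* is the full declared set of m strategies; with the two options per
preprocessing axis and three coding/test options this yields the canonical
2 x 2 x 2 x 2 x 3 = 48 specifications.

Grid order is deterministic and documented: axes are nested in the order
``missing_handling, surrogate_model, tuning, aggregation,
exposure_coding_and_test`` with the rightmost axis varying fastest, so column
``l`` of any permutation-null matrix always refers to the same strategy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError

#: Canonical axes, in nesting order, with their declared options.
AXES: dict[str, tuple[str, ...]] = {
    "missing_handling": ("drop", "impute"),
    "surrogate_model": ("random_forest", "regularized_glm"),
    "tuning": ("default", "random_search"),
    "aggregation": ("mean", "median"),
    "exposure_coding_and_test": (
        "continuous_logistic",
        "binary_200_fisher",
        "ternary_200_250_fisher",
    ),
}

AXIS_NAMES = tuple(AXES)

_SHORT = {
    "drop": "drop",
    "impute": "imp",
    "random_forest": "rf",
    "regularized_glm": "glm",
    "default": "def",
    "random_search": "rs",
    "mean": "mean",
    "median": "med",
    "continuous_logistic": "logit",
    "binary_200_fisher": "f200",
    "ternary_200_250_fisher": "f200.250",
}

_CODING_TEXT = {
    "continuous_logistic": (
        "the aggregated paO2 (continuous) has no effect on the odds of a "
        "post-operative complication (logistic regression, Wald test)"
    ),
    "binary_200_fisher": (
        "complication rates are equal below and above 200 mmHg aggregated "
        "paO2 (Fisher's exact test)"
    ),
    "ternary_200_250_fisher": (
        "complication rates are equal across the <200, 200-250 and >=250 "
        "mmHg aggregated paO2 categories (Freeman-Halton exact test)"
    ),
}


@dataclass(frozen=True)
class StrategySpec:
    """One analysis strategy: a value on each of the five decision axes."""

    id: str
    missing_handling: str
    surrogate_model: str
    tuning: str
    aggregation: str
    exposure_coding_and_test: str
    hypothesis_text: str = ""

    def __post_init__(self) -> None:
        for axis in AXIS_NAMES:
            value = getattr(self, axis)
            if value not in AXES[axis]:
                raise ConfigurationError(
                    f"unknown option {value!r} for axis {axis!r}; "
                    f"expected one of {AXES[axis]}"
                )
        if not self.id:
            raise ConfigurationError("strategy id must be a non-empty string")

    @property
    def axis_values(self) -> tuple[str, ...]:
        return tuple(getattr(self, axis) for axis in AXIS_NAMES)

    @property
    def preprocessing_key(self) -> tuple[str, str, str, str]:
        """The axes that determine the exposure vector (everything except
        the coding/test choice)."""
        return (
            self.missing_handling,
            self.surrogate_model,
            self.tuning,
            self.aggregation,
        )


def _default_id(values: Sequence[str]) -> str:
    return "-".join(_SHORT[v] for v in values)


def _default_hypothesis(values: Sequence[str]) -> str:
    mh, sm, tu, ag, coding = values
    return (
        f"H0: {_CODING_TEXT[coding]}; exposure built with "
        f"{mh} missing-value handling, {sm.replace('_', ' ')} surrogate "
        f"({tu.replace('_', ' ')} hyperparameters), {ag} aggregation."
    )


@dataclass(frozen=True)
class SpecificationGrid:
    """An ordered, immutable collection of strategies with unique ids."""

    strategies: tuple[StrategySpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.strategies) < 1:
            raise ConfigurationError("a grid needs at least one strategy")
        ids = [s.id for s in self.strategies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate strategy ids: {dup}")

    @property
    def m(self) -> int:
        return len(self.strategies)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.strategies)

    def __len__(self) -> int:
        return len(self.strategies)

    def __iter__(self) -> Iterator[StrategySpec]:
        return iter(self.strategies)

    def __getitem__(self, i: int) -> StrategySpec:
        return self.strategies[i]

    def index_of(self, strategy_id: str) -> int:
        try:
            return self.ids.index(strategy_id)
        except ValueError:
            raise KeyError(strategy_id) from None

    def to_frame(self) -> pd.DataFrame:
        """One row per strategy, in grid order, with id and axis columns."""
        return pd.DataFrame(
            [
                {"strategy_id": s.id, **dict(zip(AXIS_NAMES, s.axis_values))}
                for s in self.strategies
            ]
        )


def enumerate_grid(
    axes: Mapping[str, Sequence[str]] | None = None,
) -> SpecificationGrid:
    """Cross all axis options into a grid, rightmost axis fastest.

    ``axes`` maps axis names to the option subset to use; omitted axes get
    all canonical options. Unknown axis or option names raise
    :class:`ConfigurationError` naming the offender.
    """
    axes = dict(axes or {})
    for name in axes:
        if name not in AXES:
            raise ConfigurationError(
                f"unknown axis {name!r}; expected one of {AXIS_NAMES}"
            )
    chosen: list[tuple[str, ...]] = []
    for name in AXIS_NAMES:
        options = tuple(axes.get(name, AXES[name]))
        if len(options) < 1:
            raise ConfigurationError(f"axis {name!r} has no options")
        for opt in options:
            if opt not in AXES[name]:
                raise ConfigurationError(
                    f"unknown option {opt!r} for axis {name!r}; "
                    f"expected a subset of {AXES[name]}"
                )
        if len(set(options)) != len(options):
            raise ConfigurationError(f"axis {name!r} lists duplicate options")
        chosen.append(options)

    strategies = tuple(
        StrategySpec(
            id=_default_id(values),
            **dict(zip(AXIS_NAMES, values)),
            hypothesis_text=_default_hypothesis(values),
        )
        for values in itertools.product(*chosen)
    )
    return SpecificationGrid(strategies)


def default_grid() -> SpecificationGrid:
    """The full 48-strategy grid (2 x 2 x 2 x 2 x 3)."""
    return enumerate_grid()
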