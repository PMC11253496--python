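"""Pipeline stages realizing the preprocessing axes of the decision tree.

Stage order for every strategy: missing-value handling -> surrogate-model
fit on the timepoints with observed paO2 -> paO2 prediction at all
timepoints (observed values always take precedence) -> per-surgery
aggregation. The coding + test stage lives in :mod:`minpverse.assoc`.

None of these stages ever reads the outcome. That is deliberate: it keeps
the exposure side of every strategy invariant under outcome permutation,
which is what allows the permutation engine to reuse one preprocessing pass
across all permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import ElasticNet
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .dataset import SurgeryDataset
from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "PAO2_CLAMP",
    "SurrogateModelFit",
    "ExposureVector",
    "handle_missing",
    "fit_surrogate",
    "predict_exposure",
    "aggregate_exposure",
]

#: range (mmHg) to which surrogate predictions are clamped so that degenerate
#: extrapolations cannot produce non-physiological exposure codings
PAO2_CLAMP = (20.0, 600.0)

MIN_TRAIN_ROWS = 30
MIN_SURGERIES_AFTER_DROP = 10

#: random-search budget: the default configuration plus 9 random candidates,
#: scored by RMSE on a 25% holdout
N_SEARCH_CANDIDATES = 10
HOLDOUT_FRACTION = 0.25

RF_DEFAULTS = {"n_estimators": 100, "feature_fraction": 1.0, "min_child_samples": 5}
GLM_DEFAULTS = {"alpha": 1.0, "l1_ratio": 0.5}

#: random-search spaces (trees uniform int, penalty log-uniform, rest uniform)
RF_SPACE = {
    "n_estimators": (50, 200),
    "feature_fraction": (0.2, 1.0),
    "min_child_samples": (1, 20),
}
GLM_SPACE = {"alpha": (1e-4, 1e2), "l1_ratio": (0.0, 1.0)}


def handle_missing(
    data: SurgeryDataset, mode: str, seed: int | None = None
) -> SurgeryDataset:
    """Resolve missing proxy readings by dropping rows or imputing them.

    ``drop`` removes every measurement row with any missing proxy value
    (surgeries left without rows disappear from the analysis set; fewer
    than MIN_SURGERIES_AFTER_DROP remaining is an error). ``impute`` fills
    missing proxy entries with a chained-equations regression imputation
    (each proxy regressed on the others, iterated); the outcome and paO2
    columns are excluded from the imputation model, so the completed data
    are identical for the original and any outcome-permuted dataset.
    Complete data pass through unchanged in both modes.
    """
    if mode not in ("drop", "impute"):
        raise ConfigurationError(f"unknown missing-handling mode {mode!r}")
    proxies = data.measurements[list(data.proxy_columns)]
    incomplete = proxies.isna().any(axis=1)
    if not incomplete.any():
        return data

    if mode == "drop":
        meas = data.measurements.loc[~incomplete]
        kept = meas["surgery_id"].unique()
        if len(kept) < MIN_SURGERIES_AFTER_DROP:
            raise DegenerateDataError(
                f"dropping incomplete rows leaves {len(kept)} surgeries "
                f"(< {MIN_SURGERIES_AFTER_DROP})"
            )
        out = data.outcomes[data.outcomes["surgery_id"].isin(kept)]
        return SurgeryDataset(meas.copy(), out.copy())

    imputer = IterativeImputer(
        max_iter=10, random_state=None if seed is None else int(seed)
    )
    filled = imputer.fit_transform(proxies.to_numpy(float))
    meas = data.measurements.copy()
    meas[list(data.proxy_columns)] = filled
    return SurgeryDataset(meas, data.outcomes.copy())


@dataclass
class SurrogateModelFit:
    """A fitted proxy-vitals -> paO2 predictor plus its training record."""

    model_kind: str
    tuning: str
    estimator: object
    feature_names: tuple[str, ...]
    chosen_params: dict
    holdout_rmse: float | None
    train_rmse: float
    seed: int | None
    #: per-candidate (params, holdout RMSE) pairs for random_search; the
    #: default configuration is always candidate 0
    candidate_scores: tuple = ()

    def predict(self, proxies: np.ndarray) -> np.ndarray:
        """Raw model predictions (clamping happens in predict_exposure)."""
        return np.asarray(self.estimator.predict(proxies), float)


def _make_estimator(model_kind: str, params: dict, seed: int):
    if model_kind == "random_forest":
        import lightgbm as lgb

        return lgb.LGBMRegressor(
            boosting_type="rf",
            n_estimators=int(params["n_estimators"]),
            feature_fraction=float(params["feature_fraction"]),
            min_child_samples=int(params["min_child_samples"]),
            bagging_fraction=0.632,
            bagging_freq=1,
            n_jobs=1,
            random_state=seed,
            verbose=-1,
        )
    if model_kind == "regularized_glm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "glm",
                    ElasticNet(
                        alpha=float(params["alpha"]),
                        l1_ratio=float(params["l1_ratio"]),
                        max_iter=10_000,
                    ),
                ),
            ]
        )
    raise ConfigurationError(f"unknown surrogate model {model_kind!r}")


def _draw_candidates(model_kind: str, rng: np.random.Generator) -> list[dict]:
    """Default configuration first, then random draws from the search space."""
    if model_kind == "random_forest":
        cands = [dict(RF_DEFAULTS)]
        for _ in range(N_SEARCH_CANDIDATES - 1):
            cands.append(
                {
                    "n_estimators": int(rng.integers(*RF_SPACE["n_estimators"])),
                    "feature_fraction": float(rng.uniform(*RF_SPACE["feature_fraction"])),
                    "min_child_samples": int(rng.integers(*RF_SPACE["min_child_samples"])),
                }
            )
    else:
        lo, hi = GLM_SPACE["alpha"]
        cands = [dict(GLM_DEFAULTS)]
        for _ in range(N_SEARCH_CANDIDATES - 1):
            cands.append(
                {
                    "alpha": float(10 ** rng.uniform(np.log10(lo), np.log10(hi))),
                    "l1_ratio": float(rng.uniform(*GLM_SPACE["l1_ratio"])),
                }
            )
    return cands


def fit_surrogate(
    proxies: pd.DataFrame | np.ndarray,
    pao2: np.ndarray,
    model_kind: str,
    tuning: str,
    seed: int | None = None,
) -> SurrogateModelFit:
    """Fit the paO2 surrogate on the rows where paO2 was observed.

    ``default`` uses the documented fixed hyperparameters; ``random_search``
    scores N_SEARCH_CANDIDATES candidates (the defaults plus random draws
    from the documented spaces) by RMSE on a 25% holdout and refits the
    winner on all rows. Deterministic under ``seed``. Constant proxy columns
    are dropped with a warning; all-constant input is an error.
    """
    if tuning not in ("default", "random_search"):
        raise ConfigurationError(f"unknown tuning mode {tuning!r}")
    if isinstance(proxies, pd.DataFrame):
        names = tuple(proxies.columns)
        X = proxies.to_numpy(float)
    else:
        X = np.asarray(proxies, float)
        names = tuple(f"proxy_{j + 1}" for j in range(X.shape[1]))
    y = np.asarray(pao2, float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ConfigurationError("need at least one proxy column")
    if len(X) < MIN_TRAIN_ROWS:
        raise DegenerateDataError(
            f"only {len(X)} paO2 training rows (< {MIN_TRAIN_ROWS})"
        )
    if np.isnan(X).any() or np.isnan(y).any():
        raise ConfigurationError(
            "training rows contain missing values; apply handle_missing first"
        )

    keep = np.ptp(X, axis=0) > 0
    if not keep.any():
        raise DegenerateDataError("all proxy columns are constant")
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant proxy columns: {dropped}", stacklevel=2)
        X = X[:, keep]
        names = tuple(n for n, k in zip(names, keep) if k)

    rng = np.random.default_rng(seed)
    est_seed = int(rng.integers(2**31))
    holdout_rmse = None
    candidate_scores: tuple = ()
    if tuning == "default":
        params = dict(RF_DEFAULTS if model_kind == "random_forest" else GLM_DEFAULTS)
    else:
        candidates = _draw_candidates(model_kind, rng)
        perm = rng.permutation(len(X))
        n_val = max(1, int(round(HOLDOUT_FRACTION * len(X))))
        val, tr = perm[:n_val], perm[n_val:]
        scores = []
        for cand in candidates:
            est = _make_estimator(model_kind, cand, est_seed)
            est.fit(X[tr], y[tr])
            resid = y[val] - est.predict(X[val])
            scores.append(float(np.sqrt(np.mean(resid**2))))
        best = int(np.argmin(scores))  # ties -> first, i.e. the defaults
        params = candidates[best]
        holdout_rmse = scores[best]
        candidate_scores = tuple(zip(candidates, scores))

    estimator = _make_estimator(model_kind, params, est_seed)
    estimator.fit(X, y)
    train_rmse = float(np.sqrt(np.mean((y - estimator.predict(X)) ** 2)))
    return SurrogateModelFit(
        model_kind=model_kind,
        tuning=tuning,
        estimator=estimator,
        feature_names=names,
        chosen_params=params,
        holdout_rmse=holdout_rmse,
        train_rmse=train_rmse,
        seed=seed,
        candidate_scores=candidate_scores,
    )


def predict_exposure(fit: SurrogateModelFit, data: SurgeryDataset) -> pd.DataFrame:
    """paO2 at every measurement timepoint: observed where available,
    surrogate predictions (clamped to PAO2_CLAMP) filling the gaps.

    Returns a frame with columns ``surgery_id``, ``time``, ``pao2``.
    """
    missing_cols = set(fit.feature_names) - set(data.proxy_columns)
    if missing_cols:
        raise ConfigurationError(
            f"dataset lacks proxy columns used at training time: "
            f"{sorted(missing_cols)}"
        )
    X = data.measurements[list(fit.feature_names)].to_numpy(float)
    if np.isnan(X).any():
        raise ConfigurationError(
            "proxy values contain NaN; apply handle_missing before prediction"
        )
    observed = data.measurements["pao2"].to_numpy(float)
    predicted = np.clip(fit.predict(X), *PAO2_CLAMP)
    filled = np.where(np.isnan(observed), predicted, observed)
    return pd.DataFrame(
        {
            "surgery_id": data.measurements["surgery_id"].to_numpy(),
            "time": data.measurements["time"].to_numpy(),
            "pao2": filled,
        }
    )


@dataclass
class ExposureVector:
    """One aggregated paO2 value (mmHg) per retained surgery."""

    values: pd.Series  # indexed by surgery_id, grid-canonical (sorted) order
    aggregation: str
    excluded: tuple = ()  # surgeries with no usable measurement rows

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(float)
        if len(vals) == 0:
            raise DegenerateDataError("exposure vector is empty")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ConfigurationError("exposure values must be finite and positive")

    @property
    def n(self) -> int:
        return len(self.values)


def aggregate_exposure(filled: pd.DataFrame, aggregation: str) -> ExposureVector:
    """Collapse per-timepoint paO2 to one value per surgery (mean or median)."""
    if aggregation not in ("mean", "median"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    grouped = filled.groupby("surgery_id", sort=True)["pao2"]
    values = grouped.mean() if aggregation == "mean" else grouped.median()
    return ExposureVector(values=values, aggregation=aggregation)
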