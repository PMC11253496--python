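"""The two simulation experiments.

**Part 1 — weak FWER control.** Datasets are generated under the global
null (outcome i.i.d. Bernoulli(0.5), independent of the exposure
structure). For each replicate the full grid is run, the permutation null
is built, and each method (none / minP / Bonferroni) commits a family-wise
error iff any of its (adjusted) p-values falls below alpha. The per-method
error proportions over R replicates estimate the FWER and are reported with
Newcombe (Wilson score) confidence intervals.

**Part 2 — proportion of significant specifications.** Datasets carry a
planted exposure effect; for each replicate and method we record the
fraction of the m strategies significant at each alpha and average over
replicates. Unadjusted analysis flags the most strategies, minP fewer,
Bonferroni the fewest.

Both studies are deterministic functions of (configuration, seed). Tables
are tidy DataFrames; see :mod:`minpverse.plots` for the standard figures.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._seeding import seed_sequence
from .adjust import adjust_bonferroni, adjust_minp
from .engine import GridEvaluator
from .errors import ConfigurationError
from .grid import SpecificationGrid, default_grid
from .permutation import build_null
from .synth import GeneratorConfig, generate

__all__ = ["newcombe_ci", "fwer_study", "proportion_study",
           "PART1_SIZES", "PART2_SIZES"]

#: reference sample-size ladders of the two experiments
PART1_SIZES = (100, 200, 300, 500, 2000, 3000)
PART2_SIZES = (50, 100, 150, 200, 250, 300)

METHODS = ("none", "minp", "bonferroni")


def newcombe_ci(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    This is the single-proportion interval underlying Newcombe's
    recommendations; it behaves sensibly at the 0 and 1 boundaries.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ConfigurationError(
            f"invalid counts: {successes} successes out of {trials} trials"
        )
    if not 0 < confidence < 1:
        raise ConfigurationError("confidence must lie in (0, 1)")
    lo, hi = proportion_confint(
        successes, trials, alpha=1 - confidence, method="wilson"
    )
    # the score interval hits the boundary exactly at k = 0 and k = trials;
    # snap float round-off
    lo = 0.0 if successes == 0 else max(float(lo), 0.0)
    hi = 1.0 if successes == trials else min(float(hi), 1.0)
    return lo, hi


def _int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _replicate_pvalues(
    n: int,
    grid: SpecificationGrid,
    B: int,
    template: GeneratorConfig,
    rep_seed: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw, minP-adjusted and Bonferroni-adjusted p-values for one
    simulated dataset (NaN for failed strategies)."""
    gen_ss, eval_ss = rep_seed.spawn(2)
    cfg = replace(template, n=n)
    data, _ = generate(cfg, seed=gen_ss)
    ev = GridEvaluator(data, grid, seed=_int(eval_ss))
    raw = ev.raw_profile()
    null = build_null(data, grid, B=B, seed=_int(eval_ss), evaluator=ev)
    minp = adjust_minp(raw, null)
    bonf = adjust_bonferroni(raw)
    return raw.p, minp.adjusted, bonf.adjusted


def _iter_reps(R: int, progress: bool, label: str) -> Iterable[int]:
    if progress:
        from tqdm import tqdm

        return tqdm(range(R), desc=label, leave=False)
    return range(R)


def fwer_study(
    sizes: Sequence[int] = PART1_SIZES,
    R: int = 1000,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    grid: SpecificationGrid | None = None,
    template: GeneratorConfig | None = None,
    confidence: float = 0.95,
    progress: bool = False,
) -> pd.DataFrame:
    """Family-wise error rate under the global null, per method and n.

    Returns a tidy frame with one row per (method, n): replicate count,
    error count, FWER estimate and Newcombe CI bounds. The reference
    configuration is R = B = 1000 over ``PART1_SIZES``; scale R, B and
    ``sizes`` down for desk-sized runs.
    """
    if R < 1 or B < 1:
        raise ConfigurationError("need R >= 1 and B >= 1")
    grid = grid if grid is not None else default_grid()
    template = template if template is not None else GeneratorConfig(n=2)
    template = replace(template, beta0=0.0, beta1=0.0)  # global null
    rows = []
    for i, n in enumerate(sizes):
        size_ss = seed_sequence(seed, "fwer", int(n))
        rep_seeds = size_ss.spawn(R)
        errors = dict.fromkeys(METHODS, 0)
        failed_any = 0
        for r in _iter_reps(R, progress, f"FWER n={n}"):
            raw_p, minp_p, bonf_p = _replicate_pvalues(
                n, grid, B, template, rep_seeds[r]
            )
            if np.isnan(raw_p).any():
                failed_any += 1
            with np.errstate(invalid="ignore"):
                errors["none"] += bool(np.nanmin(raw_p) <= alpha)
                errors["minp"] += bool(np.nanmin(minp_p) <= alpha)
                errors["bonferroni"] += bool(np.nanmin(bonf_p) <= alpha)
        for method in METHODS:
            lo, hi = newcombe_ci(errors[method], R, confidence)
            rows.append(
                {
                    "method": method,
                    "n": int(n),
                    "replications": R,
                    "permutations": B,
                    "alpha": alpha,
                    "errors": errors[method],
                    "fwer": errors[method] / R,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "replicates_with_failures": failed_any,
                }
            )
    return pd.DataFrame(rows)


def proportion_study(
    sizes: Sequence[int] = PART2_SIZES,
    R: int = 1000,
    B: int = 1000,
    alphas: Sequence[float] = (0.01, 0.05, 0.1),
    beta1: float = 1.0,
    seed: int = 0,
    grid: SpecificationGrid | None = None,
    template: GeneratorConfig | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Mean fraction of significant specifications under a planted effect.

    ``beta1`` is the planted log-odds effect per (mean paO2 - 200)/50; the
    default 1.0 gives the grid non-trivial but unsaturated power over the
    reference sizes. Returns one row per (method, n, alpha).
    """
    if R < 1 or B < 1:
        raise ConfigurationError("need R >= 1 and B >= 1")
    grid = grid if grid is not None else default_grid()
    template = template if template is not None else GeneratorConfig(n=2)
    template = replace(template, beta1=float(beta1))
    alphas = tuple(alphas)
    rows = []
    for n in sizes:
        size_ss = seed_sequence(seed, "proportion", int(n))
        rep_seeds = size_ss.spawn(R)
        fractions = {
            (method, alpha): np.zeros(R) for method in METHODS for alpha in alphas
        }
        for r in _iter_reps(R, progress, f"power n={n}"):
            raw_p, minp_p, bonf_p = _replicate_pvalues(
                n, grid, B, template, rep_seeds[r]
            )
            per_method = {"none": raw_p, "minp": minp_p, "bonferroni": bonf_p}
            for method, p in per_method.items():
                ok = ~np.isnan(p)
                denom = max(int(ok.sum()), 1)
                for alpha in alphas:
                    fractions[(method, alpha)][r] = float(
                        (p[ok] <= alpha).sum() / denom
                    )
        for method in METHODS:
            for alpha in alphas:
                rows.append(
                    {
                        "method": method,
                        "n": int(n),
                        "alpha": alpha,
                        "replications": R,
                        "permutations": B,
                        "beta1": float(beta1),
                        "mean_significant_fraction": float(
                            fractions[(method, alpha)].mean()
                        ),
                    }
                )
    return pd.DataFrame(rows)
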