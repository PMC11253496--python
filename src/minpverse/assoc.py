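"""Association tests between a coded exposure and a binary outcome.

Three test methods realize the coding/test axis of the decision tree:

``continuous_logistic``
    Two-sided Wald test for the slope of a logistic regression of the
    outcome on the aggregated paO2 value.
``binary_200_fisher``
    Fisher's exact test on the 2x2 table obtained by dichotomizing paO2 at
    200 mmHg.
``ternary_200_250_fisher``
    Freeman-Halton exact test (the 2x3 extension of Fisher's test) with cut
    points 200 and 250 mmHg.

All three are exposed in a *batched* form: one exposure vector against many
outcome vectors at once. This is what makes the permutation approximation of
the minimal-p-value null cheap — the exposure side of the pipeline never
sees the outcome, so only this stage reruns per permutation. The exact tests
exploit that, for fixed exposure coding, a permuted outcome only moves the
table within fixed column margins: p-values are read from a lookup table
built once per distinct row margin.

Scalar entry points are thin wrappers over the batched code, so cached grid
execution is bitwise-identical to strategy-by-strategy execution.

Conventions: all p-values are two-sided; the exact tests sum the null
probabilities of all tables whose probability does not exceed the observed
table's probability, with a relative tie tolerance of 1e-7.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .errors import StrategyFailedError

METHODS = ("continuous_logistic", "binary_200_fisher", "ternary_200_250_fisher")

#: relative tolerance when comparing table probabilities for the "as or more
#: extreme" criterion of the exact tests (guards float ties)
TIE_RTOL = 1e-7

_GRAD_TOL = 1e-8
_MAX_NEWTON_ITER = 60
_SEPARATION_SLOPE = 15.0  # |slope| per SD of exposure beyond which we declare
# separation: odds ratios beyond e^15 per SD are numerically meaningless


# ----------------------------------------------------------------------
# exact-test machinery
# ----------------------------------------------------------------------


def _lchoose(n: int | np.ndarray, k: np.ndarray) -> np.ndarray:
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def _pvalue_from_pmf(pmf: np.ndarray, observed_pmf: np.ndarray) -> np.ndarray:
    """Sum of null probabilities of tables at most as probable as observed.

    ``pmf`` enumerates the full support; ``observed_pmf`` are the observed
    tables' probabilities. Ties count, with relative tolerance TIE_RTOL.
    """
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, observed_pmf * (1.0 + TIE_RTOL), side="right")
    # observed_pmf is itself in the support, so idx >= 1
    return np.minimum(cum[idx - 1], 1.0)


def _fisher_pvalues_for_margin(n1: int, n2: int, K: int, a: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for 2x2 tables with fixed margins.

    Margins: exposure groups of sizes ``n1``/``n2`` and ``K`` total events;
    ``a`` counts events in group 1.
    """
    lo = max(0, K - n2)
    hi = min(n1, K)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _lchoose(n1, support)
        + _lchoose(n2, K - support)
        - _lchoose(n1 + n2, K)
    )
    pmf = np.exp(logpmf)
    return _pvalue_from_pmf(pmf, pmf[a - lo])


def _fh_pvalues_for_margin(
    c: tuple[int, int, int], K: int, a0: np.ndarray, a1: np.ndarray
) -> np.ndarray:
    """Two-sided Freeman-Halton p for 2x3 tables with fixed margins.

    ``c`` are the three exposure-category sizes, ``K`` the total number of
    events, ``(a0, a1)`` the events in the first two categories.
    """
    c0, c1, c2 = c
    n = c0 + c1 + c2
    A0 = np.arange(0, min(c0, K) + 1)
    A1 = np.arange(0, min(c1, K) + 1)
    G0, G1 = np.meshgrid(A0, A1, indexing="ij")
    G2 = K - G0 - G1
    feasible = (G2 >= 0) & (G2 <= c2)
    logpmf = np.full(G0.shape, -np.inf)
    logpmf[feasible] = (
        _lchoose(c0, G0[feasible])
        + _lchoose(c1, G1[feasible])
        + _lchoose(c2, G2[feasible])
        - _lchoose(n, K)
    )
    pmf_flat = np.exp(logpmf[feasible])
    pmf_full = np.exp(logpmf)  # -inf -> 0; observed cells are feasible
    observed = pmf_full[a0, a1]
    return _pvalue_from_pmf(pmf_flat, observed)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Rows are outcome (event / no event), columns exposure groups; the
    p-value is symmetric in this choice.
    """
    t = np.asarray(table, int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    n1, n2 = t[:, 0].sum(), t[:, 1].sum()
    K = t[0].sum()
    if n1 == 0 or n2 == 0 or K == 0 or t[1].sum() == 0:
        return 1.0
    return float(_fisher_pvalues_for_margin(int(n1), int(n2), int(K), np.array([t[0, 0]]))[0])


def freeman_halton_2x3(table: np.ndarray) -> float:
    """Two-sided Freeman-Halton exact p-value for a 2x3 table.

    Invariant to column permutations; a table with an all-zero column gives
    the Fisher p-value of the remaining 2x2 table.
    """
    t = np.asarray(table, int)
    if t.shape != (2, 3) or (t < 0).any():
        raise ValueError("expected a non-negative 2x3 table")
    c = tuple(int(x) for x in t.sum(axis=0))
    K = int(t[0].sum())
    if K == 0 or t[1].sum() == 0 or sum(x > 0 for x in c) <= 1:
        return 1.0
    return float(
        _fh_pvalues_for_margin(c, K, np.array([t[0, 0]]), np.array([t[0, 1]]))[0]
    )


def _grouped_exact(
    counts_fn, keys: np.ndarray, out: np.ndarray, failures: dict[int, str]
) -> None:
    """Fill ``out`` by calling ``counts_fn(K, rows)`` once per unique margin."""
    for K in np.unique(keys):
        rows = np.flatnonzero(keys == K)
        counts_fn(int(K), rows)


def _batch_fisher(groups: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, dict[int, str]]:
    """Batched binary-coding Fisher test. ``groups`` is the boolean high/low
    split of the exposure; ``Y`` is (B, n)."""
    B, n = Y.shape
    n1 = int(groups.sum())
    n2 = n - n1
    p = np.full(B, np.nan)
    failures: dict[int, str] = {}
    K = Y.sum(axis=1).astype(int)
    a = Y[:, groups].sum(axis=1).astype(int)
    constant = (K == 0) | (K == n)
    for b in np.flatnonzero(constant):
        failures[int(b)] = "outcome constant: contingency table degenerate"
    for k in np.unique(K[~constant]):
        rows = np.flatnonzero((K == k) & ~constant)
        p[rows] = _fisher_pvalues_for_margin(n1, n2, int(k), a[rows])
    return p, failures


def _batch_freeman_halton(
    cats: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, dict[int, str]]:
    """Batched ternary-coding Freeman-Halton test. ``cats`` holds category
    codes 0/1/2 per observation."""
    B, n = Y.shape
    c = tuple(int((cats == j).sum()) for j in range(3))
    p = np.full(B, np.nan)
    failures: dict[int, str] = {}
    K = Y.sum(axis=1).astype(int)
    a0 = Y[:, cats == 0].sum(axis=1).astype(int)
    a1 = Y[:, cats == 1].sum(axis=1).astype(int)
    constant = (K == 0) | (K == n)
    for b in np.flatnonzero(constant):
        failures[int(b)] = "outcome constant: contingency table degenerate"
    for k in np.unique(K[~constant]):
        rows = np.flatnonzero((K == k) & ~constant)
        p[rows] = _fh_pvalues_for_margin(c, int(k), a0[rows], a1[rows])
    return p, failures


# ----------------------------------------------------------------------
# logistic Wald test, batched Newton-Raphson
# ----------------------------------------------------------------------


def _batch_logistic(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, dict[int, str]]:
    """Two-sided Wald p for the exposure slope, one logistic fit per row of Y.

    The exposure is standardized internally (the Wald z statistic is
    invariant under affine rescaling). Rows are updated independently with
    damped Newton steps and frozen once their gradient norm drops below
    _GRAD_TOL, so each row's result does not depend on which other rows
    share the batch.
    """
    B, n = Y.shape
    xs = (x - x.mean()) / x.std()
    y = Y.astype(float)
    K = y.sum(axis=1)

    p = np.full(B, np.nan)
    failures: dict[int, str] = {}
    fail = np.zeros(B, dtype=bool)
    constant = (K == 0) | (K == n)
    for b in np.flatnonzero(constant):
        failures[int(b)] = "outcome constant: logistic model undefined"
    fail |= constant

    with np.errstate(divide="ignore"):
        b0 = np.where(~fail, np.log(np.clip(K, 0.5, None) / np.clip(n - K, 0.5, None)), 0.0)
    b1 = np.zeros(B)
    done = fail.copy()
    h00 = np.zeros(B)
    h01 = np.zeros(B)
    h11 = np.zeros(B)

    for _ in range(_MAX_NEWTON_ITER):
        act = np.flatnonzero(~done)
        if act.size == 0:
            break
        eta = b0[act, None] + b1[act, None] * xs[None, :]
        mu = special.expit(eta)
        W = mu * (1.0 - mu)
        # row-wise sums (not BLAS matvecs) so each row's arithmetic is
        # independent of how many rows share the batch -> cached and naive
        # execution agree bitwise
        resid = y[act] - mu
        g0 = resid.sum(axis=1)
        g1 = (resid * xs).sum(axis=1)
        H00 = W.sum(axis=1)
        H01 = (W * xs).sum(axis=1)
        H11 = (W * (xs * xs)).sum(axis=1)
        det = H00 * H11 - H01 * H01

        converged = np.maximum(np.abs(g0), np.abs(g1)) < _GRAD_TOL
        separated = (np.abs(b1[act]) > _SEPARATION_SLOPE) | (det < 1e-12) | ~np.isfinite(det)
        separated &= ~converged
        for b in act[separated]:
            failures[int(b)] = "perfect separation or singular information"
        fail[act[separated]] = True
        finish = converged | separated
        h00[act[finish]] = H00[finish]
        h01[act[finish]] = H01[finish]
        h11[act[finish]] = H11[finish]
        done[act[finish]] = True

        step = ~finish
        if step.any():
            rows = act[step]
            d = det[step]
            d0 = (H11[step] * g0[step] - H01[step] * g1[step]) / d
            d1 = (H00[step] * g1[step] - H01[step] * g0[step]) / d
            damp = np.maximum(1.0, np.maximum(np.abs(d0), np.abs(d1)) / 5.0)
            b0[rows] += d0 / damp
            b1[rows] += d1 / damp
    else:
        for b in np.flatnonzero(~done):
            failures[int(b)] = "logistic fit did not converge"
        fail[~done] = True

    ok = ~fail
    det = h00[ok] * h11[ok] - h01[ok] * h01[ok]
    se = np.sqrt(h00[ok] / det)
    z = b1[ok] / se
    p[ok] = 2.0 * special.ndtr(-np.abs(z))
    return p, failures


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------


def batch_pvalues(
    method: str,
    exposure: np.ndarray,
    outcomes: np.ndarray,
    cutoffs: tuple[float, float] = (200.0, 250.0),
) -> tuple[np.ndarray, dict[int, str]]:
    """P-values of one test method for one exposure vector against many
    outcome vectors.

    Parameters
    ----------
    method:
        One of :data:`METHODS`.
    exposure:
        Aggregated paO2 per surgery, shape (n,).
    outcomes:
        Binary outcome vectors, shape (B, n); each row is tested against
        the same exposure.
    cutoffs:
        Dichotomization/categorization cut points in mmHg (low, high).

    Returns
    -------
    (p, failures):
        ``p`` has shape (B,) with NaN for failed rows; ``failures`` maps row
        index to a reason. A structural failure (constant coded exposure)
        fails every row.
    """
    exposure = np.asarray(exposure, float)
    Y = np.asarray(outcomes)
    if Y.ndim != 2 or Y.shape[1] != exposure.shape[0]:
        raise ValueError(
            f"outcomes shape {Y.shape} does not match exposure length "
            f"{exposure.shape[0]}"
        )
    low, high = cutoffs
    if not low < high:
        raise ValueError("cutoffs must be strictly increasing")
    B = Y.shape[0]

    def _all_fail(reason: str) -> tuple[np.ndarray, dict[int, str]]:
        return np.full(B, np.nan), dict.fromkeys(range(B), reason)

    if method == "continuous_logistic":
        if np.ptp(exposure) == 0:
            return _all_fail("exposure constant: logistic slope undefined")
        return _batch_logistic(exposure, Y)
    if method == "binary_200_fisher":
        groups = exposure >= low
        if groups.all() or not groups.any():
            return _all_fail(
                f"all exposures on one side of the {low:g} mmHg cutoff"
            )
        return _batch_fisher(groups, Y)
    if method == "ternary_200_250_fisher":
        cats = np.digitize(exposure, (low, high))
        if len(np.unique(cats)) <= 1:
            return _all_fail("all exposures in a single paO2 category")
        return _batch_freeman_halton(cats, Y)
    raise ValueError(f"unknown test method {method!r}; expected one of {METHODS}")


def code_and_test(
    exposure: np.ndarray,
    outcome: np.ndarray,
    method: str,
    cutoffs: tuple[float, float] = (200.0, 250.0),
) -> float:
    """Code the exposure and test it against the outcome; scalar form.

    Raises :class:`StrategyFailedError` on degenerate input (constant coded
    exposure, constant outcome, separated/non-converged logistic fit)
    instead of returning a silent p-value.
    """
    outcome = np.asarray(outcome)
    p, failures = batch_pvalues(method, exposure, outcome[None, :], cutoffs)
    if 0 in failures:
        raise StrategyFailedError(failures[0])
    return float(p[0])
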