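"""Synthetic paO2-like datasets with known ground truth.

The real motivating data — intra-operative vitals from ~3,000 neurosurgical
procedures — are not public, so this module generates datasets with the same
*structure*: per-surgery time series of proxy vitals measured at every
timepoint, arterial paO2 (mmHg) observed only at a sparse subset of
timepoints, and one binary post-operative-complication outcome per surgery.

Generative model
----------------
* Latent per-timepoint paO2 follows a stationary Gaussian AR(1) within each
  surgery (marginal N(mean, sd), autocorrelation ``ar_coef``), clipped to
  physiological bounds. The autocorrelation makes mean and median
  aggregation genuinely different choices.
* Each proxy is a linear map of latent paO2 plus independent Gaussian
  noise; individual vitals are weak-to-moderate predictors.
* paO2 is revealed on a random fraction of timepoints; proxies suffer MCAR
  missingness.
* The outcome is Bernoulli with logit beta0 + beta1 * (mean latent paO2 -
  200)/50. ``beta1 = 0`` gives an exact global null; the two simulation
  studies set (0, 0) (pure coin-flip outcome) and a planted effect
  respectively.

``generate`` additionally returns the hidden truth (latent paO2, the
per-surgery means, the coefficients) for oracle tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import SurgeryDataset
from .errors import ConfigurationError

__all__ = ["GeneratorConfig", "generate", "generate_part1_null"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-data generator.

    Defaults describe the reference study conditions: see the methods note
    for the rationale behind each value.
    """

    n: int
    timepoints: tuple[int, int] = (10, 40)
    n_proxies: int = 5
    proxy_coefficients: tuple[float, ...] = (1.0, 0.8, 0.6, -0.5, 0.4)
    proxy_intercepts: tuple[float, ...] = (50.0, 80.0, 30.0, 120.0, 60.0)
    proxy_noise_sd: float = 40.0
    pao2_mean: float = 200.0
    pao2_sd: float = 40.0
    pao2_bounds: tuple[float, float] = (50.0, 450.0)
    ar_coef: float = 0.8
    frac_pao2_observed: float = 0.1
    proxy_missing_rate: float = 0.05
    beta0: float = -1.1
    beta1: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        lo, hi = self.timepoints
        if not (1 <= lo <= hi):
            raise ConfigurationError("timepoints range must satisfy 1 <= lo <= hi")
        if self.n_proxies < 1:
            raise ConfigurationError("need at least one proxy")
        if len(self.proxy_coefficients) != self.n_proxies:
            raise ConfigurationError("proxy_coefficients length must equal n_proxies")
        if len(self.proxy_intercepts) != self.n_proxies:
            raise ConfigurationError("proxy_intercepts length must equal n_proxies")
        for rate, name in (
            (self.frac_pao2_observed, "frac_pao2_observed"),
            (self.proxy_missing_rate, "proxy_missing_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.frac_pao2_observed == 0.0:
            raise ConfigurationError(
                "frac_pao2_observed = 0 leaves no paO2 training rows"
            )
        blo, bhi = self.pao2_bounds
        if not (0 < blo < bhi):
            raise ConfigurationError("pao2_bounds must be positive and ordered")
        if not (0 <= abs(self.ar_coef) < 1):
            raise ConfigurationError("ar_coef must satisfy |rho| < 1 (stationarity)")
        if self.proxy_noise_sd < 0 or self.pao2_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")


def generate(
    config: GeneratorConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[SurgeryDataset, dict]:
    """Draw one dataset from the generative model.

    Returns ``(dataset, truth)`` where ``truth`` holds the latent
    per-timepoint paO2, the per-surgery mean latent exposure, the outcome
    coefficients and the proxy map — everything a test oracle needs.
    """
    config.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n = config.n
    lo, hi = config.timepoints
    T = rng.integers(lo, hi + 1, size=n)
    total = int(T.sum())
    surgery_idx = np.repeat(np.arange(n), T)

    # stationary AR(1) per surgery, vectorized over surgeries
    rho = config.ar_coef
    tmax = int(T.max())
    Z = np.empty((n, tmax))
    Z[:, 0] = rng.standard_normal(n)
    innov = rng.standard_normal((n, tmax - 1)) if tmax > 1 else None
    for t in range(1, tmax):
        Z[:, t] = rho * Z[:, t - 1] + np.sqrt(1 - rho**2) * innov[:, t - 1]
    keep = np.arange(tmax)[None, :] < T[:, None]
    z = Z[keep]  # flattened, surgery-major, time within surgery ascending
    pao2 = np.clip(
        config.pao2_mean + config.pao2_sd * z, *config.pao2_bounds
    )

    coeff = np.asarray(config.proxy_coefficients)
    intercepts = np.asarray(config.proxy_intercepts)
    proxies = (
        intercepts[None, :]
        + pao2[:, None] * coeff[None, :]
        + config.proxy_noise_sd * rng.standard_normal((total, config.n_proxies))
    )
    proxies[rng.random(proxies.shape) < config.proxy_missing_rate] = np.nan

    observed = rng.random(total) < config.frac_pao2_observed
    if not observed.any():
        raise ConfigurationError(
            "no paO2 observation was drawn; increase n or frac_pao2_observed"
        )
    pao2_col = np.where(observed, pao2, np.nan)

    mean_latent = np.bincount(surgery_idx, weights=pao2, minlength=n) / T
    lin = config.beta0 + config.beta1 * (mean_latent - 200.0) / 50.0
    outcome = (rng.random(n) < expit(lin)).astype(np.int8)

    times = np.concatenate([np.arange(t) * 5.0 for t in T])  # minutes
    meas = pd.DataFrame({"surgery_id": surgery_idx, "time": times, "pao2": pao2_col})
    for j in range(config.n_proxies):
        meas[f"proxy_{j + 1}"] = proxies[:, j]
    out = pd.DataFrame({"surgery_id": np.arange(n), "outcome": outcome})

    truth = {
        "latent_pao2": pao2,
        "surgery_mean_latent": mean_latent,
        "beta0": config.beta0,
        "beta1": config.beta1,
        "proxy_coefficients": tuple(config.proxy_coefficients),
        "proxy_intercepts": tuple(config.proxy_intercepts),
        "config": asdict(config),
    }
    return SurgeryDataset(meas, out), truth


def generate_part1_null(
    n: int, seed: int | None = None, template: GeneratorConfig | None = None
) -> SurgeryDataset:
    """A global-null dataset: exposure structure as usual, outcome i.i.d.
    Bernoulli(0.5) independent of everything (beta0 = beta1 = 0)."""
    base = template if template is not None else GeneratorConfig(n=n)
    cfg = replace(base, n=n, beta0=0.0, beta1=0.0)
    data, _ = generate(cfg, seed=seed)
    return data
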