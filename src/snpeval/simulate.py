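"""State-level provision distributions via lognormal moment matching.

The observation unit is one anganwadi-day provision, pooled across a
state's surveyed anganwadis. For each nutrient the sample mean m and
unbiased sample variance v are matched to a lognormal:

    sigma^2 = ln(1 + v / m^2),    mu = ln(m) - sigma^2 / 2

so that the fitted distribution's analytic mean and variance equal (m, v)
exactly. Monte-Carlo draws (1000 by default) from that distribution
represent the varying nutrient content of meals; the median and
inter-quartile range of the draws summarise daily provision per state.
A nutrient never provided (m = 0) is reported as zero provision and not
simulated; zero variance yields a degenerate point mass at m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import NUTRIENT_KEYS, ValidationError
from .engine import DailyProvision


@dataclass
class NutrientMoments:
    """Moments, lognormal parameters and simulated quartiles for one nutrient."""

    m: float
    v: float
    n_obs: int
    provided: bool
    mu: float = float("nan")
    sigma: float = float("nan")
    sim_median: float = 0.0
    sim_q1: float = 0.0
    sim_q3: float = 0.0


@dataclass
class StateNutrientSummary:
    """Per-state simulation summary across the 10-nutrient panel."""

    state_id: str
    nutrients: dict[str, NutrientMoments]
    n_draws: int
    seed: int


def summarize_state(provisions: Sequence[DailyProvision]) -> dict[str, tuple[float, float, int]]:
    """Sample mean, unbiased variance (n-1) and count per nutrient for one state.

    All provisions must belong to the same state; a single observation gets
    variance 0 rather than an error.
    """
    if len(provisions) == 0:
        raise ValidationError("/provisions", "at least one provision required")
    states = {p.state_id for p in provisions}
    if len(states) > 1:
        raise ValidationError("/provisions", f"mixed states: {sorted(states)}")
    out = {}
    for k in NUTRIENT_KEYS:
        x = np.array([p.totals[k] for p in provisions], dtype=float)
        m = float(x.mean())
        v = float(x.var(ddof=1)) if x.size > 1 else 0.0
        out[k] = (m, v, int(x.size))
    return out


def fit_lognormal(m: float, v: float) -> tuple[float, float]:
    """Method-of-moments lognormal parameters from a mean and variance."""
    if m <= 0:
        raise ValidationError("/moments/m", f"mean must be positive to fit, got {m}")
    if v < 0:
        raise ValidationError("/moments/v", f"variance must be >= 0, got {v}")
    sigma2 = math.log1p(v / (m * m))
    return math.log(m) - sigma2 / 2.0, math.sqrt(sigma2)


def lognormal_mean_var(mu: float, sigma: float) -> tuple[float, float]:
    """Analytic mean and variance of lognormal(mu, sigma)."""
    m = math.exp(mu + sigma * sigma / 2.0)
    v = math.expm1(sigma * sigma) * math.exp(2.0 * mu + sigma * sigma)
    return m, v


def simulate_provision(
    mu: float,
    sigma: float,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n_draws independent lognormal(mu, sigma) provision values.

    The seed is mandatory for reproducibility; the same seed yields
    identical draws. sigma = 0 gives a point mass at exp(mu).
    """
    if sigma < 0:
        raise ValidationError("/lognormal/sigma", f"sigma must be >= 0, got {sigma}")
    if n_draws < 1:
        raise ValidationError("/lognormal/n_draws", f"n_draws must be >= 1, got {n_draws}")
    if seed is None:
        raise ValidationError("/lognormal/seed", "seed is mandatory for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n_draws, math.exp(mu))
    return rng.lognormal(mean=mu, sigma=sigma, size=n_draws)


def median_iqr(draws: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """Empirical median and quartiles (linear-interpolation convention)."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValidationError("/draws", "at least one draw required")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3)


def state_summary(
    provisions: Sequence[DailyProvision],
    n_draws: int = 1000,
    seed: int = 0,
    state_index: int = 0,
) -> StateNutrientSummary:
    """Full simulation summary for one state's anganwadi-day provisions.

    Each nutrient draws from an independent substream spawned from
    (seed, state_index, nutrient_index), so results do not depend on
    evaluation order and are reproducible across runs.
    """
    moments = summarize_state(provisions)
    state_id = provisions[0].state_id
    nutrients: dict[str, NutrientMoments] = {}
    for j, k in enumerate(NUTRIENT_KEYS):
        m, v, n_obs = moments[k]
        if m <= 0:
            nutrients[k] = NutrientMoments(m=m, v=v, n_obs=n_obs, provided=False)
            continue
        mu, sigma = fit_lognormal(m, v)
        rng = np.random.default_rng(np.random.SeedSequence([seed, state_index, j]))
        draws = simulate_provision(mu, sigma, n_draws=n_draws, seed=rng)
        med, q1, q3 = median_iqr(draws)
        nutrients[k] = NutrientMoments(
            m=m, v=v, n_obs=n_obs, provided=True, mu=mu, sigma=sigma,
            sim_median=med, sim_q1=q1, sim_q3=q3,
        )
    return StateNutrientSummary(state_id=state_id, nutrients=nutrients, n_draws=n_draws, seed=seed)


def summaries_frame(summaries: Sequence[StateNutrientSummary]) -> pd.DataFrame:
    """One row per state-nutrient with moments, parameters and quartiles."""
    rows = []
    for s in summaries:
        for k in NUTRIENT_KEYS:
            nm = s.nutrients[k]
            rows.append(
                {
                    "state_id": s.state_id,
                    "nutrient": k,
                    "mean": nm.m,
                    "variance": nm.v,
                    "n_obs": nm.n_obs,
                    "provided": nm.provided,
                    "mu": nm.mu,
                    "sigma": nm.sigma,
                    "sim_median": nm.sim_median,
                    "sim_q1": nm.sim_q1,
                    "sim_q3": nm.sim_q3,
                    "n_draws": s.n_draws,
                }
            )
    return pd.DataFrame(rows)
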