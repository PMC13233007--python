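"""Seeded synthetic ED visit cohorts with study-like statistical structure.

No visit-level data ship with the model, so this module generates
cohorts that exercise every downstream stage: two 180-day periods of
visits with disposition, payer, ED and hospital length of stay, revenue
(missing completely at random at a configurable rate), written in the
same CSV dialect the processing pipeline reads.

Revenue and lengths of stay are log-normal — the standard right-skewed
positive family when only moments and quantiles are published to match.
Per-stratum revenue medians are a shared base scaled by disposition and
payer multipliers; :func:`study_like_config` solves the base scale and
the shared log-sd so that the *processed* cohort reproduces the study's
published per-visit figures: capped mean revenue ≈ US $1698 with the cap
(95th percentile) ≈ US $7241, median pre-period ED LOS 311 min (IQR
182–554), and 3.19% missing revenue.

For admitted visits the generator draws the ED-attributable revenue from
the stratum distribution and back-solves the whole-stay revenue as
``attributed / f(hospital LOS)``, where ``f`` is the pipeline's
attribution fraction.  The published per-visit moments describe ED-level
revenue, so parametrising at that level keeps the calibration exact;
the attribution stage then recovers the drawn value.

Generation is a pure function of the config (including its seed): the
same config yields byte-identical CSV output.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort import DISPOSITIONS, PAYERS, RAW_COLUMNS, _attribution_fractions

# Study-scale targets (published cohort figures).
STUDY_N_PRE = 81_464
STUDY_N_POST = 89_259
STUDY_MEAN_REVENUE = 1698.0          # US $/visit, pre period, after capping
STUDY_REVENUE_CAP = 7241.0           # US $, 95th percentile of per-visit revenue
STUDY_MISSINGNESS = 0.0319           # fraction of visits with missing revenue
STUDY_ED_LOS_MEDIAN = 311.0          # minutes, pre period
STUDY_ED_LOS_IQR = (182.0, 554.0)    # minutes, pre period
STUDY_POST_ED_LOS_MEDIAN = 292.0     # minutes
STUDY_POST_MEAN_REVENUE = 1722.0     # US $/visit, post period

_QUARTILE_Z = norm.ppf(0.75)


class StratumRevenue(BaseModel):
    """Log-normal parameters of one (disposition × payer) revenue stratum."""

    median: float = Field(gt=0.0)
    sigma: float = Field(gt=0.0)

    model_config = {"frozen": True}


class CohortConfig(BaseModel):
    """Full description of a synthetic cohort.

    ``revenue`` maps disposition → payer → :class:`StratumRevenue` for
    the ED-attributable revenue per visit.  ``post_ed_los_scale`` and
    ``post_revenue_scale`` multiply the LOS and revenue medians in the
    post period (1.0 = no change).  ``seed`` drives every random draw.
    """

    n_visits_pre: int = Field(gt=0)
    n_visits_post: int = Field(gt=0)
    admit_rate: float = Field(ge=0.0, le=1.0)
    payer_mix: Dict[str, float]
    revenue: Dict[str, Dict[str, StratumRevenue]]
    ed_los_median_min: float = Field(gt=0.0)
    ed_los_sigma: float = Field(gt=0.0)
    hospital_los_median_hr: float = Field(gt=0.0)
    hospital_los_sigma: float = Field(gt=0.0)
    post_ed_los_scale: float = Field(default=1.0, gt=0.0)
    post_revenue_scale: float = Field(default=1.0, gt=0.0)
    missingness_rate: float = Field(ge=0.0, le=1.0)
    seed: int = Field(default=0, ge=0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_structure(self) -> "CohortConfig":
        if set(self.payer_mix) != set(PAYERS):
            raise ValueError(f"payer_mix must have exactly the keys {PAYERS}")
        total = sum(self.payer_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"payer_mix must sum to 1, got {total!r}")
        if any(p < 0 for p in self.payer_mix.values()):
            raise ValueError("payer_mix fractions must be >= 0")
        if set(self.revenue) != set(DISPOSITIONS):
            raise ValueError(f"revenue must have exactly the keys {DISPOSITIONS}")
        for dispo, by_payer in self.revenue.items():
            if set(by_payer) != set(PAYERS):
                raise ValueError(
                    f"revenue[{dispo!r}] must have exactly the keys {PAYERS}"
                )
        return self


# ---------------------------------------------------------------------------
# Log-normal helpers and moment-matching calibration
# ---------------------------------------------------------------------------

def lognormal_sigma_from_iqr(median: float, q1: float, q3: float) -> float:
    """Shared log-sd implied by a median and interquartile range.

    For a log-normal, ``q3/q1 = exp(2 * z_0.75 * sigma)``; the median
    fixes the location independently.
    """
    if not 0 < q1 < q3:
        raise ValueError("need 0 < q1 < q3")
    return math.log(q3 / q1) / (2.0 * _QUARTILE_Z)


def _capped_lognormal_mean(mu: float, sigma: float, cap: float) -> float:
    """E[min(X, cap)] for X ~ LogNormal(mu, sigma), in closed form."""
    a = (math.log(cap) - mu) / sigma
    return math.exp(mu + 0.5 * sigma**2) * norm.cdf(a - sigma) + cap * (
        1.0 - norm.cdf(a)
    )


def _mixture_p95_gap(base_median: float, multipliers, weights, sigma, cap) -> float:
    """P(X <= cap) - 0.95 for the stratum mixture."""
    prob = sum(
        w * norm.cdf((math.log(cap) - math.log(base_median * k)) / sigma)
        for k, w in zip(multipliers, weights)
    )
    return prob - 0.95


def solve_revenue_calibration(
    multipliers,
    weights,
    target_capped_mean: float = STUDY_MEAN_REVENUE,
    target_p95: float = STUDY_REVENUE_CAP,
    sigma_bracket: tuple[float, float] = (0.3, 2.5),
    p95_multipliers=None,
    p95_weights=None,
) -> tuple[float, float]:
    """Solve (base median, shared sigma) for a stratum mixture so that the
    mixture's 95th percentile equals ``target_p95`` and its mean after
    capping at that percentile equals ``target_capped_mean``.

    For each candidate sigma the base median is pinned by the percentile
    condition (monotone, solved by bisection); the capped mean is then
    monotone in sigma over the bracket, giving a 1-D root find.  The
    percentile condition may use its own mixture (``p95_*`` arguments),
    e.g. both periods pooled, while the capped mean is evaluated on the
    primary mixture (e.g. the pre period only).
    """
    multipliers = list(multipliers)
    weights = list(weights)
    p95_multipliers = list(p95_multipliers) if p95_multipliers is not None else multipliers
    p95_weights = list(p95_weights) if p95_weights is not None else weights
    for w in (weights, p95_weights):
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("stratum weights must sum to 1")

    def base_for_sigma(sigma: float) -> float:
        return brentq(
            _mixture_p95_gap,
            target_p95 / max(p95_multipliers) / 1e4,
            target_p95 / min(p95_multipliers),
            args=(p95_multipliers, p95_weights, sigma, target_p95),
            xtol=1e-10,
        )

    def capped_mean_gap(sigma: float) -> float:
        base = base_for_sigma(sigma)
        mean = sum(
            w * _capped_lognormal_mean(math.log(base * k), sigma, target_p95)
            for k, w in zip(multipliers, weights)
        )
        return mean - target_capped_mean

    sigma = brentq(capped_mean_gap, *sigma_bracket, xtol=1e-10)
    return base_for_sigma(sigma), sigma


#: Relative revenue level per disposition (admit visits attribute a larger
#: ED share) and payer (reimbursement generosity), base = medicare discharge.
DEFAULT_DISPO_MULTIPLIER = {"admit": 4.0, "discharge": 1.0}
DEFAULT_PAYER_MULTIPLIER = {
    "medicare": 1.0,
    "medicaid": 0.7,
    "private": 1.4,
    "self_pay": 0.5,
}
DEFAULT_ADMIT_RATE = 0.25
DEFAULT_PAYER_MIX = {
    "medicare": 0.30,
    "medicaid": 0.25,
    "private": 0.35,
    "self_pay": 0.10,
}


def study_like_config(
    seed: int = 0,
    n_visits_pre: int = STUDY_N_PRE,
    n_visits_post: int = STUDY_N_POST,
) -> CohortConfig:
    """Config whose processed cohort reproduces the study's figures.

    Revenue strata are calibrated (see :func:`solve_revenue_calibration`)
    so the pooled per-visit revenue has 95th percentile ≈ $7241 and
    capped mean ≈ $1698; ED LOS matches median 311 min with IQR 182–554
    pre-intervention and median 292 min post; missingness is 3.19%.
    """
    weights, multipliers = [], []
    for dispo in DISPOSITIONS:
        w_dispo = DEFAULT_ADMIT_RATE if dispo == "admit" else 1.0 - DEFAULT_ADMIT_RATE
        for payer in PAYERS:
            weights.append(w_dispo * DEFAULT_PAYER_MIX[payer])
            multipliers.append(
                DEFAULT_DISPO_MULTIPLIER[dispo] * DEFAULT_PAYER_MULTIPLIER[payer]
            )
    # The published cap is the 95th percentile pooled over BOTH periods
    # (post revenue runs ~1.4% higher); the capped-mean target is pre-only.
    rev_scale = STUDY_POST_MEAN_REVENUE / STUDY_MEAN_REVENUE
    w_pre = n_visits_pre / (n_visits_pre + n_visits_post)
    pooled_mult = multipliers + [k * rev_scale for k in multipliers]
    pooled_w = [w * w_pre for w in weights] + [w * (1 - w_pre) for w in weights]
    base, sigma = solve_revenue_calibration(
        multipliers, weights, p95_multipliers=pooled_mult, p95_weights=pooled_w
    )
    revenue = {
        dispo: {
            payer: StratumRevenue(
                median=base
                * DEFAULT_DISPO_MULTIPLIER[dispo]
                * DEFAULT_PAYER_MULTIPLIER[payer],
                sigma=sigma,
            )
            for payer in PAYERS
        }
        for dispo in DISPOSITIONS
    }
    return CohortConfig(
        n_visits_pre=n_visits_pre,
        n_visits_post=n_visits_post,
        admit_rate=DEFAULT_ADMIT_RATE,
        payer_mix=DEFAULT_PAYER_MIX,
        revenue=revenue,
        ed_los_median_min=STUDY_ED_LOS_MEDIAN,
        ed_los_sigma=lognormal_sigma_from_iqr(
            STUDY_ED_LOS_MEDIAN, *STUDY_ED_LOS_IQR
        ),
        hospital_los_median_hr=72.0,
        hospital_los_sigma=0.7,
        post_ed_los_scale=STUDY_POST_ED_LOS_MEDIAN / STUDY_ED_LOS_MEDIAN,
        post_revenue_scale=STUDY_POST_MEAN_REVENUE / STUDY_MEAN_REVENUE,
        missingness_rate=STUDY_MISSINGNESS,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a raw visit table (the pipeline's CSV dialect) from a config.

    One deterministic substream per (period, field) is spawned from the
    master seed, so the output is reproducible and insensitive to how
    other fields are consumed.
    """
    frames = []
    master = np.random.SeedSequence(config.seed)
    period_seeds = master.spawn(2)
    for period, n, seed_seq in (
        ("pre", config.n_visits_pre, period_seeds[0]),
        ("post", config.n_visits_post, period_seeds[1]),
    ):
        frames.append(_generate_period(config, period, n, seed_seq))
    return pd.concat(frames, ignore_index=True)[list(RAW_COLUMNS)]


def _generate_period(
    config: CohortConfig, period: str, n: int, seed_seq: np.random.SeedSequence
) -> pd.DataFrame:
    streams = [np.random.default_rng(s) for s in seed_seq.spawn(5)]
    rng_dispo, rng_payer, rng_los, rng_rev, rng_miss = streams

    is_admit = rng_dispo.random(n) < config.admit_rate
    disposition = np.where(is_admit, "admit", "discharge")
    payer = rng_payer.choice(
        PAYERS, size=n, p=[config.payer_mix[p] for p in PAYERS]
    )

    los_scale = config.post_ed_los_scale if period == "post" else 1.0
    ed_los = rng_los.lognormal(
        mean=math.log(config.ed_los_median_min * los_scale),
        sigma=config.ed_los_sigma,
        size=n,
    )
    hospital_los = np.full(n, np.nan)
    hospital_los[is_admit] = rng_los.lognormal(
        mean=math.log(config.hospital_los_median_hr),
        sigma=config.hospital_los_sigma,
        size=int(is_admit.sum()),
    )
    hospital_los = np.round(hospital_los, 2)  # CSV precision; used below as stored

    rev_scale = config.post_revenue_scale if period == "post" else 1.0
    attributed = np.empty(n)
    z = rng_rev.standard_normal(n)
    for dispo in DISPOSITIONS:
        for pay in PAYERS:
            sel = (disposition == dispo) & (payer == pay)
            stratum = config.revenue[dispo][pay]
            attributed[sel] = (stratum.median * rev_scale) * np.exp(
                stratum.sigma * z[sel]
            )
    # Whole-stay revenue for admits: invert the ED attribution fraction so
    # the processing pipeline recovers the drawn per-visit value exactly.
    revenue = attributed.copy()
    frac = _attribution_fractions(hospital_los[is_admit])
    revenue[is_admit] = attributed[is_admit] / frac

    missing = rng_miss.random(n) < config.missingness_rate
    revenue[missing] = np.nan

    return pd.DataFrame(
        {
            "visit_id": [f"{period}-{i:07d}" for i in range(n)],
            "period": period,
            "disposition": disposition,
            "payer": payer,
            "ed_los_min": np.round(ed_los, 1),
            "hospital_los_hr": hospital_los,
            "revenue_usd": np.round(revenue, 2),
        }
    )
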