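"""Visit-level revenue processing for emergency-department (ED) cohorts.

The operating-margin model works from period aggregates (visit count,
total revenue, median ED length of stay), but hospital billing extracts
arrive as one row per visit with the revenue of the *whole* encounter.
This module turns such extracts into period summaries in three stages:

1. **Attribution** — an admitted patient's revenue covers the entire
   hospital stay; only a fraction is creditable to the ED.  The fraction
   is ``24 h / hospital LOS`` for stays of at least a day and
   ``12 h / hospital LOS`` (capped at 1) for shorter stays.  Revenue for
   discharged patients is credited wholly to the ED.
2. **Capping** — per-visit revenue is winsorised at a high percentile
   (default the 95th, pooled over both study periods) so that rare
   high-revenue encounters, which follow high-acuity pathways regardless
   of triage, do not dominate the totals.
3. **Imputation** — visits with missing revenue receive the mean capped
   revenue of their (disposition × payer) stratum, computed from observed
   visits pooled across periods.

The in-memory container is a :class:`pandas.DataFrame` with the columns
listed in :data:`RAW_COLUMNS` (input) plus the derived columns in
:data:`DERIVED_COLUMNS`; :class:`VisitRecord` is a convenience row type
for building small tables programmatically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PERIODS = ("pre", "post")
DISPOSITIONS = ("admit", "discharge")
PAYERS = ("medicare", "medicaid", "private", "self_pay")
OTHER_PAYER = "other"

#: Input CSV dialect (UTF-8, comma-separated; empty revenue cell = missing).
RAW_COLUMNS = (
    "visit_id",
    "period",
    "disposition",
    "payer",
    "ed_los_min",
    "hospital_los_hr",
    "revenue_usd",
)
#: Columns added by the processing pipeline.
DERIVED_COLUMNS = ("attributed_revenue", "capped_revenue", "final_revenue", "imputed")

#: Hours of ED care credited against a hospital stay of >= 1 day.
FULL_DAY_CREDIT_HR = 24.0
#: Hours credited against a short stay (< 1 day); fraction capped at 1.
SHORT_STAY_CREDIT_HR = 12.0


@dataclass(frozen=True)
class VisitRecord:
    """One ED visit as it moves through the processing stages.

    ``stay_revenue`` is the revenue of the entire hospital stay for
    admits and the ED revenue for discharges; ``None`` means missing.
    """

    visit_id: str
    period: str
    disposition: str
    payer: str
    ed_los_min: float
    hospital_los_hr: float | None = None
    stay_revenue: float | None = None
    attributed_revenue: float | None = None
    capped_revenue: float | None = None
    final_revenue: float | None = None
    imputed: bool = False


@dataclass(frozen=True)
class PeriodSummary:
    """Aggregate state of one study period.

    Attributes
    ----------
    n_visits : int
        Visit count ``V``.
    total_revenue : float
        Total attributed, capped, imputed revenue ``R`` in US $.
    median_ed_los : float
        Median ED length of stay ``L`` in minutes.
    """

    n_visits: int
    total_revenue: float
    median_ed_los: float

    def __post_init__(self) -> None:
        if self.n_visits <= 0:
            raise ValueError("PeriodSummary requires n_visits > 0")
        if self.total_revenue < 0:
            raise ValueError("PeriodSummary requires total_revenue >= 0")
        if self.median_ed_los <= 0:
            raise ValueError("PeriodSummary requires median_ed_los > 0")

    @property
    def revenue_per_visit(self) -> float:
        """Average revenue per ED visit, ``R / V`` (US $)."""
        return self.total_revenue / self.n_visits

    def to_dict(self) -> dict:
        return {
            "n_visits": self.n_visits,
            "total_revenue": self.total_revenue,
            "median_ed_los": self.median_ed_los,
            "revenue_per_visit": self.revenue_per_visit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PeriodSummary":
        missing = {"n_visits", "total_revenue", "median_ed_los"} - set(d)
        if missing:
            raise ValueError(f"period summary missing fields: {sorted(missing)}")
        return cls(
            n_visits=int(d["n_visits"]),
            total_revenue=float(d["total_revenue"]),
            median_ed_los=float(d["median_ed_los"]),
        )


@dataclass
class ProcessedCohort:
    """Result of the full attribute → cap → impute pipeline."""

    frame: pd.DataFrame
    cap_value: float
    imputed_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_imputed(self) -> int:
        return int(sum(self.imputed_counts.values()))

    def summaries(self) -> dict[str, PeriodSummary]:
        """Period summaries for every period present in the cohort."""
        out = {}
        for period in PERIODS:
            if (self.frame["period"] == period).any():
                out[period] = summarize_period(self.frame, period)
        return out


# ---------------------------------------------------------------------------
# Stage 1: admission-revenue attribution
# ---------------------------------------------------------------------------

def attribution_fraction(hospital_los_hr: float) -> float:
    """Fraction of a hospital stay's revenue creditable to the ED.

    ``24 / LOS`` for stays of 24 h or longer (so a one-day stay is
    credited fully) and ``min(1, 12 / LOS)`` for shorter stays.  The
    fraction is always in ``(0, 1]``.
    """
    if hospital_los_hr <= 0:
        raise ValueError(f"hospital_los_hr must be > 0, got {hospital_los_hr}")
    if hospital_los_hr >= FULL_DAY_CREDIT_HR:
        return FULL_DAY_CREDIT_HR / hospital_los_hr
    return min(1.0, SHORT_STAY_CREDIT_HR / hospital_los_hr)


def attribute_admission_revenue(stay_revenue: float, hospital_los_hr: float) -> float:
    """ED-attributable share of an admitted patient's whole-stay revenue.

    Parameters
    ----------
    stay_revenue : float
        Revenue of the entire hospital stay, US $ (>= 0).
    hospital_los_hr : float
        Total hospital length of stay in hours (> 0).

    Returns
    -------
    float
        ``stay_revenue * attribution_fraction(hospital_los_hr)``,
        always between 0 and ``stay_revenue``.
    """
    if stay_revenue < 0:
        raise ValueError(f"stay_revenue must be >= 0, got {stay_revenue}")
    return stay_revenue * attribution_fraction(hospital_los_hr)


def _attribution_fractions(hospital_los_hr: np.ndarray) -> np.ndarray:
    """Vectorised :func:`attribution_fraction` (NaN passes through)."""
    los = np.asarray(hospital_los_hr, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            los >= FULL_DAY_CREDIT_HR,
            FULL_DAY_CREDIT_HR / los,
            np.minimum(1.0, SHORT_STAY_CREDIT_HR / los),
        )
    return frac


def attribute_revenue(visits: pd.DataFrame) -> pd.DataFrame:
    """Add the ``attributed_revenue`` column to a validated visit table.

    Discharged visits keep their revenue unchanged; admitted visits are
    credited the attribution fraction of their whole-stay revenue.
    Missing revenue stays missing.
    """
    out = visits.copy()
    admit = out["disposition"] == "admit"
    frac = np.ones(len(out))
    frac[admit.to_numpy()] = _attribution_fractions(
        out.loc[admit, "hospital_los_hr"].to_numpy()
    )
    out["attributed_revenue"] = out["revenue_usd"].to_numpy(dtype=float) * frac
    return out


# ---------------------------------------------------------------------------
# Stage 2: percentile capping
# ---------------------------------------------------------------------------

PercentileMethod = Literal["linear", "nearest_rank"]


def cap_revenue(
    visits: pd.DataFrame,
    percentile: float = 0.95,
    method: PercentileMethod = "linear",
) -> tuple[pd.DataFrame, float]:
    """Winsorise attributed revenue at a pooled percentile.

    The cap is computed over the non-missing attributed revenue of *both*
    periods pooled, then each non-missing value is replaced by
    ``min(value, cap)``.  Missing values stay missing.

    Parameters
    ----------
    visits : pandas.DataFrame
        Table with an ``attributed_revenue`` column.
    percentile : float
        Fraction in ``(0, 1]``; ``1.0`` makes capping a no-op.
    method : {"linear", "nearest_rank"}
        Percentile convention: linear interpolation between order
        statistics (default) or the nearest-rank (inverted CDF) value.

    Returns
    -------
    (pandas.DataFrame, float)
        Copy of the table with a ``capped_revenue`` column, and the cap.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError(f"percentile must be in (0, 1], got {percentile}")
    observed = visits["attributed_revenue"].dropna().to_numpy(dtype=float)
    if observed.size == 0:
        raise ValueError("cannot cap revenue: all attributed revenue is missing")
    np_method = {"linear": "linear", "nearest_rank": "inverted_cdf"}[method]
    cap_value = float(np.percentile(observed, percentile * 100.0, method=np_method))
    out = visits.copy()
    out["capped_revenue"] = np.minimum(
        out["attributed_revenue"].to_numpy(dtype=float), cap_value
    )
    return out, cap_value


# ---------------------------------------------------------------------------
# Stage 3: stratified mean imputation
# ---------------------------------------------------------------------------

def impute_missing_revenue(visits: pd.DataFrame) -> pd.DataFrame:
    """Fill missing revenue with (disposition × payer) stratum means.

    Stratum means are computed from capped revenue of observed visits
    pooled across both periods.  A stratum with missing values but no
    observed ones falls back to the overall mean (logged as a warning).
    Adds ``final_revenue`` (always present afterwards) and ``imputed``.
    """
    observed = visits["capped_revenue"].notna()
    if not observed.any():
        raise ValueError("cannot impute: no observed revenue in the cohort")
    out = visits.copy()
    overall_mean = float(out.loc[observed, "capped_revenue"].mean())
    stratum_means = (
        out.loc[observed]
        .groupby(["disposition", "payer"], observed=True)["capped_revenue"]
        .mean()
    )
    final = out["capped_revenue"].copy()
    missing = ~observed
    for (dispo, payer), idx in out.loc[missing].groupby(
        ["disposition", "payer"], observed=True
    ).groups.items():
        if (dispo, payer) in stratum_means.index:
            final.loc[idx] = stratum_means.loc[(dispo, payer)]
        else:
            logger.warning(
                "stratum (%s, %s) has %d missing but no observed revenue; "
                "falling back to the overall mean %.2f",
                dispo, payer, len(idx), overall_mean,
            )
            final.loc[idx] = overall_mean
    out["final_revenue"] = final
    out["imputed"] = missing.to_numpy()
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def summarize_period(visits: pd.DataFrame, period: str) -> PeriodSummary:
    """Aggregate one period into a :class:`PeriodSummary`.

    Total revenue is accumulated with :func:`math.fsum` so the sum is
    exact to well below cent precision regardless of row order.
    """
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}, got {period!r}")
    rows = visits[visits["period"] == period]
    if len(rows) == 0:
        raise ValueError(f"no records for period {period!r}")
    if rows["final_revenue"].isna().any():
        raise ValueError(
            f"period {period!r} has records without final_revenue; "
            "run imputation first"
        )
    return PeriodSummary(
        n_visits=int(len(rows)),
        total_revenue=math.fsum(rows["final_revenue"].to_numpy(dtype=float)),
        median_ed_los=float(rows["ed_los_min"].median()),
    )


# ---------------------------------------------------------------------------
# Validation and I/O
# ---------------------------------------------------------------------------

def _bad_rows(mask: pd.Series, limit: int = 5) -> str:
    rows = [str(i) for i in mask.index[mask][:limit]]
    suffix = ", ..." if int(mask.sum()) > limit else ""
    return ", ".join(rows) + suffix


def validate_visits(visits: pd.DataFrame, *, lenient_payers: bool = False) -> pd.DataFrame:
    """Validate a raw visit table against the input schema.

    Raises ``ValueError`` naming the offending rows (by 0-based data row
    number) on the first violated rule.  With ``lenient_payers`` unknown
    payer codes are mapped to the ``"other"`` stratum instead of
    rejected.
    """
    missing_cols = [c for c in RAW_COLUMNS if c not in visits.columns]
    if missing_cols:
        raise ValueError(f"input is missing columns: {missing_cols}")
    out = visits.reset_index(drop=True).copy()

    bad = ~out["period"].isin(PERIODS)
    if bad.any():
        raise ValueError(f"unknown period values at rows {_bad_rows(bad)}")
    bad = ~out["disposition"].isin(DISPOSITIONS)
    if bad.any():
        raise ValueError(f"unknown disposition values at rows {_bad_rows(bad)}")

    bad = ~out["payer"].isin(PAYERS)
    if bad.any():
        if lenient_payers:
            logger.warning(
                "mapping %d unknown payer codes to %r", int(bad.sum()), OTHER_PAYER
            )
            out.loc[bad, "payer"] = OTHER_PAYER
        else:
            raise ValueError(f"unknown payer codes at rows {_bad_rows(bad)}")

    ed_los = pd.to_numeric(out["ed_los_min"], errors="coerce")
    bad = ed_los.isna() | (ed_los <= 0)
    if bad.any():
        raise ValueError(f"ed_los_min must be > 0 at rows {_bad_rows(bad)}")
    out["ed_los_min"] = ed_los

    hlos = pd.to_numeric(out["hospital_los_hr"], errors="coerce")
    admit = out["disposition"] == "admit"
    bad = admit & (hlos.isna() | (hlos <= 0))
    if bad.any():
        raise ValueError(
            f"admitted visits need hospital_los_hr > 0 at rows {_bad_rows(bad)}"
        )
    out["hospital_los_hr"] = hlos.where(admit)

    revenue = pd.to_numeric(out["revenue_usd"], errors="coerce")
    bad = out["revenue_usd"].notna() & revenue.isna() | (revenue < 0)
    if bad.any():
        raise ValueError(
            f"revenue_usd must be >= 0 or empty at rows {_bad_rows(bad)}"
        )
    out["revenue_usd"] = revenue
    return out


def process_visits(
    visits: pd.DataFrame,
    *,
    percentile: float = 0.95,
    method: PercentileMethod = "linear",
    lenient_payers: bool = False,
) -> ProcessedCohort:
    """Run the full pipeline: validate → attribute → cap → impute.

    Imputation uses capped values, so imputed revenue never exceeds the
    cap.  Returns the processed table plus the cap value and per-stratum
    imputation counts for audit logging.
    """
    frame = validate_visits(visits, lenient_payers=lenient_payers)
    frame = attribute_revenue(frame)
    frame, cap_value = cap_revenue(frame, percentile=percentile, method=method)
    frame = impute_missing_revenue(frame)
    counts = (
        frame.loc[frame["imputed"]]
        .groupby(["disposition", "payer"], observed=True)
        .size()
    )
    imputed_counts = {tuple(k): int(v) for k, v in counts.items()}
    logger.info(
        "processed %d visits: cap %.2f (percentile %.2f), %d imputed",
        len(frame), cap_value, percentile, int(frame["imputed"].sum()),
    )
    return ProcessedCohort(frame=frame, cap_value=cap_value, imputed_counts=imputed_counts)


def read_visits(path, *, lenient_payers: bool = False) -> pd.DataFrame:
    """Read and validate a visit-level CSV (see :data:`RAW_COLUMNS`)."""
    raw = pd.read_csv(
        path,
        dtype={"visit_id": str, "period": str, "disposition": str, "payer": str},
    )
    return validate_visits(raw, lenient_payers=lenient_payers)


def write_visits(visits: pd.DataFrame, path) -> None:
    """Write a visit table (raw or processed) as UTF-8 CSV."""
    visits.to_csv(path, index=False)


def records_to_frame(records: Iterable[VisitRecord]) -> pd.DataFrame:
    """Build a raw visit table from :class:`VisitRecord` objects."""
    rows = [
        {
            "visit_id": r.visit_id,
            "period": r.period,
            "disposition": r.disposition,
            "payer": r.payer,
            "ed_los_min": r.ed_los_min,
            "hospital_los_hr": r.hospital_los_hr,
            "revenue_usd": r.stay_revenue,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(RAW_COLUMNS))
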