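"""Confounder screening: stratified summaries and year-over-year shift scans.

A hidden covariate (here: the pre-bleed anesthetic) can split a
historical-control pool into strata with different endpoint locations.
``stratified_summary`` tabulates mean/SD/CI per stratum of any design
covariate; ``year_shift_scan`` automates the visual time-series check by
testing every adjacent calendar-year pair with a Welch t-test and
flagging abrupt, large shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .stats import welch_test
from .store import HCDPool

__all__ = [
    "StratumSummary",
    "ShiftPolicy",
    "BoundaryShift",
    "stratified_summary",
    "year_shift_scan",
    "STRATIFIERS",
]

# AnimalRecord attributes usable as stratifiers
STRATIFIERS = (
    "anesthetic",
    "study_start_year",
    "sex",
    "strain",
    "supplier",
    "route",
    "vehicle",
    "lab_site",
    "study_id",
)


@dataclass(frozen=True)
class StratumSummary:
    stratum: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def stratified_summary(
    pool: HCDPool, stratifier: str, endpoint: str = "CA", confidence: float = 0.95
) -> list[StratumSummary]:
    """Mean, SD and t-based CI of an endpoint per level of a covariate.

    Strata are ordered deterministically by label. Records lacking the
    endpoint are ignored.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(
            f"unknown stratifier {stratifier!r}; valid names: {STRATIFIERS}"
        )
    groups: dict[str, list[float]] = {}
    for rec in pool.records:
        if not rec.has(endpoint):
            continue
        groups.setdefault(str(getattr(rec, stratifier)), []).append(
            rec.value(endpoint)
        )
    out = []
    for label in sorted(groups):
        vals = np.asarray(groups[label])
        mean = float(vals.mean())
        if vals.size >= 2:
            sd = float(vals.std(ddof=1))
            half = float(
                _sps.t.ppf(0.5 + confidence / 2, vals.size - 1)
                * sd
                / np.sqrt(vals.size)
            )
        else:
            sd, half = 0.0, 0.0
        out.append(
            StratumSummary(
                stratum=label,
                n=int(vals.size),
                mean=mean,
                sd=sd,
                ci_low=mean - half,
                ci_high=mean + half,
            )
        )
    return out


@dataclass(frozen=True)
class ShiftPolicy:
    """When an adjacent-year gap counts as a shift.

    A boundary is flagged when the Bonferroni-adjusted Welch p-value is
    at or below ``alpha`` and the absolute mean gap exceeds
    ``gap_sd_multiplier`` times the earlier year's within-year SD.
    Defaults are tuned to catch a ~0.3 mmol/L step at ~30 animals/year
    while ignoring sampling noise.
    """

    alpha: float = 0.01
    gap_sd_multiplier: float = 2.0


@dataclass(frozen=True)
class BoundaryShift:
    year_from: int
    year_to: int
    gap: float  # mean(year_to) - mean(year_from)
    p_value: float
    p_adjusted: float
    flagged: bool


def year_shift_scan(
    pool: HCDPool,
    endpoint: str = "CA",
    policy: ShiftPolicy | None = None,
) -> list[BoundaryShift]:
    """Test every adjacent calendar-year pair for a level shift.

    Returns all testable boundaries sorted by |gap| descending; pairs
    where either year has fewer than 2 animals are skipped.
    """
    policy = policy or ShiftPolicy()
    by_year: dict[int, list[float]] = {}
    for rec in pool.records:
        if rec.has(endpoint):
            by_year.setdefault(rec.study_start_year, []).append(rec.value(endpoint))
    years = sorted(y for y, v in by_year.items() if len(v) >= 2)
    if len(years) < 2:
        raise ValueError("need at least 2 calendar years with >= 2 animals each")

    pairs = [
        (y, y + 1) for y in years if y + 1 in by_year and len(by_year[y + 1]) >= 2
    ]
    results = []
    for y0, y1 in pairs:
        a = np.asarray(by_year[y0])
        b = np.asarray(by_year[y1])
        gap = float(b.mean() - a.mean())
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            p = 1.0 if gap == 0.0 else 0.0
        else:
            p = welch_test(a, b).p_value
        p_adj = min(1.0, p * len(pairs))
        flagged = p_adj <= policy.alpha and abs(gap) > policy.gap_sd_multiplier * float(
            a.std(ddof=1)
        )
        results.append(
            BoundaryShift(
                year_from=y0,
                year_to=y1,
                gap=gap,
                p_value=p,
                p_adjusted=p_adj,
                flagged=flagged,
            )
        )
    results.sort(key=lambda r: (-abs(r.gap), r.year_from))
    return results
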