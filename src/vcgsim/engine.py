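"""Virtual-control-group resampling engine.

The core procedure: run Dunnett's test once on the original study, then
repeatedly (default 500 iterations) replace the concurrent control group
(CCG) with animals drawn without replacement from a historical-control
pool — optionally keeping sentinel animals and/or restricting the pool —
re-run the test against the unchanged dose groups, classify each
iteration's conclusion against the original one, and summarize the share
of consistent conclusions per dose group as the reproducibility [%].

Sentinel animals are the concurrent controls retained when the rest are
replaced: of n kept animals, the n/2 lightest and n/2 heaviest by
initial body weight (plus the middle animal when n is odd), so the
original body-weight location and spread are approximately preserved.
Their measured primary-endpoint values can further narrow the pool to
their mean +/- 2 SD range.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .stats import DunnettResult, dunnett_test
from .store import FilterCriteria, HCDPool, AnimalRecord, filter_pool
from .synthetic import LegacyStudy

__all__ = [
    "Scenario",
    "OutcomeCategory",
    "SentinelSelection",
    "ResamplingReport",
    "select_sentinels",
    "sentinel_filter",
    "sample_vcg",
    "classify_outcome",
    "classify_results",
    "run_resampling",
]

_ANESTHETIC_FILTERS = ("none", "match_study")


@dataclass(frozen=True)
class Scenario:
    """One resampling configuration (which controls to replace, how to filter)."""

    name: str = "custom"
    n_keep_sentinels: int = 0
    pool_anesthetic_filter: str = "none"
    sentinel_range_filter: bool = False
    iterations: int = 500
    alpha: float = 0.05
    seed: int = 0
    endpoints: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        if self.n_keep_sentinels < 0:
            raise ValueError("n_keep_sentinels must be >= 0")
        if self.pool_anesthetic_filter not in _ANESTHETIC_FILTERS:
            raise ValueError(
                f"pool_anesthetic_filter must be one of {_ANESTHETIC_FILTERS}"
            )
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.endpoints:
            raise ValueError("endpoints must not be empty")

    @property
    def primary_endpoint(self) -> str:
        return self.endpoints[0]


class OutcomeCategory(str, enum.Enum):
    """How one iteration's VCG-based conclusion relates to the original."""

    CONSISTENT_SIGNIFICANT = "consistent_significant"
    CONSISTENT_NONSIGNIFICANT = "consistent_nonsignificant"
    INCONSISTENT_SIGNIFICANT = "inconsistent_significant"
    INCONSISTENT_NONSIGNIFICANT = "inconsistent_nonsignificant"
    INVERTED_SIGNIFICANT = "inverted_significant"

    @property
    def consistent(self) -> bool:
        return self in (
            OutcomeCategory.CONSISTENT_SIGNIFICANT,
            OutcomeCategory.CONSISTENT_NONSIGNIFICANT,
        )


def classify_outcome(
    original_significant: bool,
    original_direction: str,
    vcg_significant: bool,
    vcg_direction: str,
) -> OutcomeCategory:
    """Total mapping of (original, VCG) significance/direction to a category."""
    if not original_significant:
        if not vcg_significant:
            return OutcomeCategory.CONSISTENT_NONSIGNIFICANT
        return OutcomeCategory.INCONSISTENT_SIGNIFICANT
    if not vcg_significant:
        return OutcomeCategory.INCONSISTENT_NONSIGNIFICANT
    if original_direction == vcg_direction:
        return OutcomeCategory.CONSISTENT_SIGNIFICANT
    return OutcomeCategory.INVERTED_SIGNIFICANT


def classify_results(
    original: DunnettResult, vcg: DunnettResult
) -> list[OutcomeCategory]:
    if len(original.comparisons) != len(vcg.comparisons):
        raise ValueError("original and VCG results cover different dose groups")
    return [
        classify_outcome(o.significant, o.direction, v.significant, v.direction)
        for o, v in zip(original.comparisons, vcg.comparisons)
    ]


@dataclass(frozen=True)
class SentinelSelection:
    """Which concurrent controls are kept and the range their values define."""

    kept: tuple[AnimalRecord, ...]
    replaced: tuple[AnimalRecord, ...]
    endpoint: str
    range_low: float | None
    range_high: float | None

    @property
    def kept_ids(self) -> tuple[str, ...]:
        return tuple(a.subject_id for a in self.kept)

    @property
    def replaced_ids(self) -> tuple[str, ...]:
        return tuple(a.subject_id for a in self.replaced)


def select_sentinels(
    control: list[AnimalRecord], n_keep: int, endpoint: str = "CA"
) -> SentinelSelection:
    """Pick sentinel animals from the extremes of the initial body weights.

    Animals are sorted ascending by initial body weight (ties broken by
    subject id); floor(n/2) lightest and floor(n/2) heaviest are kept,
    plus the animal at rank floor((N+1)/2) of the full sorted list when
    n is odd. The kept animals' primary-endpoint values define the
    mean +/- 2 SD range (undefined when fewer than 2 are kept).
    """
    n_total = len(control)
    if n_keep > n_total:
        raise ValueError(f"n_keep = {n_keep} exceeds group size {n_total}")
    order = sorted(control, key=lambda a: (a.initial_body_weight, a.subject_id))
    n_half = n_keep // 2
    kept_idx = set(range(n_half)) | set(range(n_total - n_half, n_total))
    if n_keep % 2 == 1:
        kept_idx.add((n_total + 1) // 2 - 1)
    kept = tuple(order[i] for i in sorted(kept_idx))
    replaced = tuple(order[i] for i in range(n_total) if i not in kept_idx)
    if len(kept) >= 2:
        vals = np.array([a.value(endpoint) for a in kept])
        mean, sd = vals.mean(), vals.std(ddof=1)
        lo, hi = float(mean - 2 * sd), float(mean + 2 * sd)
    else:
        lo = hi = None
    return SentinelSelection(
        kept=kept, replaced=replaced, endpoint=endpoint, range_low=lo, range_high=hi
    )


def sentinel_filter(
    pool: HCDPool, selection: SentinelSelection, endpoint: str | None = None
) -> HCDPool:
    """Restrict the pool to the sentinels' mean +/- 2 SD range (closed)."""
    if selection.range_low is None:
        raise ValueError(
            "sentinel range undefined (fewer than 2 kept animals); "
            "disable the sentinel range filter"
        )
    endpoint = endpoint or selection.endpoint
    lo, hi = selection.range_low, selection.range_high
    kept = [
        r for r in pool.records if r.has(endpoint) and lo <= r.value(endpoint) <= hi
    ]
    return pool.subset(
        kept, f"sentinel range filter on {endpoint}: [{lo:.6g}, {hi:.6g}]"
    )


def sample_vcg(
    pool: HCDPool,
    n: int,
    endpoints: tuple[str, ...],
    rng: np.random.Generator,
) -> list[AnimalRecord]:
    """Draw n distinct animals carrying all requested endpoints, uniformly.

    All endpoint values are later taken from the same animals, preserving
    the animal-level linkage between correlated parameters.
    """
    eligible = [r for r in pool.records if r.has(*endpoints)]
    if len(eligible) < n:
        raise ValueError(
            f"eligible pool has {len(eligible)} animals with endpoints "
            f"{endpoints}, cannot draw {n}"
        )
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx]


@dataclass
class ResamplingReport:
    """Per-dose-group outcome-category counts and reproducibility [%]."""

    scenario: Scenario
    original: dict[str, DunnettResult]  # endpoint -> result
    dose_labels: tuple[str, ...]
    counts: dict[str, dict[str, dict[str, int]]]  # endpoint -> label -> category -> n
    sentinel_selection: SentinelSelection
    pool_provenance: list
    iteration_log: list[dict] = field(default_factory=list)

    def reproducibility_percent(self, group: str, endpoint: str | None = None) -> float:
        endpoint = endpoint or self.scenario.primary_endpoint
        c = self.counts[endpoint][group]
        consistent = (
            c[OutcomeCategory.CONSISTENT_SIGNIFICANT.value]
            + c[OutcomeCategory.CONSISTENT_NONSIGNIFICANT.value]
        )
        return 100.0 * consistent / self.scenario.iterations

    def to_dict(self) -> dict:
        """JSON-serializable summary (used for reports and determinism checks)."""
        return {
            "scenario": {
                "name": self.scenario.name,
                "n_keep_sentinels": self.scenario.n_keep_sentinels,
                "pool_anesthetic_filter": self.scenario.pool_anesthetic_filter,
                "sentinel_range_filter": self.scenario.sentinel_range_filter,
                "iterations": self.scenario.iterations,
                "alpha": self.scenario.alpha,
                "seed": self.scenario.seed,
                "endpoints": list(self.scenario.endpoints),
            },
            "original": {
                ep: {
                    c.label: {
                        "mean_difference": c.mean_difference,
                        "t_statistic": c.t_statistic,
                        "p_value": c.p_value,
                        "significant": c.significant,
                        "direction": c.direction,
                    }
                    for c in res.comparisons
                }
                for ep, res in self.original.items()
            },
            "sentinels": {
                "kept": list(self.sentinel_selection.kept_ids),
                "range_low": self.sentinel_selection.range_low,
                "range_high": self.sentinel_selection.range_high,
            },
            "counts": self.counts,
            "reproducibility_percent": {
                ep: {
                    g: self.reproducibility_percent(g, ep) for g in self.dose_labels
                }
                for ep in self.counts
            },
            "iterations": self.iteration_log,
        }


def run_resampling(
    study: LegacyStudy, pool: HCDPool, scenario: Scenario
) -> ResamplingReport:
    """Execute one resampling scenario end to end.

    The original Dunnett result is computed once on the unmodified study.
    The pool is filtered per the scenario (anesthetic match first, then
    the sentinel range); each iteration draws (group size - n_keep)
    animals without replacement, assembles the virtual control from the
    sentinel values plus the drawn values (constant control-group size),
    re-runs Dunnett's test against the unchanged dose groups and
    classifies the conclusion per dose group. Fully reproducible from
    scenario.seed via per-iteration substreams.
    """
    for ep in scenario.endpoints:
        if ep not in study.dose_values:
            raise ValueError(f"study has no dose-group values for endpoint {ep!r}")
    n_control = len(study.control_animals)
    if scenario.n_keep_sentinels > n_control:
        raise ValueError(
            f"n_keep_sentinels = {scenario.n_keep_sentinels} exceeds the "
            f"control-group size {n_control}"
        )

    original = {
        ep: dunnett_test(
            study.control_values(ep),
            study.dose_group_values(ep),
            alpha=scenario.alpha,
            labels=study.dose_labels,
        )
        for ep in scenario.endpoints
    }

    selection = select_sentinels(
        study.control_animals, scenario.n_keep_sentinels, scenario.primary_endpoint
    )

    working = pool
    if scenario.pool_anesthetic_filter == "match_study":
        # unknown-anesthetic animals cannot be verified, so they are excluded too
        working = filter_pool(
            working, FilterCriteria(anesthetics={study.anesthetic})
        )
    if scenario.sentinel_range_filter:
        working = sentinel_filter(working, selection, scenario.primary_endpoint)

    n_replace = n_control - scenario.n_keep_sentinels
    eligible = [r for r in working.records if r.has(*scenario.endpoints)]
    if len(eligible) < n_replace:
        raise ValueError(
            f"filtered pool has only {len(eligible)} eligible animals; "
            f"{n_replace} are needed per iteration"
        )
    sentinel_ids = set(selection.kept_ids)

    categories = [c.value for c in OutcomeCategory]
    counts = {
        ep: {g: {c: 0 for c in categories} for g in study.dose_labels}
        for ep in scenario.endpoints
    }
    log: list[dict] = []
    primary = scenario.primary_endpoint

    for it in range(scenario.iterations):
        # domain tag 3 keeps iteration streams disjoint from generator streams
        rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 3, it)))
        drawn = sample_vcg(working, n_replace, scenario.endpoints, rng)
        drawn_ids = [a.subject_id for a in drawn]
        if sentinel_ids.intersection(drawn_ids):
            raise RuntimeError("a sentinel animal was drawn from the pool")

        entry: dict = {"iteration": it, "subject_ids": list(selection.kept_ids) + drawn_ids}
        for ep in scenario.endpoints:
            virtual = np.array(
                [a.value(ep) for a in selection.kept] + [a.value(ep) for a in drawn]
            )
            assert virtual.size == n_control
            vcg_res = dunnett_test(
                virtual,
                study.dose_group_values(ep),
                alpha=scenario.alpha,
                labels=study.dose_labels,
            )
            for label, cat in zip(
                study.dose_labels, classify_results(original[ep], vcg_res)
            ):
                counts[ep][label][cat.value] += 1
            if ep == primary:
                entry["vcg_mean"] = float(virtual.mean())
                entry["vcg_sd"] = float(virtual.std(ddof=1))
            entry[f"p_values_{ep}"] = [c.p_value for c in vcg_res.comparisons]
        log.append(entry)

    return ResamplingReport(
        scenario=scenario,
        original=original,
        dose_labels=study.dose_labels,
        counts=counts,
        sentinel_selection=selection,
        pool_provenance=list(working.provenance),
        iteration_log=log,
    )
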