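"""Synthetic historical-control pools and legacy-study fixtures.

The generator emulates the statistical structure of a rat-toxicology
historical control database for serum calcium: a two-component normal
mixture induced by a calendar-year changeover of the pre-bleed anesthetic
(CO2 before the changeover year elevates electrolytes; isoflurane after
lowers them), a phosphate endpoint correlated with calcium within each
stratum, and body weights independent of the electrolytes. A legacy
study fixture (one control plus dose groups) can be drawn with its group
sample moments matched exactly to prescribed targets via affine
rescaling, so the original Dunnett conclusions are reproduced from
printed summaries alone.

Default calibration (all configurable): isoflurane stratum 2.55 +/- 0.07
mmol/L, CO2 stratum 2.87 +/- 0.14 mmol/L, CO2 share w = 0.44 (fitted to
the reported pool moments 2.68-2.69 +/- 0.19-0.20), 30 studies x 10 male
control animals, study years 2011-2021 with the changeover at 2017.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .store import ENDPOINT_UNITS, AnimalRecord, HCDPool, Measurement, ProvenanceEntry

__all__ = [
    "MixtureSpec",
    "GroupSpec",
    "EndpointConfig",
    "LegacyStudy",
    "default_mixture_spec",
    "legacy_group_specs",
    "generate_hcd_pool",
    "generate_legacy_study",
    "moment_match",
    "calibrate_mixture_weight",
    "fit_mixture_weight",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Two-stratum normal mixture for the primary electrolyte endpoint.

    Component 0 is the isoflurane (post-changeover) stratum, component 1
    the CO2 (pre-changeover) stratum; ``weight_second`` is the CO2 share.
    """

    component_means: tuple[float, ...] = (2.55, 2.87)
    component_sds: tuple[float, ...] = (0.07, 0.14)
    weight_second: float = 0.44
    n_studies: int = 30
    animals_per_study: int = 10
    year_range: tuple[int, int] = (2011, 2021)
    changeover_year: int = 2017

    def __post_init__(self) -> None:
        if len(self.component_means) != len(self.component_sds):
            raise ValueError("component_means and component_sds must have equal length")
        if len(self.component_means) < 1:
            raise ValueError("component_means must not be empty")
        if any(s <= 0 for s in self.component_sds):
            raise ValueError("component_sds must all be positive")
        if not 0.0 <= self.weight_second <= 1.0:
            raise ValueError(f"weight_second must lie in [0, 1], got {self.weight_second}")
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        if self.animals_per_study < 1:
            raise ValueError("animals_per_study must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError(f"year_range out of order: {self.year_range}")
        if not self.year_range[0] <= self.changeover_year <= self.year_range[1] + 1:
            raise ValueError(
                "changeover_year must lie within year_range or at its upper boundary"
            )

    @property
    def mixture_mean(self) -> float:
        w = self.weight_second
        m1, m2 = self.component_means[0], self.component_means[1]
        return w * m2 + (1.0 - w) * m1

    @property
    def mixture_sd(self) -> float:
        w = self.weight_second
        m1, m2 = self.component_means[0], self.component_means[1]
        s1, s2 = self.component_sds[0], self.component_sds[1]
        var = (
            w * s2**2
            + (1.0 - w) * s1**2
            + w * (1.0 - w) * (m2 - m1) ** 2
        )
        return float(np.sqrt(var))


@dataclass(frozen=True)
class GroupSpec:
    """Target sample moments for one group of a simulated study."""

    label: str
    target_mean: float
    target_sd: float
    n: int = 10

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.target_sd < 0:
            raise ValueError(f"group {self.label!r}: target_sd must be >= 0")


@dataclass(frozen=True)
class EndpointConfig:
    """Secondary-endpoint parameters; stand-ins, aligned with the mixture strata.

    Phosphate tracks the anesthetic like calcium does (CO2 stratum
    elevated) and correlates with calcium within each stratum; body
    weights are independent of the electrolytes.
    """

    phosphate_stratum_means: tuple[float, ...] = (2.05, 2.30)
    phosphate_stratum_sds: tuple[float, ...] = (0.15, 0.15)
    ca_phos_correlation: float = 0.5
    initial_weight_range_g: tuple[float, float] = (150.0, 250.0)
    day28_weight_mean_g: float = 300.0
    day28_weight_sd_g: float = 20.0
    measurement_day: int = 28

    def __post_init__(self) -> None:
        if not -1.0 < self.ca_phos_correlation < 1.0:
            raise ValueError("ca_phos_correlation must lie in (-1, 1)")


@dataclass
class LegacyStudy:
    """A completed study whose concurrent controls get replaced by VCGs."""

    study_id: str
    endpoint: str
    anesthetic: str
    control_animals: list[AnimalRecord]
    dose_values: dict[str, dict[str, np.ndarray]]  # endpoint -> label -> values
    group_labels: tuple[str, ...]  # control label first, then dose labels

    @property
    def dose_labels(self) -> tuple[str, ...]:
        return self.group_labels[1:]

    def control_values(self, endpoint: str | None = None) -> np.ndarray:
        endpoint = endpoint or self.endpoint
        return np.array([a.value(endpoint) for a in self.control_animals])

    def dose_group_values(self, endpoint: str | None = None) -> list[np.ndarray]:
        endpoint = endpoint or self.endpoint
        return [self.dose_values[endpoint][lab] for lab in self.dose_labels]


def study_to_dict(study: LegacyStudy) -> dict:
    """JSON-serializable form of a legacy study (inverse of study_from_dict)."""
    return {
        "study_id": study.study_id,
        "endpoint": study.endpoint,
        "anesthetic": study.anesthetic,
        "group_labels": list(study.group_labels),
        "control_animals": [
            {
                "subject_id": a.subject_id,
                "initial_body_weight": a.initial_body_weight,
                "study_start_year": a.study_start_year,
                "measurements": {
                    code: {"value": m.value, "unit": m.unit, "day": m.day}
                    for code, m in a.measurements.items()
                },
            }
            for a in study.control_animals
        ],
        "dose_values": {
            ep: {lab: list(vals) for lab, vals in groups.items()}
            for ep, groups in study.dose_values.items()
        },
    }


def study_from_dict(data: dict) -> LegacyStudy:
    control = [
        AnimalRecord(
            subject_id=a["subject_id"],
            study_id=data["study_id"],
            initial_body_weight=a["initial_body_weight"],
            study_start_year=a["study_start_year"],
            anesthetic=data["anesthetic"],
            measurements={
                code: Measurement(m["value"], m["unit"], m["day"])
                for code, m in a["measurements"].items()
            },
        )
        for a in data["control_animals"]
    ]
    return LegacyStudy(
        study_id=data["study_id"],
        endpoint=data["endpoint"],
        anesthetic=data["anesthetic"],
        control_animals=control,
        dose_values={
            ep: {lab: np.asarray(vals) for lab, vals in groups.items()}
            for ep, groups in data["dose_values"].items()
        },
        group_labels=tuple(data["group_labels"]),
    )


def default_mixture_spec(weight_second: float = 0.44) -> MixtureSpec:
    """The calibrated serum-calcium mixture (see module docstring)."""
    return MixtureSpec(weight_second=weight_second)


def legacy_group_specs() -> list[GroupSpec]:
    """Group moments of the reference 28-day legacy study (serum calcium).

    Control 2.57 +/- 0.06, dose groups 2.57 +/- 0.05, 2.64 +/- 0.04 and
    2.69 +/- 0.04 mmol/L, 10 male rats each; Dunnett's test on these
    moments flags dose groups 2 and 3 only.
    """
    return [
        GroupSpec("CCG", 2.57, 0.06, 10),
        GroupSpec("DG1", 2.57, 0.05, 10),
        GroupSpec("DG2", 2.64, 0.04, 10),
        GroupSpec("DG3", 2.69, 0.04, 10),
    ]


def moment_match(values, target_mean: float, target_sd: float) -> np.ndarray:
    """Affinely rescale a sample to exact target mean and SD (ddof=1).

    z-standardizes then shifts/scales; preserves the rank order and is
    exact to floating-point precision.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("moment_match needs at least 2 values (SD undefined)")
    if target_sd < 0:
        raise ValueError("target_sd must be >= 0")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("input sample has zero SD; cannot rescale")
    return target_mean + (x - x.mean()) * (target_sd / sd)


def calibrate_mixture_weight(m1: float, m2: float, target_mean: float) -> float:
    """Mixture weight w of the second component with w*m2+(1-w)*m1 = target."""
    if m1 == m2:
        raise ValueError("component means must differ")
    lo, hi = min(m1, m2), max(m1, m2)
    if not lo <= target_mean <= hi:
        raise ValueError(
            f"target mean {target_mean} outside component range [{lo}, {hi}]"
        )
    return (target_mean - m1) / (m2 - m1)


def fit_mixture_weight(
    m1: float, s1: float, m2: float, s2: float,
    target_mean: float, target_sd: float,
) -> float:
    """Least-squares mixture weight against target pool mean and SD jointly."""

    def loss(w: float) -> float:
        mean = w * m2 + (1 - w) * m1
        var = w * s2**2 + (1 - w) * s1**2 + w * (1 - w) * (m2 - m1) ** 2
        return (mean - target_mean) ** 2 + (np.sqrt(var) - target_sd) ** 2

    res = minimize_scalar(loss, bounds=(0.0, 1.0), method="bounded")
    return float(res.x)


# substream domain tags keep pool, fixture and resampling streams disjoint
_DOMAIN_POOL = 1
_DOMAIN_LEGACY = 2


def _study_rng(seed: int, index: int) -> np.random.Generator:
    # deterministic substream per (seed, study index)
    return np.random.default_rng(np.random.SeedSequence((seed, _DOMAIN_POOL, index)))


def generate_hcd_pool(
    spec: MixtureSpec,
    endpoint_config: EndpointConfig | None = None,
    seed: int = 0,
) -> HCDPool:
    """Draw a synthetic historical-control pool from a mixture spec.

    Studies before the changeover year use CO2 anesthesia and draw the
    electrolytes from the second mixture component; studies from the
    changeover year on use isoflurane and the first component. The CO2
    study count is round(weight_second * n_studies); study years are
    uniform within each regime's span. Same seed, same pool, bit for bit.
    """
    cfg = endpoint_config or EndpointConfig()
    n_co2 = round(spec.weight_second * spec.n_studies)
    pre_years = list(range(spec.year_range[0], spec.changeover_year))
    post_years = list(range(spec.changeover_year, spec.year_range[1] + 1))
    if n_co2 > 0 and not pre_years:
        raise ValueError("weight_second > 0 but no years before changeover_year")
    if n_co2 < spec.n_studies and not post_years:
        raise ValueError("weight_second < 1 but no years from changeover_year on")

    day = cfg.measurement_day
    records: list[AnimalRecord] = []
    for i in range(spec.n_studies):
        rng = _study_rng(seed, i)
        is_co2 = i < n_co2
        year = int(rng.choice(pre_years if is_co2 else post_years))
        stratum = 1 if is_co2 else 0
        mu_ca = spec.component_means[stratum]
        sd_ca = spec.component_sds[stratum]
        mu_p = cfg.phosphate_stratum_means[stratum]
        sd_p = cfg.phosphate_stratum_sds[stratum]
        rho = cfg.ca_phos_correlation
        study_id = f"HCD{i + 1:03d}"
        for j in range(spec.animals_per_study):
            ca = mu_ca + sd_ca * rng.standard_normal()
            phos = (
                mu_p
                + rho * sd_p / sd_ca * (ca - mu_ca)
                + sd_p * np.sqrt(1 - rho**2) * rng.standard_normal()
            )
            bw_init = rng.uniform(*cfg.initial_weight_range_g)
            bw28 = cfg.day28_weight_mean_g + cfg.day28_weight_sd_g * rng.standard_normal()
            records.append(
                AnimalRecord(
                    subject_id=f"{study_id}-A{j + 1:02d}",
                    study_id=study_id,
                    age_weeks_at_start=float(rng.uniform(6.0, 9.0)),
                    initial_body_weight=float(bw_init),
                    study_start_year=year,
                    anesthetic="CO2" if is_co2 else "isoflurane",
                    measurements={
                        "CA": Measurement(float(ca), ENDPOINT_UNITS["CA"], day),
                        "PHOS": Measurement(float(phos), ENDPOINT_UNITS["PHOS"], day),
                        "BW": Measurement(float(bw28), ENDPOINT_UNITS["BW"], day),
                    },
                )
            )
    n = len(records)
    provenance = [
        ProvenanceEntry(
            f"synthetic pool (seed={seed}, {spec.n_studies} studies x "
            f"{spec.animals_per_study} animals, CO2 share {spec.weight_second})",
            n, n,
        )
    ]
    return HCDPool(records=records, provenance=provenance)


def generate_legacy_study(
    groups: list[GroupSpec],
    endpoint: str = "CA",
    exact_moments: bool = True,
    seed: int = 0,
    study_id: str = "LEGACY",
    anesthetic: str = "isoflurane",
    study_year: int = 2018,
) -> LegacyStudy:
    """Simulate a control + dose-group study with prescribed group moments.

    With ``exact_moments`` each group's sample mean and SD hit the
    targets to floating-point precision via affine rescaling. The first
    group is the concurrent control; its animals carry independent
    initial body weights so sentinel selection has something to sort by.
    """
    if len(groups) < 2:
        raise ValueError("need at least a control group and one dose group")
    if endpoint not in ENDPOINT_UNITS:
        raise ValueError(f"unknown endpoint code {endpoint!r}")
    if exact_moments and any(g.n < 2 for g in groups):
        raise ValueError("exact_moments requires n >= 2 in every group (SD undefined)")
    rng = np.random.default_rng(np.random.SeedSequence((seed, _DOMAIN_LEGACY, 0)))
    unit = ENDPOINT_UNITS[endpoint]

    group_values: dict[str, np.ndarray] = {}
    for g in groups:
        draws = rng.normal(g.target_mean, g.target_sd, size=g.n)
        if g.target_sd == 0.0:
            draws = np.full(g.n, float(g.target_mean))
        elif exact_moments:
            draws = moment_match(draws, g.target_mean, g.target_sd)
        group_values[g.label] = draws

    control = groups[0]
    control_animals = [
        AnimalRecord(
            subject_id=f"{study_id}-C{j + 1:02d}",
            study_id=study_id,
            initial_body_weight=float(rng.uniform(150.0, 250.0)),
            study_start_year=study_year,
            anesthetic=anesthetic,
            measurements={endpoint: Measurement(float(v), unit, 28)},
        )
        for j, v in enumerate(group_values[control.label])
    ]
    dose_values = {endpoint: {g.label: group_values[g.label] for g in groups[1:]}}
    return LegacyStudy(
        study_id=study_id,
        endpoint=endpoint,
        anesthetic=anesthetic,
        control_animals=control_animals,
        dose_values=dose_values,
        group_labels=tuple(g.label for g in groups),
    )
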