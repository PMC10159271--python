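"""End-to-end reproducible case study over the six standard sub-scenarios.

Ties generator, store, statistics and resampling engine together: build
the calibrated historical-control pool and the legacy-study fixture,
run each requested sub-scenario, and emit a machine-readable summary
(scenario x dose group -> reproducibility % and category breakdown)
plus per-iteration logs, all deterministic for a fixed global seed.

Sub-scenario naming: "1" = confounder unknown (unfiltered pool),
"2" = confounder known (pool restricted to the study's anesthetic);
"a" = replace all controls, "b" = keep 2 sentinel animals,
"c" = keep half (5 of 10). Sentinel scenarios additionally narrow the
pool to the sentinels' primary-endpoint mean +/- 2 SD range.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .engine import OutcomeCategory, ResamplingReport, Scenario, run_resampling
from .store import HCDPool
from .synthetic import (
    EndpointConfig,
    GroupSpec,
    LegacyStudy,
    MixtureSpec,
    default_mixture_spec,
    fit_mixture_weight,
    generate_hcd_pool,
    generate_legacy_study,
    legacy_group_specs,
)

__all__ = [
    "STANDARD_SCENARIO_SETTINGS",
    "standard_scenario",
    "CaseStudyConfig",
    "CaseStudyResult",
    "run_case_study",
    "scenario_seed",
]

STANDARD_SCENARIO_SETTINGS: dict[str, dict] = {
    "1a": dict(n_keep_sentinels=0, pool_anesthetic_filter="none", sentinel_range_filter=False),
    "1b": dict(n_keep_sentinels=2, pool_anesthetic_filter="none", sentinel_range_filter=True),
    "1c": dict(n_keep_sentinels=5, pool_anesthetic_filter="none", sentinel_range_filter=True),
    "2a": dict(n_keep_sentinels=0, pool_anesthetic_filter="match_study", sentinel_range_filter=False),
    "2b": dict(n_keep_sentinels=2, pool_anesthetic_filter="match_study", sentinel_range_filter=True),
    "2c": dict(n_keep_sentinels=5, pool_anesthetic_filter="match_study", sentinel_range_filter=True),
}


def scenario_seed(global_seed: int, name: str) -> int:
    """Derive a per-scenario integer seed (< 2^31) from the global seed."""
    index = sorted(STANDARD_SCENARIO_SETTINGS).index(name)
    ss = np.random.SeedSequence((global_seed, 4, index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def standard_scenario(
    name: str,
    global_seed: int,
    iterations: int = 500,
    alpha: float = 0.05,
    endpoints: tuple[str, ...] = ("CA",),
) -> Scenario:
    if name not in STANDARD_SCENARIO_SETTINGS:
        raise ValueError(
            f"unknown scenario {name!r}; valid: {sorted(STANDARD_SCENARIO_SETTINGS)}"
        )
    return Scenario(
        name=name,
        iterations=iterations,
        alpha=alpha,
        seed=scenario_seed(global_seed, name),
        endpoints=endpoints,
        **STANDARD_SCENARIO_SETTINGS[name],
    )


@dataclass
class CaseStudyConfig:
    """Everything needed to rerun the case study from scratch."""

    seed: int
    mixture: MixtureSpec = field(default_factory=default_mixture_spec)
    groups: list[GroupSpec] = field(default_factory=legacy_group_specs)
    endpoint_config: EndpointConfig = field(default_factory=EndpointConfig)
    scenario_names: tuple[str, ...] = ("1a", "1b", "1c", "2a", "2b", "2c")
    iterations: int = 500
    alpha: float = 0.05
    endpoints: tuple[str, ...] = ("CA",)
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if len(set(self.scenario_names)) != len(self.scenario_names):
            raise ValueError("scenario names must be unique")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mixture": vars(self.mixture) | {},
            "groups": [vars(g) for g in self.groups],
            "endpoint_config": vars(self.endpoint_config) | {},
            "scenario_names": list(self.scenario_names),
            "iterations": self.iterations,
            "alpha": self.alpha,
            "endpoints": list(self.endpoints),
        }

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class CaseStudyResult:
    config: CaseStudyConfig
    pool: HCDPool
    study: LegacyStudy
    reports: dict[str, ResamplingReport]
    summary: pd.DataFrame
    calibration: dict


def _summary_frame(
    reports: dict[str, ResamplingReport], endpoint: str
) -> pd.DataFrame:
    rows = []
    for name in sorted(reports):
        rep = reports[name]
        for group in rep.dose_labels:
            counts = rep.counts[endpoint][group]
            row = {
                "scenario": name,
                "dose_group": group,
                "reproducibility_percent": rep.reproducibility_percent(group, endpoint),
            }
            for cat in OutcomeCategory:
                row[cat.value] = counts[cat.value]
            rows.append(row)
    return pd.DataFrame(rows)


def run_case_study(config: CaseStudyConfig) -> CaseStudyResult:
    """Generate pool + fixture, run every scenario, optionally write outputs."""
    pool = generate_hcd_pool(config.mixture, config.endpoint_config, seed=config.seed)
    study = generate_legacy_study(
        config.groups, endpoint=config.endpoints[0], exact_moments=True, seed=config.seed
    )

    m1, m2 = config.mixture.component_means[:2]
    s1, s2 = config.mixture.component_sds[:2]
    n_co2 = round(config.mixture.weight_second * config.mixture.n_studies)
    calibration = {
        "mixture_weight": config.mixture.weight_second,
        "mixture_weight_lsq_vs_2.68_0.19": fit_mixture_weight(m1, s1, m2, s2, 2.68, 0.19),
        "mixture_weight_lsq_vs_2.69_0.20": fit_mixture_weight(m1, s1, m2, s2, 2.69, 0.20),
        "theoretical_pool_mean": config.mixture.mixture_mean,
        "theoretical_pool_sd": config.mixture.mixture_sd,
        "n_co2_studies": n_co2,
        "n_isoflurane_studies": config.mixture.n_studies - n_co2,
    }

    reports: dict[str, ResamplingReport] = {}
    for name in config.scenario_names:
        scenario = standard_scenario(
            name,
            config.seed,
            iterations=config.iterations,
            alpha=config.alpha,
            endpoints=config.endpoints,
        )
        try:
            reports[name] = run_resampling(study, pool, scenario)
        except Exception as exc:  # propagate with scenario context
            raise RuntimeError(f"scenario {name} failed: {exc}") from exc

    summary = _summary_frame(reports, config.endpoints[0])
    result = CaseStudyResult(
        config=config,
        pool=pool,
        study=study,
        reports=reports,
        summary=summary,
        calibration=calibration,
    )
    if config.output_dir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: CaseStudyResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.csv", index=False)

    header = {
        "package_version": __version__,
        "seed": result.config.seed,
        "config_hash": result.config.config_hash(),
        "config": result.config.to_dict(),
        "calibration": result.calibration,
    }
    payload = {
        "header": header,
        "scenarios": {
            name: {
                k: v for k, v in rep.to_dict().items() if k != "iterations"
            }
            for name, rep in result.reports.items()
        },
    }
    (out / "case_study.json").write_text(json.dumps(payload, indent=2) + "\n")

    for name, rep in result.reports.items():
        rows = []
        for entry in rep.iteration_log:
            row = {
                "iteration": entry["iteration"],
                "subject_ids": ";".join(entry["subject_ids"]),
                "vcg_mean": entry["vcg_mean"],
                "vcg_sd": entry["vcg_sd"],
            }
            primary = rep.scenario.primary_endpoint
            for label, p in zip(
                rep.dose_labels, entry[f"p_values_{primary}"]
            ):
                row[f"p_{label}"] = p
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / f"iterations_{name}.csv", index=False)
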