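"""Animal-level historical control data (HCD) in a simplified SEND-like dialect.

Three CSV tables make up a pool on disk:

* ``DM.csv`` — demographics: USUBJID, STUDYID, SEX, STRAIN, SUPPLIER,
  AGEWKS, ROUTE, VEHICLE, BWINIT, STARTYR, SITE
* ``LB.csv`` — laboratory results: USUBJID, LBTESTCD, LBSTRESN, LBSTRESU, LBDY
* ``META.csv`` — per-study anesthetic procedure: STUDYID, ANESTH

The variable names mirror the SEND DM/LB domains so real exports can be
down-converted, while the anesthetic lives in a side table precisely
because the SEND standard does not record it. A ``provenance.json`` file
written next to the tables logs every filter applied to the pool with
before/after record counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "Measurement",
    "AnimalRecord",
    "FilterCriteria",
    "ProvenanceEntry",
    "HCDPool",
    "write_pool",
    "read_pool",
    "filter_pool",
    "attach_metadata",
    "ENDPOINT_UNITS",
    "ANESTHETICS",
]

ENDPOINT_UNITS = {
    "CA": "mmol/L",
    "PHOS": "mmol/L",
    "K": "mmol/L",
    "SODIUM": "mmol/L",
    "BW": "g",
}
ANESTHETICS = ("CO2", "isoflurane", "unknown")

_DM_COLUMNS = [
    "USUBJID", "STUDYID", "SEX", "STRAIN", "SUPPLIER", "AGEWKS",
    "ROUTE", "VEHICLE", "BWINIT", "STARTYR", "SITE",
]
_LB_COLUMNS = ["USUBJID", "LBTESTCD", "LBSTRESN", "LBSTRESU", "LBDY"]
_META_COLUMNS = ["STUDYID", "ANESTH"]


@dataclass(frozen=True)
class Measurement:
    value: float
    unit: str
    day: int


@dataclass
class AnimalRecord:
    """One historical (or study) control animal with design covariates."""

    subject_id: str
    study_id: str
    sex: str = "M"
    strain: str = "WISTAR HAN"
    supplier: str = "CHARLES RIVER"
    age_weeks_at_start: float = 7.0
    route: str = "ORAL GAVAGE"
    vehicle: str = "ETHANOL/KOLLIPHOR/WATER"
    initial_body_weight: float = 200.0
    study_start_year: int = 2018
    anesthetic: str = "unknown"
    lab_site: str = "WUPPERTAL"
    measurements: dict[str, Measurement] = field(default_factory=dict)

    def value(self, endpoint: str) -> float:
        return self.measurements[endpoint].value

    def has(self, *endpoints: str) -> bool:
        return all(e in self.measurements for e in endpoints)


@dataclass(frozen=True)
class ProvenanceEntry:
    description: str
    n_before: int
    n_after: int


@dataclass
class HCDPool:
    """Filtered collection of animal records, the VCG sample population."""

    records: list[AnimalRecord]
    provenance: list[ProvenanceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids in pool: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def values(self, endpoint: str) -> list[float]:
        return [r.value(endpoint) for r in self.records if r.has(endpoint)]

    def subset(self, records: list[AnimalRecord], description: str) -> "HCDPool":
        entry = ProvenanceEntry(description, len(self.records), len(records))
        return HCDPool(records=records, provenance=[*self.provenance, entry])


@dataclass
class FilterCriteria:
    """Pool selection criteria; unset (None) fields mean no constraint.

    All ranges are closed intervals. ``max_measurement_day`` prunes
    measurements taken after that study day rather than dropping animals.
    """

    year_range: tuple[int, int] | None = None
    age_weeks_range: tuple[float, float] | None = None
    weight_range_g: tuple[float, float] | None = None
    sex: str | None = None
    strains: set[str] | None = None
    suppliers: set[str] | None = None
    route: str | None = None
    vehicle: str | None = None
    max_measurement_day: int | None = None
    anesthetics: set[str] | None = None
    required_endpoints: set[str] | None = None

    def __post_init__(self) -> None:
        for name in ("year_range", "age_weeks_range", "weight_range_g"):
            bounds = getattr(self, name)
            if bounds is not None and bounds[0] > bounds[1]:
                raise ValueError(f"{name} bounds out of order: {bounds}")

    def describe(self) -> str:
        parts = [
            f"{k}={v!r}"
            for k, v in vars(self).items()
            if v is not None
        ]
        return "filter(" + (", ".join(parts) if parts else "no constraints") + ")"

    def admits(self, rec: AnimalRecord) -> bool:
        c = self
        if c.year_range and not c.year_range[0] <= rec.study_start_year <= c.year_range[1]:
            return False
        if c.age_weeks_range and not (
            c.age_weeks_range[0] <= rec.age_weeks_at_start <= c.age_weeks_range[1]
        ):
            return False
        if c.weight_range_g and not (
            c.weight_range_g[0] <= rec.initial_body_weight <= c.weight_range_g[1]
        ):
            return False
        if c.sex is not None and rec.sex != c.sex:
            return False
        if c.strains is not None and rec.strain not in c.strains:
            return False
        if c.suppliers is not None and rec.supplier not in c.suppliers:
            return False
        if c.route is not None and rec.route != c.route:
            return False
        if c.vehicle is not None and rec.vehicle != c.vehicle:
            return False
        if c.anesthetics is not None and rec.anesthetic not in c.anesthetics:
            return False
        if c.required_endpoints is not None and not rec.has(*c.required_endpoints):
            return False
        return True


def filter_pool(pool: HCDPool, criteria: FilterCriteria) -> HCDPool:
    """Keep records satisfying all set constraints; log a provenance entry.

    An empty result is legal. The measurement-day constraint trims each
    surviving record's measurements to study days <= the bound.
    """
    kept = []
    for rec in pool.records:
        if not criteria.admits(rec):
            continue
        if criteria.max_measurement_day is not None:
            trimmed = {
                code: m
                for code, m in rec.measurements.items()
                if m.day <= criteria.max_measurement_day
            }
            rec = replace(rec, measurements=trimmed)
        kept.append(rec)
    return pool.subset(kept, criteria.describe())


def attach_metadata(pool: HCDPool, metadata: dict[str, str] | pd.DataFrame) -> HCDPool:
    """Join per-study anesthetic metadata onto the pool's records.

    Studies absent from the metadata keep anesthetic = "unknown".
    Contradictory duplicate rows for the same study are an error.
    """
    if isinstance(metadata, pd.DataFrame):
        mapping: dict[str, str] = {}
        for _, row in metadata.iterrows():
            sid, anesth = str(row["STUDYID"]), str(row["ANESTH"])
            if sid in mapping and mapping[sid] != anesth:
                raise ValueError(
                    f"contradictory anesthetic for study {sid}: "
                    f"{mapping[sid]!r} vs {anesth!r}"
                )
            mapping[sid] = anesth
    else:
        mapping = dict(metadata)
    for anesth in mapping.values():
        if anesth not in ANESTHETICS:
            raise ValueError(f"unknown anesthetic {anesth!r}; expected {ANESTHETICS}")
    records = [
        replace(rec, anesthetic=mapping.get(rec.study_id, "unknown"))
        for rec in pool.records
    ]
    return HCDPool(records=records, provenance=list(pool.provenance))


def write_pool(pool: HCDPool, directory: str | Path) -> list[Path]:
    """Write DM.csv / LB.csv / META.csv (+ provenance.json) for a pool."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    dm_rows = []
    lb_rows = []
    meta: dict[str, str] = {}
    for rec in pool.records:
        dm_rows.append(
            {
                "USUBJID": rec.subject_id,
                "STUDYID": rec.study_id,
                "SEX": rec.sex,
                "STRAIN": rec.strain,
                "SUPPLIER": rec.supplier,
                "AGEWKS": repr(rec.age_weeks_at_start),
                "ROUTE": rec.route,
                "VEHICLE": rec.vehicle,
                "BWINIT": repr(rec.initial_body_weight),
                "STARTYR": rec.study_start_year,
                "SITE": rec.lab_site,
            }
        )
        for code, m in rec.measurements.items():
            lb_rows.append(
                {
                    "USUBJID": rec.subject_id,
                    "LBTESTCD": code,
                    "LBSTRESN": repr(m.value),
                    "LBSTRESU": m.unit,
                    "LBDY": m.day,
                }
            )
        if rec.anesthetic != "unknown":
            prev = meta.get(rec.study_id)
            if prev is not None and prev != rec.anesthetic:
                raise ValueError(
                    f"study {rec.study_id} has records with conflicting anesthetics"
                )
            meta[rec.study_id] = rec.anesthetic

    paths = []
    dm = pd.DataFrame(dm_rows, columns=_DM_COLUMNS)
    lb = pd.DataFrame(lb_rows, columns=_LB_COLUMNS)
    mt = pd.DataFrame(
        sorted(meta.items()), columns=_META_COLUMNS
    )
    for name, frame in (("DM.csv", dm), ("LB.csv", lb), ("META.csv", mt)):
        path = directory / name
        frame.to_csv(path, index=False)
        paths.append(path)

    prov_path = directory / "provenance.json"
    prov_path.write_text(
        json.dumps(
            [vars(e) for e in pool.provenance], indent=2
        )
        + "\n"
    )
    paths.append(prov_path)
    return paths


def read_pool(directory: str | Path) -> HCDPool:
    """Read a pool written by :func:`write_pool`; round-trips losslessly."""
    directory = Path(directory)
    for name in ("DM.csv", "LB.csv", "META.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"required table {name} missing in {directory}")

    dm = pd.read_csv(directory / "DM.csv", dtype=str, keep_default_na=False)
    lb = pd.read_csv(directory / "LB.csv", dtype=str, keep_default_na=False)
    mt = pd.read_csv(directory / "META.csv", dtype=str, keep_default_na=False)

    anesthetic_by_study = {}
    for _, row in mt.iterrows():
        sid, anesth = row["STUDYID"], row["ANESTH"]
        if sid in anesthetic_by_study and anesthetic_by_study[sid] != anesth:
            raise ValueError(f"META.csv: contradictory anesthetic for study {sid}")
        if anesth not in ANESTHETICS:
            raise ValueError(f"META.csv: unknown anesthetic {anesth!r} for study {sid}")
        anesthetic_by_study[sid] = anesth

    def _num(text: str, table: str, line: int) -> float:
        try:
            return float(text)
        except ValueError:
            raise ValueError(
                f"{table} line {line}: malformed numeric value {text!r}"
            ) from None

    records: dict[str, AnimalRecord] = {}
    for i, row in dm.iterrows():
        rec = AnimalRecord(
            subject_id=row["USUBJID"],
            study_id=row["STUDYID"],
            sex=row["SEX"],
            strain=row["STRAIN"],
            supplier=row["SUPPLIER"],
            age_weeks_at_start=_num(row["AGEWKS"], "DM.csv", i + 2),
            route=row["ROUTE"],
            vehicle=row["VEHICLE"],
            initial_body_weight=_num(row["BWINIT"], "DM.csv", i + 2),
            study_start_year=int(_num(row["STARTYR"], "DM.csv", i + 2)),
            anesthetic=anesthetic_by_study.get(row["STUDYID"], "unknown"),
            lab_site=row["SITE"],
        )
        if rec.subject_id in records:
            raise ValueError(f"DM.csv: duplicate subject id {rec.subject_id}")
        records[rec.subject_id] = rec

    for i, row in lb.iterrows():
        code = row["LBTESTCD"]
        if code not in ENDPOINT_UNITS:
            raise ValueError(
                f"LB.csv line {i + 2}: unknown endpoint code {code!r} "
                f"(expected one of {sorted(ENDPOINT_UNITS)})"
            )
        sid = row["USUBJID"]
        if sid not in records:
            raise ValueError(f"LB.csv line {i + 2}: unknown subject {sid!r}")
        records[sid].measurements[code] = Measurement(
            value=_num(row["LBSTRESN"], "LB.csv", i + 2),
            unit=row["LBSTRESU"],
            day=int(_num(row["LBDY"], "LB.csv", i + 2)),
        )

    provenance = []
    prov_path = directory / "provenance.json"
    if prov_path.exists():
        provenance = [
            ProvenanceEntry(**e) for e in json.loads(prov_path.read_text())
        ]
    return HCDPool(records=list(records.values()), provenance=provenance)
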