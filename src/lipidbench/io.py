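"""CSV/JSON readers and writers.

All machine formats are UTF-8, comma-separated, '.' decimal, with a
mandatory header row; mean and sd are always separate columns.  Readers
validate schema and values and report the offending *file line number*
(header = line 1).  Fatty-acid codes are resolved through the synonym map,
so report-style spellings ("9c,C18:1") and PUFA acronyms are accepted.

Full precision is preserved everywhere except the benchmark CSV, which is a
report artifact rounded to 2 decimals; the benchmark JSON keeps full
precision and round-trips exactly.
"""

from __future__ import annotations

import json
import math
import pathlib
from typing import Mapping, Sequence

import pandas as pd

from . import registry as _registry
from .benchmark import ReferenceInterval
from .errors import SchemaError
from .indexes import PANEL_ORDER, LipidIndexPanel
from .quantitation import CompositionProfile, PeakTable, StandardPoint
from .registry import FattyAcidDef
from .stats import ComparisonResult, CorrelationResult, DogRecord

METADATA_COLUMNS = ["sample_id", "sex", "neutered", "age_months", "bodyweight_kg", "breed"]


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = pathlib.Path(path)
    if not path.exists():
        raise SchemaError(f"missing file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: malformed header, missing columns {missing}")
    return df


def _line(idx: int) -> int:
    """File line of DataFrame row ``idx`` (header occupies line 1)."""
    return int(idx) + 2


def read_standards_csv(
    path, registry: Sequence[FattyAcidDef] | None = None
) -> dict[str, list[StandardPoint]]:
    """``fa_code,concentration_ug_ml,area`` -> per-FA standard points."""
    df = _read_csv(path, ["fa_code", "concentration_ug_ml", "area"])
    out: dict[str, list[StandardPoint]] = {}
    for idx, row in df.iterrows():
        code = _registry.normalize_code(str(row["fa_code"]), registry)
        if code == "other":
            raise SchemaError(f"line {_line(idx)}: standards cannot be 'other'")
        conc = float(row["concentration_ug_ml"])
        area = float(row["area"])
        if conc <= 0 or area <= 0:
            raise SchemaError(
                f"line {_line(idx)}: non-positive standard for {code}"
            )
        out.setdefault(code, []).append(StandardPoint(code, conc, area))
    return out


def read_peaks_csv(
    path, registry: Sequence[FattyAcidDef] | None = None
) -> list[PeakTable]:
    """``sample_id,fa_code,area`` -> one :class:`PeakTable` per sample.

    Non-cluster area may be pooled under ``fa_code = other``.  Duplicate
    (sample, cluster code) pairs and negative areas are rejected with their
    line number.
    """
    df = _read_csv(path, ["sample_id", "fa_code", "area"])
    rows_by_sample: dict[str, list[tuple[str, float]]] = {}
    seen: set[tuple[str, str]] = set()
    order: list[str] = []
    for idx, row in df.iterrows():
        sample = str(row["sample_id"])
        code = _registry.normalize_code(str(row["fa_code"]), registry)
        area = float(row["area"])
        if area < 0:
            raise SchemaError(
                f"line {_line(idx)}: negative area for {code} in {sample}"
            )
        if code != "other":
            if (sample, code) in seen:
                raise SchemaError(
                    f"line {_line(idx)}: duplicate peak ({sample}, {code})"
                )
            seen.add((sample, code))
        if sample not in rows_by_sample:
            rows_by_sample[sample] = []
            order.append(sample)
        rows_by_sample[sample].append((code, area))
    return [PeakTable(s, tuple(rows_by_sample[s])) for s in order]


def read_metadata_csv(path) -> list[DogRecord]:
    df = _read_csv(path, METADATA_COLUMNS)
    records = []
    truthy = {"true", "1", "yes", "t"}
    falsy = {"false", "0", "no", "f"}
    for idx, row in df.iterrows():
        sex = str(row["sex"]).strip().upper()
        if sex not in ("M", "F"):
            raise SchemaError(f"line {_line(idx)}: sex must be M or F, got {row['sex']!r}")
        raw_neutered = str(row["neutered"]).strip().lower()
        if raw_neutered in truthy:
            neutered = True
        elif raw_neutered in falsy:
            neutered = False
        else:
            raise SchemaError(f"line {_line(idx)}: unparseable neutered flag")
        records.append(
            DogRecord(
                sample_id=str(row["sample_id"]),
                sex=sex,  # type: ignore[arg-type]
                neutered=neutered,
                age_months=float(row["age_months"]),
                bodyweight_kg=float(row["bodyweight_kg"]),
                breed=str(row["breed"]),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate sample_id in metadata")
    return records


def write_metadata_csv(records: Sequence[DogRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "sex": r.sex,
                "neutered": r.neutered,
                "age_months": r.age_months,
                "bodyweight_kg": r.bodyweight_kg,
                "breed": r.breed,
            }
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def write_standards_csv(standards: Mapping[str, Sequence[StandardPoint]], path) -> None:
    rows = [
        {"fa_code": p.fa_code, "concentration_ug_ml": p.concentration_ug_ml, "area": p.area}
        for pts in standards.values()
        for p in pts
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_peaks_csv(tables: Sequence[PeakTable], path) -> None:
    rows = [
        {"sample_id": t.sample_id, "fa_code": code, "area": area}
        for t in tables
        for code, area in t.rows
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_profiles_csv(
    profiles: Sequence[CompositionProfile],
    path,
    registry: Sequence[FattyAcidDef] | None = None,
) -> None:
    """One row per sample: the ten percentages plus coverage columns."""
    codes = _registry.cluster_codes(registry)
    rows = []
    for p in profiles:
        row: dict = {"sample_id": p.sample_id}
        row.update({c: p.percent[c] for c in codes})
        row["coverage_fraction"] = p.coverage_fraction
        row["coverage_pass"] = p.coverage_pass
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_profiles_csv(
    path, registry: Sequence[FattyAcidDef] | None = None
) -> list[CompositionProfile]:
    codes = _registry.cluster_codes(registry)
    df = _read_csv(path, ["sample_id"] + codes + ["coverage_fraction", "coverage_pass"])
    out = []
    for _, row in df.iterrows():
        percent = {c: float(row[c]) for c in codes}
        out.append(
            CompositionProfile(
                sample_id=str(row["sample_id"]),
                quantity_ug_ml={},
                percent=percent,
                coverage_fraction=float(row["coverage_fraction"]),
                coverage_pass=bool(row["coverage_pass"]),
            )
        )
    return out


def write_panels_csv(panels: Sequence[LipidIndexPanel], path) -> None:
    rows = [{"sample_id": p.sample_id, **p.as_dict()} for p in panels]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_panels_csv(path) -> list[LipidIndexPanel]:
    df = _read_csv(path, ["sample_id"] + list(PANEL_ORDER))
    return [
        LipidIndexPanel(
            sample_id=str(row["sample_id"]),
            **{name: float(row[name]) for name in PANEL_ORDER},
        )
        for _, row in df.iterrows()
    ]


def _interval_record(ri: ReferenceInterval, ndigits: int | None) -> dict:
    def r(v):
        if v is None:
            return None
        return round(v, ndigits) if ndigits is not None else v

    return {
        "parameter": ri.parameter,
        "n": ri.n,
        "min": r(ri.minimum),
        "max": r(ri.maximum),
        "median": r(ri.median),
        "p2_5": r(ri.p2_5),
        "p97_5": r(ri.p97_5),
    }


def write_benchmark(
    benchmark: Sequence[ReferenceInterval], path, fmt: str = "csv"
) -> None:
    """Benchmark table: CSV rounded to 2 decimals, JSON at full precision."""
    path = pathlib.Path(path)
    if fmt == "csv":
        pd.DataFrame([_interval_record(ri, 2) for ri in benchmark]).to_csv(
            path, index=False
        )
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([_interval_record(ri, None) for ri in benchmark], fh, indent=1)
    else:
        raise SchemaError(f"unknown benchmark format: {fmt!r}")


def read_benchmark_json(path) -> list[ReferenceInterval]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return [
        ReferenceInterval(
            parameter=d["parameter"],
            n=int(d["n"]),
            minimum=float(d["min"]),
            maximum=float(d["max"]),
            median=float(d["median"]),
            p2_5=None if d["p2_5"] is None else float(d["p2_5"]),
            p97_5=None if d["p97_5"] is None else float(d["p97_5"]),
        )
        for d in doc
    ]


def write_comparisons_csv(comparisons: Sequence[ComparisonResult], path) -> None:
    rows = [
        {
            "parameter": c.parameter,
            "n_m": c.group_a.n,
            "mean_m": c.group_a.mean,
            "sd_m": c.group_a.sd,
            "n_f": c.group_b.n,
            "mean_f": c.group_b.mean,
            "sd_f": c.group_b.sd,
            "test_used": c.test_used,
            "statistic": c.statistic,
            "p_value": c.p_value,
            "significant": c.significant,
        }
        for c in comparisons
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_correlations_csv(correlations: Sequence[CorrelationResult], path) -> None:
    rows = [
        {
            "parameter": c.parameter,
            "covariate": c.covariate,
            "method": c.method,
            "r": c.r,
            "p_value": c.p_value,
            "n": c.n,
            "significant": c.significant,
        }
        for c in correlations
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
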