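"""Delimited-text readers and writers for patient cards and result tables.

The canonical interchange format is a UTF-8 CSV with a header row, one row
per clinic visit, missing values as empty fields and dates as ISO 8601
(``YYYY-MM-DD``). Malformed rows are never silently dropped: the reader
collects them and raises an error naming every offending row number.
"""

from __future__ import annotations

import datetime
import logging
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .types import DischargeStatus, Facility, Oedema, PatientCard, RunConfig, Sex, VisitRecord

log = logging.getLogger(__name__)

#: Column order of the patient-card CSV.
CARD_COLUMNS = [
    "card_id",
    "country",
    "facility",
    "sex",
    "age_months",
    "visit_date",
    "muac_mm",
    "weight_kg",
    "height_cm",
    "oedema",
]

_OPTIONAL_COLUMNS = {"discharge_status"}


class SchemaError(ValueError):
    """The file header does not match the expected card schema."""


class DuplicateRecordError(ValueError):
    """Two visits share the same (card_id, visit_date)."""


class MalformedRowError(ValueError):
    """One or more rows failed to parse; carries 1-based data row numbers."""

    def __init__(self, problems: List[tuple]):
        self.problems = problems
        msg = "; ".join(f"row {r}: {why}" for r, why in problems)
        super().__init__(f"{len(problems)} malformed row(s): {msg}")


_OEDEMA_IN = {
    "": Oedema.MISSING,
    "0": Oedema.ABSENT,
    "1": Oedema.PRESENT,
    "2": Oedema.PRESENT,
    "3": Oedema.PRESENT,
}
_OEDEMA_OUT = {Oedema.MISSING: "", Oedema.ABSENT: "0", Oedema.PRESENT: "1"}


def _parse_row(row: Dict[str, str], rownum: int, problems: list):
    def fail(why: str):
        problems.append((rownum, why))

    out: Dict[str, object] = {}
    out["card_id"] = row["card_id"].strip()
    if not out["card_id"]:
        fail("empty card_id")
        return None
    out["country"] = row["country"].strip()
    try:
        out["facility"] = Facility(row["facility"].strip().upper())
    except ValueError:
        fail(f"unknown facility {row['facility']!r}")
        return None
    sex = row["sex"].strip().upper()
    if sex == "":
        out["sex"] = None
    elif sex in ("F", "M"):
        out["sex"] = Sex(sex)
    else:
        fail(f"unknown sex {sex!r}")
        return None

    def num(field: str, conv, what: str):
        raw = row[field].strip()
        if raw == "":
            return None
        try:
            return conv(raw)
        except ValueError:
            fail(f"unparseable {what} {raw!r}")
            return None

    out["age_months"] = num("age_months", int, "age")
    date_raw = row["visit_date"].strip()
    if date_raw == "":
        out["visit_date"] = None
    elif _iso_like(date_raw):
        try:
            out["visit_date"] = datetime.date.fromisoformat(date_raw)
        except ValueError:
            fail(f"unparseable date {date_raw!r}")
            return None
    else:
        fail(f"unparseable date {date_raw!r}")
        return None
    out["muac"] = num("muac_mm", int, "muac")
    out["weight"] = num("weight_kg", float, "weight")
    out["height"] = num("height_cm", float, "height")
    oed = row["oedema"].strip()
    out["oedema"] = _OEDEMA_IN.get(oed)
    if out["oedema"] is None:
        fail(f"unknown oedema code {oed!r}")
        return None
    ds = row.get("discharge_status", "").strip().lower()
    out["discharge_status"] = DischargeStatus(ds) if ds else DischargeStatus.UNKNOWN
    if problems and problems[-1][0] == rownum:
        return None
    return out


def _iso_like(s: str) -> bool:
    parts = s.split("-")
    return len(parts) == 3 and all(p.isdigit() for p in parts) and len(parts[0]) == 4


def read_patient_cards(path, schema: Optional[Dict[str, str]] = None) -> List[PatientCard]:
    """Read a patient-card CSV into a list of :class:`PatientCard`.

    Parameters
    ----------
    path : str or path-like
    schema : dict, optional
        Mapping from the file's column names to the canonical ones in
        :data:`CARD_COLUMNS`, for files with renamed headers.

    Raises
    ------
    SchemaError
        If a mandatory column is absent after applying ``schema``.
    MalformedRowError
        Listing the 1-based data row number of every unparseable row.
    DuplicateRecordError
        If a card has two visits on the same date.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in CARD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    problems: list = []
    parsed = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        rec = _parse_row(row, i, problems)
        if rec is not None:
            parsed.append(rec)
    if problems:
        raise MalformedRowError(problems)

    cards: List[PatientCard] = []
    order: List[str] = []
    by_id: Dict[str, list] = {}
    for rec in parsed:
        cid = rec["card_id"]
        if cid not in by_id:
            by_id[cid] = []
            order.append(cid)
        by_id[cid].append(rec)

    for cid in order:
        recs = by_id[cid]
        dates = [r["visit_date"] for r in recs if r["visit_date"] is not None]
        if len(dates) != len(set(dates)):
            seen = set()
            dup = next(d for d in dates if d in seen or seen.add(d))
            raise DuplicateRecordError(f"card {cid!r} has two visits dated {dup}")
        head = recs[0]
        visits = tuple(
            VisitRecord(
                visit_date=r["visit_date"],
                muac=r["muac"],
                weight=r["weight"],
                height=r["height"],
                oedema=r["oedema"],
            )
            for r in recs
        )
        cards.append(
            PatientCard(
                card_id=cid,
                country=head["country"],
                facility=head["facility"],
                age_months=head["age_months"],
                sex=head["sex"],
                visits=visits,
                discharge_status=head["discharge_status"],
            )
        )
    log.info("read %d cards (%d visits) from %s", len(cards), len(parsed), path)
    return cards


def write_patient_cards(cards: Sequence[PatientCard], path) -> None:
    """Write cards to the canonical CSV, one row per visit."""
    rows = []
    for c in cards:
        for v in c.visits:
            rows.append(
                {
                    "card_id": c.card_id,
                    "country": c.country,
                    "facility": c.facility.value,
                    "sex": "" if c.sex is None else c.sex.value,
                    "age_months": "" if c.age_months is None else c.age_months,
                    "visit_date": "" if v.visit_date is None else v.visit_date.isoformat(),
                    "muac_mm": "" if v.muac is None else v.muac,
                    "weight_kg": "" if v.weight is None else f"{v.weight:.1f}",
                    "height_cm": "" if v.height is None else f"{v.height:.1f}",
                    "oedema": _OEDEMA_OUT[v.oedema],
                    "discharge_status": c.discharge_status.value,
                }
            )
    pd.DataFrame(rows, columns=CARD_COLUMNS + ["discharge_status"]).to_csv(path, index=False)


# Fixed numeric formatting for result tables, keyed by column-name fragment:
# velocities and gains to 2 dp, kcal to whole numbers, percentages to 1 dp.
def _format_value(col: str, v):
    if pd.isna(v):
        return ""
    c = col.lower()
    if "kcal" in c:
        return f"{float(v):.0f}"
    if "velocity" in c or "gain" in c or "slope" in c:
        return f"{float(v):.2f}"
    if "percent" in c or "pct" in c or c.endswith("_frac"):
        return f"{float(v):.1f}"
    return v


def write_result_table(rows: pd.DataFrame, path) -> None:
    """Write a result table as CSV with the package's fixed numeric formats."""
    out = rows.copy()
    for col in out.columns:
        if pd.api.types.is_numeric_dtype(out[col]):
            out[col] = [_format_value(col, v) for v in out[col]]
    out.to_csv(path, index=False)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_run_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML key-value file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "muac_window" in raw:
        raw["muac_window"] = tuple(raw["muac_window"])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def write_run_config(cfg: RunConfig, path) -> None:
    import dataclasses

    import yaml

    d = dataclasses.asdict(cfg)
    d["muac_window"] = list(d["muac_window"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
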