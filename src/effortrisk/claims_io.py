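"""Table schemas and file I/O for claims, contacts, weights and reports.

All tables travel as UTF-8, comma-delimited, header-bearing text.  In
memory the canonical containers are :class:`pandas.DataFrame` objects
with the column layouts documented below; the row-level dataclasses
(:class:`ClaimRecord`, :class:`ContactEvent`) exist for construction and
validation of individual records.

claims.csv columns
    claim_id, household_id, member_id, service_date, diagnosis_codes,
    out_of_network, denied, adjusted

    ``service_date`` is an ISO-8601 calendar date.  ``diagnosis_codes``
    holds one or more codes separated by ";".  Booleans are serialized
    as ``true``/``false`` (case-insensitive on read).

contacts.csv columns
    household_id, channel, event_date          channel in {phone, web, mobile}

weights config (JSON or YAML by extension)
    calls_pct, denials_pct, web_mobile_pct, out_of_network_pct,
    adjustments_pct, household_pct             six percentages summing to 100
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import (
    IntegrityError,
    ParameterError,
    RowValidationError,
    SchemaError,
    WeightSumError,
)
from .rounding import format_fixed

# Canonical factor order used throughout the package (report column order).
FACTORS = (
    "household",
    "out_of_network",
    "adjustments",
    "denials",
    "calls",
    "web_mobile",
)

CHANNELS = ("phone", "web", "mobile")

CLAIMS_COLUMNS = [
    "claim_id",
    "household_id",
    "member_id",
    "service_date",
    "diagnosis_codes",
    "out_of_network",
    "denied",
    "adjusted",
]

CONTACTS_COLUMNS = ["household_id", "channel", "event_date"]

#: Table-3-shaped report layout: diagnosis label, six averages, total.
REPORT_COLUMNS = [
    "diagnosis",
    "avg_household_size",
    "avg_out_of_network",
    "avg_adjustments",
    "avg_denials",
    "avg_phone",
    "avg_web_mobile",
    "total_effort_risk",
]

_CODE_SEP = ";"
_BOOL_MAP = {"true": True, "false": False}


@dataclass(frozen=True)
class ClaimRecord:
    """One adjudicated claim line.

    ``diagnosis_codes`` is an ordered, non-empty tuple of opaque
    ICD-style code strings; the three flags record whether the provider
    was out of the plan's network, whether payment was denied, and
    whether the claim needed reprocessing (adjustment).
    """

    claim_id: str
    household_id: str
    member_id: str
    service_date: dt.date
    diagnosis_codes: tuple[str, ...]
    out_of_network: bool
    denied: bool
    adjusted: bool

    def __post_init__(self) -> None:
        if not self.diagnosis_codes or any(not c for c in self.diagnosis_codes):
            raise RowValidationError(
                f"claim {self.claim_id!r} has an empty diagnosis code list or code"
            )


@dataclass(frozen=True)
class ContactEvent:
    """One consumer inquiry to the payer's contact center."""

    household_id: str
    channel: str  # phone | web | mobile
    event_date: dt.date

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise RowValidationError(
                f"unknown contact channel {self.channel!r}; expected one of {CHANNELS}"
            )


@dataclass(frozen=True)
class EffortWeights:
    """The six expert-elicited percentage weights.

    Total consumer effort is defined as 100%, so the six percentages
    must sum to exactly 100 (within 1e-9) and be non-negative.
    """

    calls_pct: float
    denials_pct: float
    web_mobile_pct: float
    out_of_network_pct: float
    adjustments_pct: float
    household_pct: float

    def __post_init__(self) -> None:
        vals = self.as_dict()
        for key, v in vals.items():
            if v < 0:
                raise ParameterError(f"weight {key} is negative: {v!r}")
        total = math.fsum(vals.values())
        if abs(total - 100.0) > 1e-9:
            raise WeightSumError(total)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def fraction(self, factor: str) -> float:
        """Weight of a canonical factor name as a fraction of 1."""
        return getattr(self, f"{factor}_pct") / 100.0


WEIGHT_KEYS = tuple(f"{f}_pct" for f in FACTORS)


# ---------------------------------------------------------------------------
# frame <-> record conversion and validation

def claims_to_frame(records: Iterable[ClaimRecord]) -> pd.DataFrame:
    records = list(records)
    frame = pd.DataFrame(
        {
            "claim_id": [r.claim_id for r in records],
            "household_id": [r.household_id for r in records],
            "member_id": [r.member_id for r in records],
            "service_date": [r.service_date for r in records],
            "diagnosis_codes": [r.diagnosis_codes for r in records],
            "out_of_network": pd.Series([r.out_of_network for r in records], dtype=bool),
            "denied": pd.Series([r.denied for r in records], dtype=bool),
            "adjusted": pd.Series([r.adjusted for r in records], dtype=bool),
        },
        columns=CLAIMS_COLUMNS,
    )
    return validate_claims(frame)


def frame_to_claims(frame: pd.DataFrame) -> list[ClaimRecord]:
    return [
        ClaimRecord(
            claim_id=row.claim_id,
            household_id=row.household_id,
            member_id=row.member_id,
            service_date=row.service_date,
            diagnosis_codes=tuple(row.diagnosis_codes),
            out_of_network=bool(row.out_of_network),
            denied=bool(row.denied),
            adjusted=bool(row.adjusted),
        )
        for row in frame.itertuples(index=False)
    ]


def contacts_to_frame(events: Iterable[ContactEvent]) -> pd.DataFrame:
    events = list(events)
    frame = pd.DataFrame(
        {
            "household_id": [e.household_id for e in events],
            "channel": [e.channel for e in events],
            "event_date": [e.event_date for e in events],
        },
        columns=CONTACTS_COLUMNS,
    )
    return validate_contacts(frame)


def frame_to_contacts(frame: pd.DataFrame) -> list[ContactEvent]:
    return [
        ContactEvent(row.household_id, row.channel, row.event_date)
        for row in frame.itertuples(index=False)
    ]


def _check_columns(frame: pd.DataFrame, expected: Sequence[str], what: str) -> None:
    missing = [c for c in expected if c not in frame.columns]
    unknown = [c for c in frame.columns if c not in expected]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")
    if unknown:
        raise SchemaError(f"{what} table has unknown column(s): {', '.join(unknown)}")


def validate_claims(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a claims frame in place and return it.

    Checks the column set, claim_id uniqueness, non-empty diagnosis
    code lists, and that no member_id appears under two household_ids.
    """
    _check_columns(frame, CLAIMS_COLUMNS, "claims")
    if frame.empty:
        return frame
    dup = frame["claim_id"].duplicated()
    if dup.any():
        offenders = frame.loc[dup, "claim_id"].unique().tolist()
        raise IntegrityError(
            f"duplicate claim_id(s): {offenders[:5]}", offenders=offenders
        )
    for pos, codes in enumerate(frame["diagnosis_codes"]):
        if len(codes) == 0 or any(not c for c in codes):
            raise RowValidationError("empty diagnosis code field", row=pos + 1)
    hh_per_member = frame.groupby("member_id", sort=False)["household_id"].nunique()
    bad = hh_per_member[hh_per_member > 1]
    if not bad.empty:
        raise IntegrityError(
            f"member_id(s) appear under more than one household: {bad.index.tolist()}",
            offenders=bad.index.tolist(),
        )
    return frame


def validate_contacts(frame: pd.DataFrame) -> pd.DataFrame:
    _check_columns(frame, CONTACTS_COLUMNS, "contacts")
    bad = ~frame["channel"].isin(CHANNELS)
    if bad.any():
        first = int(bad.idxmax())
        raise RowValidationError(
            f"unknown channel {frame.loc[first, 'channel']!r}; "
            f"expected one of {CHANNELS}",
            row=first + 1,
        )
    return frame


# ---------------------------------------------------------------------------
# readers / writers

def _parse_bool(value: str, column: str, row: int) -> bool:
    try:
        return _BOOL_MAP[str(value).strip().lower()]
    except KeyError:
        raise RowValidationError(
            f"column {column!r}: cannot parse boolean from {value!r}", row=row
        ) from None


def _parse_date(value: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise RowValidationError(f"invalid ISO date {value!r}", row=row) from None


def read_claims(path: str | Path) -> pd.DataFrame:
    """Read and validate a claims.csv file.

    Returns the canonical claims frame (row order preserved).  Multiple
    diagnosis codes are split on ";" into a tuple.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(raw, CLAIMS_COLUMNS, "claims")
    n = len(raw)
    frame = pd.DataFrame(
        {
            "claim_id": raw["claim_id"],
            "household_id": raw["household_id"],
            "member_id": raw["member_id"],
            "service_date": [
                _parse_date(v, i + 1) for i, v in enumerate(raw["service_date"])
            ],
            "diagnosis_codes": [
                _split_codes(v, i + 1) for i, v in enumerate(raw["diagnosis_codes"])
            ],
            "out_of_network": pd.Series(
                [_parse_bool(v, "out_of_network", i + 1)
                 for i, v in enumerate(raw["out_of_network"])], dtype=bool),
            "denied": pd.Series(
                [_parse_bool(v, "denied", i + 1)
                 for i, v in enumerate(raw["denied"])], dtype=bool),
            "adjusted": pd.Series(
                [_parse_bool(v, "adjusted", i + 1)
                 for i, v in enumerate(raw["adjusted"])], dtype=bool),
        },
        columns=CLAIMS_COLUMNS,
    )
    if n == 0:
        frame = frame.astype({c: object for c in ["service_date", "diagnosis_codes"]})
    return validate_claims(frame)


def _split_codes(value: str, row: int) -> tuple[str, ...]:
    codes = tuple(c.strip() for c in str(value).split(_CODE_SEP) if c.strip())
    if not codes:
        raise RowValidationError("empty diagnosis code field", row=row)
    return codes


def write_claims(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a claims frame to CSV in the documented dialect."""
    validate_claims(frame)
    out = pd.DataFrame(
        {
            "claim_id": frame["claim_id"],
            "household_id": frame["household_id"],
            "member_id": frame["member_id"],
            "service_date": [d.isoformat() for d in frame["service_date"]],
            "diagnosis_codes": [_CODE_SEP.join(c) for c in frame["diagnosis_codes"]],
            "out_of_network": _render_bool(frame["out_of_network"]),
            "denied": _render_bool(frame["denied"]),
            "adjusted": _render_bool(frame["adjusted"]),
        },
        columns=CLAIMS_COLUMNS,
    )
    out.to_csv(path, index=False)


def _render_bool(series: pd.Series) -> list[str]:
    return ["true" if v else "false" for v in series]


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Read and validate a contacts.csv file."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(raw, CONTACTS_COLUMNS, "contacts")
    frame = pd.DataFrame(
        {
            "household_id": raw["household_id"],
            "channel": raw["channel"],
            "event_date": [
                _parse_date(v, i + 1) for i, v in enumerate(raw["event_date"])
            ],
        },
        columns=CONTACTS_COLUMNS,
    )
    return validate_contacts(frame)


def write_contacts(frame: pd.DataFrame, path: str | Path) -> None:
    validate_contacts(frame)
    out = frame.copy()
    out["event_date"] = [d.isoformat() for d in frame["event_date"]]
    out.to_csv(path, index=False)


def read_weights(path: str | Path) -> EffortWeights:
    """Read an EffortWeights config (JSON or YAML by file extension).

    The file must map exactly the six ``*_pct`` keys to percentages
    summing to 100.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"weights config {path} is not a key->number mapping")
    missing = [k for k in WEIGHT_KEYS if k not in data]
    if missing:
        raise SchemaError(f"weights config is missing key(s): {', '.join(missing)}")
    unknown = [k for k in data if k not in WEIGHT_KEYS]
    if unknown:
        raise SchemaError(f"weights config has unknown key(s): {', '.join(unknown)}")
    return EffortWeights(**{k: float(v) for k, v in data.items()})


def write_weights(weights: EffortWeights, path: str | Path) -> None:
    path = Path(path)
    data = weights.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def write_report(scores: pd.DataFrame, path: str | Path) -> None:
    """Write ranked effort scores as a tab-delimited report.

    ``scores`` is the frame produced by ``effort_scoring.rank_diagnoses``
    (columns ``diagnosis`` plus ``mean_<factor>`` for the six factors and
    ``total``).  Output has the eight report columns, all numbers
    rendered half-up to two decimals, rows in descending total order.
    """
    ordered = scores.sort_values(
        ["total", "diagnosis"], ascending=[False, True], kind="mergesort"
    )
    out = pd.DataFrame(
        {
            "diagnosis": ordered["diagnosis"],
            "avg_household_size": _fmt(ordered["mean_household"]),
            "avg_out_of_network": _fmt(ordered["mean_out_of_network"]),
            "avg_adjustments": _fmt(ordered["mean_adjustments"]),
            "avg_denials": _fmt(ordered["mean_denials"]),
            "avg_phone": _fmt(ordered["mean_calls"]),
            "avg_web_mobile": _fmt(ordered["mean_web_mobile"]),
            "total_effort_risk": _fmt(ordered["total"]),
        },
        columns=REPORT_COLUMNS,
    )
    out.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report.tsv back into a frame (numbers as floats)."""
    frame = pd.read_csv(path, sep="\t")
    _check_columns(frame, REPORT_COLUMNS, "report")
    return frame


def _fmt(series: pd.Series) -> list[str]:
    return [format_fixed(v) for v in series]
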