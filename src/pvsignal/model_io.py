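"""Domain types for spontaneous adverse-event reports and their exchange formats.

A :class:`Report` models one FAERS-style spontaneous report: the products the
reporter implicated (suspected) or merely recorded (concomitant), the reaction
list coded as MedDRA Preferred Terms (PTs), patient demographics, and the
regulatory seriousness outcomes. Reports travel as CSV with ``|``-delimited
multi-valued cells, or as an equivalent JSON-lines dialect; both round-trip
losslessly. A :class:`Vocabulary` maps PTs to System Organ Classes (SOCs).

Labels (products, ingredients, PTs) are stored as read; all comparisons in the
pipeline go through :func:`canon`, which trims, collapses whitespace and
case-folds, because dashboard exports vary in casing.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

UNSPECIFIED = "unspecified"
SEXES = ("female", "male", UNSPECIFIED)
REPORTER_TYPES = ("consumer", "healthcare_professional", UNSPECIFIED)

#: Regulatory seriousness outcome categories, in the default severity order
#: used for mutually exclusive classification (see :mod:`pvsignal.preprocess`).
OUTCOME_CATEGORIES = (
    "death",
    "life_threatening",
    "hospitalization",
    "disability",
    "congenital_anomaly",
    "required_intervention",
    "other",
    "non_serious",
)

MAX_AGE_YEARS = 130.0

REPORT_COLUMNS = (
    "case_id",
    "suspect_products",
    "suspect_ingredients",
    "concomitant_products",
    "reactions",
    "sex",
    "age_years",
    "reporter_type",
    "country",
    "event_date",
    "outcomes",
)

DELIM = "|"

_SEX_ALIASES = {
    "female": "female",
    "f": "female",
    "male": "male",
    "m": "male",
    "": UNSPECIFIED,
    "unspecified": UNSPECIFIED,
    "not specified": UNSPECIFIED,
    "unknown": UNSPECIFIED,
}

_REPORTER_ALIASES = {
    "consumer": "consumer",
    "healthcare_professional": "healthcare_professional",
    "healthcare professional": "healthcare_professional",
    "hcp": "healthcare_professional",
    "": UNSPECIFIED,
    "unspecified": UNSPECIFIED,
    "not specified": UNSPECIFIED,
    "unknown": UNSPECIFIED,
}

_OUTCOME_ALIASES = {
    "death": "death",
    "died": "death",
    "life_threatening": "life_threatening",
    "life threatening": "life_threatening",
    "hospitalization": "hospitalization",
    "hospitalizations": "hospitalization",
    "hospitalisation": "hospitalization",
    "disability": "disability",
    "disabled": "disability",
    "congenital_anomaly": "congenital_anomaly",
    "congenital anomaly": "congenital_anomaly",
    "required_intervention": "required_intervention",
    "required intervention": "required_intervention",
    "other": "other",
    "other outcomes": "other",
    "other_outcomes": "other",
    "non_serious": "non_serious",
    "non-serious": "non_serious",
    "non serious": "non_serious",
}


class SchemaError(ValueError):
    """A file does not conform to the report-exchange or vocabulary schema."""


def canon(text: str) -> str:
    """Canonical form of a label: whitespace-collapsed, trimmed, case-folded."""
    return " ".join(str(text).split()).casefold()


@dataclass
class Product:
    """One product mentioned in a report.

    ``role`` distinguishes the product(s) the reporter implicated in the event
    (``suspected``) from other medication the patient was taking
    (``concomitant``).
    """

    name: str
    active_ingredient: str = ""
    role: str = "suspected"

    def __post_init__(self) -> None:
        if not str(self.name).strip():
            raise ValueError("product name must be non-empty")
        if self.role not in ("suspected", "concomitant"):
            raise ValueError(f"invalid product role {self.role!r}")


@dataclass
class Report:
    """One spontaneous adverse-event report (one version of one case)."""

    case_id: str
    products: list[Product]
    reactions: list[str]
    sex: str = UNSPECIFIED
    age_years: Optional[float] = None
    reporter_type: str = UNSPECIFIED
    country: str = UNSPECIFIED
    event_date: Optional[datetime.date] = None
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not str(self.case_id).strip():
            raise ValueError("case_id must be non-empty")
        if not any(p.role == "suspected" for p in self.products):
            raise ValueError(f"report {self.case_id}: needs >=1 suspected product")
        # canonical storage order: suspected first, concomitant after
        # (within-role order preserved; makes round-trips order-stable)
        self.products = [p for p in self.products if p.role == "suspected"] + [
            p for p in self.products if p.role == "concomitant"
        ]
        if not self.reactions:
            raise ValueError(f"report {self.case_id}: needs >=1 reaction")
        if self.age_years is not None:
            self.age_years = float(self.age_years)
            if not (0.0 <= self.age_years <= MAX_AGE_YEARS):
                raise ValueError(
                    f"report {self.case_id}: age {self.age_years} outside [0, {MAX_AGE_YEARS}]"
                )
        if self.sex not in SEXES:
            raise ValueError(f"report {self.case_id}: invalid sex {self.sex!r}")
        if self.reporter_type not in REPORTER_TYPES:
            raise ValueError(
                f"report {self.case_id}: invalid reporter_type {self.reporter_type!r}"
            )
        self.outcomes = frozenset(self.outcomes)
        unknown = self.outcomes - set(OUTCOME_CATEGORIES)
        if unknown:
            raise ValueError(
                f"report {self.case_id}: unknown outcome token(s) {sorted(unknown)}"
            )

    @property
    def suspected(self) -> list[Product]:
        return [p for p in self.products if p.role == "suspected"]

    @property
    def concomitant(self) -> list[Product]:
        return [p for p in self.products if p.role == "concomitant"]

    def reaction_set(self) -> frozenset[str]:
        """Canonicalised reaction PTs (each PT counted once per report)."""
        return frozenset(canon(r) for r in self.reactions)


@dataclass
class Provenance:
    """Stage counters accumulated along the preprocessing pipeline."""

    n_raw: Optional[int] = None
    n_after_dedup: Optional[int] = None
    n_excluded_multidrug: Optional[int] = None
    n_final: Optional[int] = None
    n_parse_warnings: int = 0

    def validate(self) -> None:
        if (
            self.n_after_dedup is not None
            and self.n_excluded_multidrug is not None
            and self.n_final is not None
        ):
            if self.n_final != self.n_after_dedup - self.n_excluded_multidrug:
                raise ValueError(
                    "provenance inconsistent: "
                    f"n_final={self.n_final} != n_after_dedup={self.n_after_dedup}"
                    f" - n_excluded_multidrug={self.n_excluded_multidrug}"
                )


@dataclass
class ReportSet:
    """Ordered collection of reports plus pipeline provenance counters."""

    reports: list[Report] = field(default_factory=list)
    provenance: Provenance = field(default_factory=Provenance)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def __getitem__(self, i):
        return self.reports[i]


@dataclass
class Vocabulary:
    """PT -> System Organ Class mapping (a fixture standing in for MedDRA).

    Keys are canonicalised PTs; values keep display casing. Unknown PTs are
    surfaced to the caller (``soc_of`` returns ``None``), never dropped.
    """

    pt_to_soc: dict[str, str]

    def __len__(self) -> int:
        return len(self.pt_to_soc)

    def soc_of(self, pt: str) -> Optional[str]:
        return self.pt_to_soc.get(canon(pt))


# ---------------------------------------------------------------------------
# parsing helpers


def _split_cell(cell: str) -> list[str]:
    return [tok.strip() for tok in str(cell).split(DELIM) if tok.strip()]


def _split_cell_positional(cell: str) -> list[str]:
    """Split keeping empty slots (ingredients align with product positions)."""
    s = str(cell)
    if not s.strip():
        return []
    return [tok.strip() for tok in s.split(DELIM)]


def _parse_sex(token: str, warn: list[int]) -> str:
    key = canon(token)
    if key in _SEX_ALIASES:
        return _SEX_ALIASES[key]
    warn[0] += 1
    logger.warning("unrecognised sex token %r -> unspecified", token)
    return UNSPECIFIED


def _parse_reporter(token: str, warn: list[int]) -> str:
    key = canon(token)
    if key in _REPORTER_ALIASES:
        return _REPORTER_ALIASES[key]
    warn[0] += 1
    logger.warning("unrecognised reporter token %r -> unspecified", token)
    return UNSPECIFIED


def _parse_age(token, warn: list[int]) -> Optional[float]:
    if token is None:
        return None
    s = str(token).strip()
    if not s:
        return None
    try:
        age = float(s)
    except ValueError:
        warn[0] += 1
        logger.warning("unparseable age %r -> missing", token)
        return None
    if not (0.0 <= age <= MAX_AGE_YEARS):
        warn[0] += 1
        logger.warning("out-of-range age %r -> missing", token)
        return None
    return age


def _parse_date(token, warn: list[int]) -> Optional[datetime.date]:
    """ISO-8601 (YYYY-MM-DD) only; anything else is missing-with-warning."""
    if token is None:
        return None
    s = str(token).strip()
    if not s:
        return None
    try:
        return datetime.date.fromisoformat(s)
    except ValueError:
        warn[0] += 1
        logger.warning("unparseable event date %r -> missing", token)
        return None


def _parse_outcomes(tokens: Sequence[str]) -> frozenset[str]:
    out = set()
    for tok in tokens:
        key = canon(tok)
        if key not in _OUTCOME_ALIASES:
            raise SchemaError(f"unknown outcome token {tok!r}")
        out.add(_OUTCOME_ALIASES[key])
    return frozenset(out)


def _record_to_report(rec: dict, warn: list[int]) -> Report:
    """Build a Report from one parsed record (lists already split)."""
    sus_names = rec["suspect_products"]
    sus_ings = rec["suspect_ingredients"]
    if len(sus_ings) < len(sus_names):
        sus_ings = sus_ings + [""] * (len(sus_names) - len(sus_ings))
    products = [
        Product(name=n, active_ingredient=i, role="suspected")
        for n, i in zip(sus_names, sus_ings)
    ]
    products += [
        Product(name=n, role="concomitant") for n in rec["concomitant_products"]
    ]
    country = str(rec.get("country") or "").strip() or UNSPECIFIED
    return Report(
        case_id=str(rec["case_id"]).strip(),
        products=products,
        reactions=list(rec["reactions"]),
        sex=_parse_sex(rec.get("sex") or "", warn),
        age_years=_parse_age(rec.get("age_years"), warn),
        reporter_type=_parse_reporter(rec.get("reporter_type") or "", warn),
        country=country,
        event_date=_parse_date(rec.get("event_date"), warn),
        outcomes=_parse_outcomes(rec.get("outcomes") or []),
    )


def read_reports(path, format: str = "csv") -> ReportSet:
    """Read a report file into a :class:`ReportSet`.

    Parameters
    ----------
    path
        File in the repository exchange dialect.
    format
        ``"csv"`` (``|``-delimited multi-valued cells) or ``"jsonl"``
        (one JSON object per line, list-valued fields).

    Unparseable ages and dates become missing and increment
    ``provenance.n_parse_warnings``; missing mandatory columns and empty
    files are hard errors.
    """
    path = Path(path)
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")
    warn = [0]
    records: list[dict] = []
    if format == "csv":
        try:
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise SchemaError(f"{path}: no records") from None
        missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        if frame.empty:
            raise SchemaError(f"{path}: no records")
        for row in frame.itertuples(index=False):
            rec = dict(zip(frame.columns, row))
            for col in (
                "suspect_products",
                "concomitant_products",
                "reactions",
                "outcomes",
            ):
                rec[col] = _split_cell(rec[col])
            rec["suspect_ingredients"] = _split_cell_positional(
                rec["suspect_ingredients"]
            )
            records.append(rec)
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
        if not records:
            raise SchemaError(f"{path}: no records")
        for rec in records:
            missing = [c for c in REPORT_COLUMNS if c not in rec]
            if missing:
                raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    reports = [_record_to_report(rec, warn) for rec in records]
    rs = ReportSet(
        reports=reports,
        provenance=Provenance(n_raw=len(reports), n_parse_warnings=warn[0]),
    )
    if warn[0]:
        logger.warning("%s: %d field-level parse warnings", path, warn[0])
    return rs


def _report_to_record(r: Report) -> dict:
    return {
        "case_id": r.case_id,
        "suspect_products": [p.name for p in r.suspected],
        "suspect_ingredients": [p.active_ingredient for p in r.suspected],
        "concomitant_products": [p.name for p in r.concomitant],
        "reactions": list(r.reactions),
        "sex": r.sex,
        "age_years": r.age_years,
        "reporter_type": r.reporter_type,
        "country": "" if r.country == UNSPECIFIED else r.country,
        "event_date": r.event_date.isoformat() if r.event_date else "",
        "outcomes": sorted(r.outcomes, key=OUTCOME_CATEGORIES.index),
    }


def write_reports(reports: ReportSet, path, format: str = "csv") -> None:
    """Write a ReportSet so that :func:`read_reports` reproduces it exactly.

    Multi-valued cells are ``|``-joined; a value containing the delimiter
    cannot round-trip and is a hard error.
    """
    path = Path(path)
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")
    records = [_report_to_record(r) for r in reports]
    for rec in records:
        for col in (
            "suspect_products",
            "suspect_ingredients",
            "concomitant_products",
            "reactions",
        ):
            for tok in rec[col]:
                if DELIM in tok:
                    raise ValueError(
                        f"value {tok!r} contains the reserved delimiter {DELIM!r}"
                    )
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
            writer.writeheader()
            for rec in records:
                row = dict(rec)
                for col in (
                    "suspect_products",
                    "suspect_ingredients",
                    "concomitant_products",
                    "reactions",
                    "outcomes",
                ):
                    row[col] = DELIM.join(row[col])
                if row["age_years"] is None:
                    row["age_years"] = ""
                writer.writerow(row)
    else:
        with open(path, "w") as fh:
            for rec in records:
                fh.write(json.dumps(rec) + "\n")


def load_vocabulary(path) -> Vocabulary:
    """Load a two-column ``pt,soc`` table into a :class:`Vocabulary`.

    Duplicate consistent rows are deduplicated silently; duplicate PTs with
    conflicting SOCs are a hard error (every PT maps to exactly one SOC).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty vocabulary") from None
    for col in ("pt", "soc"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing mandatory column(s) ['{col}']")
    if frame.empty:
        raise SchemaError(f"{path}: empty vocabulary")
    mapping: dict[str, str] = {}
    for pt, soc in zip(frame["pt"], frame["soc"]):
        key = canon(pt)
        soc = str(soc).strip()
        if key in mapping and canon(mapping[key]) != canon(soc):
            raise SchemaError(
                f"{path}: PT {pt!r} maps to both {mapping[key]!r} and {soc!r}"
            )
        mapping.setdefault(key, soc)
    return Vocabulary(pt_to_soc=mapping)


__all__ = [
    "Product",
    "Report",
    "ReportSet",
    "Provenance",
    "Vocabulary",
    "SchemaError",
    "canon",
    "read_reports",
    "write_reports",
    "load_vocabulary",
    "OUTCOME_CATEGORIES",
    "SEXES",
    "REPORTER_TYPES",
    "UNSPECIFIED",
    "REPORT_COLUMNS",
]
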