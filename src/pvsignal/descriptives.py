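"""Descriptive summaries of analysed report sets.

Frequency tables (count and percent of a stated denominator), the drug
ranking, the target-vs-other characteristics table (sex, age bands, median
age, reporter type, country, mutually exclusive outcome), the top reported
events with their System Organ Class, the outcome distribution within a
drug-event subset, and the male-to-female reporting ratio.

All displayed percentages are rounded to 2 decimals with half-up rounding;
full precision is retained internally.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .model_io import ReportSet, UNSPECIFIED, Vocabulary, canon
from .preprocess import (
    DEFAULT_OUTCOME_PRECEDENCE,
    DrugCatalog,
    assign_canonical,
    classify_outcome,
)

logger = logging.getLogger(__name__)

AGE_BANDS = ("<18", "18-44", "45-64", ">=65", UNSPECIFIED)

_US_NAMES = {"us", "usa", "united states", "united states of america"}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of regulatory tables)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quant, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyRow:
    label: str
    count: int
    soc: Optional[str] = None


@dataclass
class FrequencyTable:
    """Rows of (label, count) against a single stated denominator."""

    group: str
    denominator: int
    rows: list[FrequencyRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.denominator < 0:
            raise ValueError("denominator must be >= 0")
        for row in self.rows:
            if row.count < 0 or row.count > self.denominator:
                raise ValueError(
                    f"count {row.count} for {row.label!r} outside [0, {self.denominator}]"
                )

    @classmethod
    def from_counts(
        cls, group: str, counts: Sequence[tuple], denominator: int
    ) -> "FrequencyTable":
        rows = [FrequencyRow(*item) for item in counts]
        return cls(group=group, denominator=denominator, rows=rows)

    def percent(self, label: str) -> float:
        """Displayed percent (2 dp, half-up) for one row label."""
        for row in self.rows:
            if canon(row.label) == canon(label):
                return self.percent_of(row.count)
        raise KeyError(label)

    def percent_of(self, count: int) -> float:
        if self.denominator == 0:
            return math.nan
        return round_half_up(100.0 * count / self.denominator)

    def count(self, label: str) -> int:
        for row in self.rows:
            if canon(row.label) == canon(label):
                return row.count
        raise KeyError(label)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "label": [r.label for r in self.rows],
            "count": [r.count for r in self.rows],
            "percent": [self.percent_of(r.count) for r in self.rows],
        }
        if any(r.soc is not None for r in self.rows):
            data["soc"] = [r.soc for r in self.rows]
        return pd.DataFrame(data)


def drug_ranking(reports: ReportSet, catalog: DrugCatalog) -> FrequencyTable:
    """Reports per canonical COVID-19 drug, descending, over all analysed reports."""
    labels = assign_canonical(reports, catalog)
    counts = Counter(lbl for lbl in labels if lbl is not None)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], canon(kv[0])))
    return FrequencyTable.from_counts("all drugs", rows, denominator=len(reports))


def age_band(age: Optional[float]) -> str:
    if age is None:
        return UNSPECIFIED
    if age < 18:
        return "<18"
    if age < 45:
        return "18-44"
    if age < 65:
        return "45-64"
    return ">=65"


def _country_bucket(country: str) -> str:
    key = canon(country)
    if key == UNSPECIFIED or not key:
        return UNSPECIFIED
    return "US" if key in _US_NAMES else "other"


def median_age(reports: Sequence) -> float:
    """Median over non-missing ages; midpoint of the two central values."""
    ages = sorted(r.age_years for r in reports if r.age_years is not None)
    if not ages:
        return math.nan
    mid = len(ages) // 2
    if len(ages) % 2:
        return float(ages[mid])
    return (ages[mid - 1] + ages[mid]) / 2.0


def _group_summary(
    name: str, group: list, precedence: Sequence[str]
) -> dict:
    n = len(group)
    sex = Counter(r.sex for r in group)
    bands = Counter(age_band(r.age_years) for r in group)
    reporter = Counter(r.reporter_type for r in group)
    country = Counter(_country_bucket(r.country) for r in group)
    outcome = Counter(classify_outcome(r, precedence) for r in group)
    return {
        "n": n,
        "sex": FrequencyTable.from_counts(
            name, [(s, sex.get(s, 0)) for s in ("female", "male", UNSPECIFIED)], n
        ),
        "age_bands": FrequencyTable.from_counts(
            name, [(b, bands.get(b, 0)) for b in AGE_BANDS], n
        ),
        "median_age": median_age(group),
        "reporter": FrequencyTable.from_counts(
            name,
            [
                (t, reporter.get(t, 0))
                for t in ("consumer", "healthcare_professional", UNSPECIFIED)
            ],
            n,
        ),
        "country": FrequencyTable.from_counts(
            name, [(c, country.get(c, 0)) for c in ("US", "other", UNSPECIFIED)], n
        ),
        "outcome": FrequencyTable.from_counts(
            name, [(c, outcome.get(c, 0)) for c in precedence], n
        ),
    }


def characteristics_table(
    reports: ReportSet,
    target_drug: str,
    catalog: DrugCatalog,
    precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE,
) -> dict:
    """Target-drug vs other-COVID-drug characteristics summary.

    Reports with no catalogued COVID-19 drug belong to neither column (the
    comparator column mirrors the published table: reports whose suspected
    drug is some *other* COVID-19 drug). Outcome rows are mutually exclusive
    and sum to each group's N.
    """
    labels = assign_canonical(reports, catalog)
    tdrug = canon(target_drug)
    target = [r for r, l in zip(reports, labels) if l and canon(l) == tdrug]
    other = [r for r, l in zip(reports, labels) if l and canon(l) != tdrug]
    return {
        "target": _group_summary(target_drug, target, precedence),
        "other": _group_summary("other COVID-19 drugs", other, precedence),
    }


def top_events(
    reports: ReportSet,
    drug: str,
    k: int,
    vocabulary: Vocabulary,
    catalog: DrugCatalog,
) -> FrequencyTable:
    """Top-k reaction PTs among the drug's reports, with SOC annotation.

    A report mentioning a PT any number of times increments that PT once;
    the percent denominator is the drug's report count. PTs absent from the
    vocabulary get SOC ``"UNMAPPED"`` with a warning.
    """
    labels = assign_canonical(reports, catalog)
    tdrug = canon(drug)
    group = [r for r, l in zip(reports, labels) if l and canon(l) == tdrug]
    counts: Counter = Counter()
    display: dict[str, str] = {}
    for rep in group:
        for raw in rep.reactions:
            display.setdefault(canon(raw), raw.strip())
        counts.update(rep.reaction_set())
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[: max(k, 0)]
    rows = []
    for pt_key, count in top:
        soc = vocabulary.soc_of(pt_key)
        if soc is None:
            logger.warning("PT %r not in vocabulary; SOC set to UNMAPPED", display[pt_key])
            soc = "UNMAPPED"
        rows.append((display[pt_key], count, soc))
    return FrequencyTable.from_counts(drug, rows, denominator=len(group))


def outcome_distribution(
    reports: ReportSet,
    drug: str,
    pt: str,
    catalog: DrugCatalog,
    precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE,
) -> FrequencyTable:
    """Mutually exclusive outcome distribution within one (drug, PT) subset."""
    labels = assign_canonical(reports, catalog)
    tdrug, tpt = canon(drug), canon(pt)
    subset = [
        r
        for r, l in zip(reports, labels)
        if l and canon(l) == tdrug and tpt in r.reaction_set()
    ]
    if not subset:
        logger.warning("no reports match drug=%r pt=%r; empty table", drug, pt)
        return FrequencyTable(group=f"{drug} / {pt}", denominator=0, rows=[])
    counts = Counter(classify_outcome(r, precedence) for r in subset)
    return FrequencyTable.from_counts(
        f"{drug} / {pt}",
        [(c, counts.get(c, 0)) for c in precedence],
        denominator=len(subset),
    )


def sex_ratio_from_counts(n_male: int, n_female: int) -> float:
    """Male-to-female reporting ratio; NaN (with warning) when no females."""
    if n_female == 0:
        logger.warning("sex ratio undefined: zero female reports")
        return math.nan
    return n_male / n_female


def sex_ratio(
    reports: ReportSet,
    catalog: DrugCatalog,
    drug: Optional[str] = None,
    rest: bool = False,
) -> float:
    """Male-to-female ratio for the drug's group (or, with rest=True, the
    other-COVID-drug group); full precision, display rounded by callers."""
    if drug is None:
        group = list(reports)
    else:
        labels = assign_canonical(reports, catalog)
        tdrug = canon(drug)
        if rest:
            group = [r for r, l in zip(reports, labels) if l and canon(l) != tdrug]
        else:
            group = [r for r, l in zip(reports, labels) if l and canon(l) == tdrug]
    counts = Counter(r.sex for r in group)
    return sex_ratio_from_counts(counts.get("male", 0), counts.get("female", 0))


__all__ = [
    "FrequencyRow",
    "FrequencyTable",
    "round_half_up",
    "drug_ranking",
    "characteristics_table",
    "top_events",
    "outcome_distribution",
    "sex_ratio",
    "sex_ratio_from_counts",
    "median_age",
    "age_band",
    "AGE_BANDS",
]
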