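"""Report preprocessing: deduplication, combination normalisation, exclusion.

Spontaneous-report databases contain multiple versions of the same case under
different case IDs. Two reports are treated as duplicates when eight fields
match after canonicalisation: suspected product name(s), suspected active
ingredient(s), reactions, sex, age, reporting country, event date, and
concomitant product name(s). Within a collision group the report with the
lexicographically smallest case ID is kept (deterministic and
order-independent).

Combination therapies (e.g. nirmatrelvir + ritonavir) are normalised to a
single canonical label from a :class:`DrugCatalog` before counting distinct
COVID-19 drugs; reports left with two or more distinct COVID-19 drugs among
the suspected products are excluded so each analysed report attributes its
events to at most one drug.

Seriousness outcomes are classified into exactly one of the eight regulatory
categories using a configurable precedence order (most severe wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .model_io import (
    OUTCOME_CATEGORIES,
    Provenance,
    Report,
    ReportSet,
    canon,
)

logger = logging.getLogger(__name__)

MISSING = "<missing>"

#: Default severity precedence for mutually exclusive outcome classification.
DEFAULT_OUTCOME_PRECEDENCE = OUTCOME_CATEGORIES


@dataclass(frozen=True)
class DrugEntry:
    """One catalogued drug: canonical label, ingredient set, synonyms.

    An entry with two or more ingredients is a combination therapy; its
    ingredient set collapses to the single canonical label.
    """

    label: str
    ingredients: tuple[str, ...]
    synonyms: tuple[str, ...] = ()

    @property
    def is_combination(self) -> bool:
        return len(self.ingredients) >= 2


@dataclass
class DrugCatalog:
    """Catalogue of COVID-19 drugs and their combination normalisations."""

    drugs: list[DrugEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [canon(d.label) for d in self.drugs]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate canonical labels in drug catalog")
        combo_keys = [frozenset(canon(i) for i in d.ingredients) for d in self.drugs if d.is_combination]
        if len(combo_keys) != len(set(combo_keys)):
            raise ValueError("combination ingredient-sets must be distinct")

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.drugs]

    def has_label(self, label: str) -> bool:
        key = canon(label)
        return any(canon(d.label) == key for d in self.drugs)

    @classmethod
    def from_dict(cls, data: dict) -> "DrugCatalog":
        entries = []
        for item in data["drugs"]:
            entries.append(
                DrugEntry(
                    label=item["label"],
                    ingredients=tuple(item.get("ingredients") or [item["label"]]),
                    synonyms=tuple(item.get("synonyms") or ()),
                )
            )
        return cls(drugs=entries)

    @classmethod
    def from_yaml(cls, path) -> "DrugCatalog":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_catalog() -> DrugCatalog:
    """The ten EUA COVID-19 drugs shipped with the package."""
    ref = resources.files("pvsignal.data").joinpath("catalog.yaml")
    return DrugCatalog.from_dict(yaml.safe_load(ref.read_text()))


def canonical_drug(report: Report, catalog: DrugCatalog) -> set[str]:
    """Canonical COVID-19 drug labels among a report's suspected products.

    Suspected product names and active ingredients are matched against the
    catalogue case-insensitively. Any subset of suspected ingredients exactly
    matching a combination's ingredient set collapses to that combination's
    single label (the ingredients are then consumed, so e.g. bamlanivimab
    within bamlanivimab/etesevimab does not additionally match the
    single-agent entry). Non-catalogued products pass through unmatched.
    """
    tokens = set()
    for p in report.suspected:
        tokens.add(canon(p.name))
        if str(p.active_ingredient).strip():
            tokens.add(canon(p.active_ingredient))
    tokens.discard("")

    labels: set[str] = set()
    # Combinations first, largest ingredient set first.
    for entry in sorted(
        (d for d in catalog.drugs if d.is_combination),
        key=lambda d: -len(d.ingredients),
    ):
        ing = {canon(i) for i in entry.ingredients}
        names = {canon(entry.label)} | {canon(s) for s in entry.synonyms}
        if ing <= tokens:
            labels.add(entry.label)
            tokens -= ing
        elif names & tokens:
            labels.add(entry.label)
            tokens -= names
    for entry in catalog.drugs:
        if entry.is_combination:
            continue
        names = {canon(entry.label)} | {canon(s) for s in entry.synonyms}
        names |= {canon(i) for i in entry.ingredients}
        if names & tokens:
            labels.add(entry.label)
            tokens -= names
    return labels


def dedup_key(report: Report) -> tuple:
    """The 8-field canonical matching key used for duplicate detection.

    Missing values are encoded as a sentinel distinct from any real value;
    age matches on the value rounded to integer years.
    """
    age = MISSING if report.age_years is None else int(round(report.age_years))
    country = canon(report.country)
    date = report.event_date.isoformat() if report.event_date else MISSING
    return (
        tuple(sorted(canon(p.name) for p in report.suspected)),
        tuple(
            sorted(
                canon(p.active_ingredient)
                for p in report.suspected
                if str(p.active_ingredient).strip()
            )
        ),
        tuple(sorted(report.reaction_set())),
        report.sex,
        age,
        country,
        date,
        tuple(sorted(canon(p.name) for p in report.concomitant)),
    )


def dedup_reports(reports: ReportSet) -> tuple[ReportSet, list[Report]]:
    """Remove duplicate report versions; keep one report per collision group.

    Returns the kept reports (input order preserved) and the removed ones.
    The survivor of each group is the report with the smallest case ID.
    """
    best: dict[tuple, int] = {}
    for idx, rep in enumerate(reports):
        key = dedup_key(rep)
        cur = best.get(key)
        if cur is None or rep.case_id < reports[cur].case_id:
            best[key] = idx
    keep_idx = set(best.values())
    kept = [r for i, r in enumerate(reports) if i in keep_idx]
    removed = [r for i, r in enumerate(reports) if i not in keep_idx]
    prov = Provenance(
        n_raw=reports.provenance.n_raw if reports.provenance.n_raw is not None else len(reports),
        n_after_dedup=len(kept),
        n_parse_warnings=reports.provenance.n_parse_warnings,
    )
    return ReportSet(reports=kept, provenance=prov), removed


def exclude_multidrug(
    reports: ReportSet, catalog: DrugCatalog
) -> tuple[ReportSet, list[Report]]:
    """Exclude reports whose suspected products span >= 2 distinct COVID drugs.

    Combination normalisation is applied first, so a catalogued combination
    counts as one drug and is never excluded on its own. Reports with no
    catalogued COVID-19 drug are kept (they serve as comparators).
    """
    kept, excluded = [], []
    for rep in reports:
        if len(canonical_drug(rep, catalog)) >= 2:
            excluded.append(rep)
        else:
            kept.append(rep)
    prov = Provenance(
        n_raw=reports.provenance.n_raw,
        n_after_dedup=reports.provenance.n_after_dedup
        if reports.provenance.n_after_dedup is not None
        else len(reports),
        n_excluded_multidrug=len(excluded),
        n_parse_warnings=reports.provenance.n_parse_warnings,
    )
    prov.n_final = prov.n_after_dedup - len(excluded)
    prov.validate()
    return ReportSet(reports=kept, provenance=prov), excluded


def assign_canonical(
    reports: ReportSet, catalog: DrugCatalog
) -> list[Optional[str]]:
    """Per-report canonical COVID-drug label (or None) after preprocessing.

    Raises if any report still carries two or more distinct COVID drugs,
    i.e. if :func:`exclude_multidrug` has not been applied.
    """
    out: list[Optional[str]] = []
    for rep in reports:
        labels = canonical_drug(rep, catalog)
        if len(labels) > 1:
            raise ValueError(
                f"report {rep.case_id} carries {sorted(labels)}; "
                "run exclude_multidrug first"
            )
        out.append(next(iter(labels)) if labels else None)
    return out


def classify_outcome(
    report: Report,
    precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE,
) -> str:
    """Map a report's outcome set to exactly one category.

    The highest-precedence category present wins; an empty outcome set is
    non-serious. Unknown tokens (in the report or the precedence list) are
    hard errors.
    """
    if set(precedence) != set(OUTCOME_CATEGORIES):
        raise ValueError("precedence must cover all 8 outcome categories")
    unknown = set(report.outcomes) - set(OUTCOME_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown outcome token(s) {sorted(unknown)}")
    if not report.outcomes:
        return "non_serious"
    rank = {cat: i for i, cat in enumerate(precedence)}
    return min(report.outcomes, key=lambda c: rank[c])


def preprocess_reports(
    reports: ReportSet, catalog: Optional[DrugCatalog] = None
) -> tuple[ReportSet, dict]:
    """Full preprocessing chain: dedup then multi-drug exclusion.

    Returns the clean ReportSet and a provenance log dictionary.
    """
    catalog = catalog or default_catalog()
    deduped, removed = dedup_reports(reports)
    clean, excluded = exclude_multidrug(deduped, catalog)
    log = {
        "n_raw": clean.provenance.n_raw,
        "n_after_dedup": clean.provenance.n_after_dedup,
        "n_excluded_multidrug": clean.provenance.n_excluded_multidrug,
        "n_final": clean.provenance.n_final,
        "n_parse_warnings": clean.provenance.n_parse_warnings,
        "removed_duplicate_case_ids": [r.case_id for r in removed],
        "excluded_multidrug_case_ids": [r.case_id for r in excluded],
    }
    logger.info(
        "preprocess: %s raw -> %s after dedup -> %s final (%s excluded multi-drug)",
        log["n_raw"],
        log["n_after_dedup"],
        log["n_final"],
        log["n_excluded_multidrug"],
    )
    return clean, log


__all__ = [
    "DrugEntry",
    "DrugCatalog",
    "default_catalog",
    "canonical_drug",
    "dedup_key",
    "dedup_reports",
    "exclude_multidrug",
    "assign_canonical",
    "classify_outcome",
    "preprocess_reports",
    "DEFAULT_OUTCOME_PRECEDENCE",
]
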