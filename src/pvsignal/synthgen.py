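"""Synthetic FAERS-like report generator with a known-truth ledger.

The generator emulates a COVID-19 EUA dashboard extract: each report draws
one suspected COVID-19 drug from configured marginals (or none), mentions
each reaction PT independently with probability

    p(drug, pt) = logit^-1( logit(baseline_pt) + log_OR(drug, pt) )

so the true drug-event reporting odds ratio for an injected effect is exactly
``exp(log_OR)``, draws demographics from configurable marginals with
per-field missingness, and injects two kinds of artefacts on purpose:
near-duplicate report versions (exact copies of the eight matching fields
under a fresh case ID) and multi-COVID-drug reports. Every injected artefact
and every true effect is recorded in a :class:`TruthLedger` so downstream
deduplication, exclusion and signal recovery can be tested against ground
truth.

Reports whose independent PT draws come up empty receive a padding PT
("Drug ineffective" by default) so the >=1-reaction invariant holds without
conditioning the modelled PT indicators on non-emptiness (which would bias
the recoverable odds ratios).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .model_io import (
    Product,
    Provenance,
    Report,
    ReportSet,
    UNSPECIFIED,
    canon,
)
from .preprocess import default_catalog

TARGET_DRUG = "Nirmatrelvir/Ritonavir"

_AGE_BAND_RANGES = {"<18": (0, 17), "18-44": (18, 44), "45-64": (45, 64), ">=65": (65, 95)}
_OTHER_COUNTRIES = ("CA", "GB", "FR", "DE", "JP")
_NON_COVID_SUSPECTS = ("Ibuprofen", "Amoxicillin", "Hydrochlorothiazide")
_SERIOUS_EXTRA_RATE = 0.15  # chance a serious report also lists "other"
_NONSERIOUS_EMPTY_RATE = 0.5  # chance a non-serious report has an empty outcome set


class DrugSpec(BaseModel):
    label: str
    marginal: float = Field(ge=0.0, le=1.0)


class PTSpec(BaseModel):
    label: str
    baseline: float = Field(gt=0.0, lt=1.0)


class EffectSpec(BaseModel):
    drug: str
    pt: str
    log_or: float


class SynthConfig(BaseModel):
    """Generator parameters; defaults give a small generic configuration.

    ``preset_paperlike()`` returns a configuration whose drug marginals and
    demographic mixes emulate a published COVID-19 EUA dashboard extract.
    """

    n_reports: int = Field(default=1000, ge=0)
    seed: int = 0
    drugs: list[DrugSpec] = Field(
        default_factory=lambda: [
            DrugSpec(label="Nirmatrelvir/Ritonavir", marginal=0.4),
            DrugSpec(label="Remdesivir", marginal=0.3),
            DrugSpec(label="Sotrovimab", marginal=0.2),
        ]
    )
    pt_universe: list[PTSpec] = Field(
        default_factory=lambda: [
            PTSpec(label="Disease recurrence", baseline=0.02),
            PTSpec(label="Dysgeusia", baseline=0.05),
            PTSpec(label="Diarrhoea", baseline=0.08),
            PTSpec(label="Headache", baseline=0.10),
            PTSpec(label="Nausea", baseline=0.08),
            PTSpec(label="Fatigue", baseline=0.07),
            PTSpec(label="Cough", baseline=0.06),
            PTSpec(label="Pyrexia", baseline=0.05),
            PTSpec(label="Vomiting", baseline=0.04),
            PTSpec(label="Dizziness", baseline=0.06),
            PTSpec(label="Rash", baseline=0.05),
            PTSpec(label="Pruritus", baseline=0.04),
            PTSpec(label="Insomnia", baseline=0.04),
            PTSpec(label="Arthralgia", baseline=0.05),
            PTSpec(label="Myalgia", baseline=0.05),
            PTSpec(label="Chills", baseline=0.06),
            PTSpec(label="Malaise", baseline=0.06),
            PTSpec(label="Asthenia", baseline=0.05),
            PTSpec(label="Dyspnoea", baseline=0.05),
            PTSpec(label="Drug ineffective", baseline=0.06),
        ]
    )
    effects: list[EffectSpec] = Field(default_factory=list)
    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"female": 0.551, "male": 0.449}
    )
    age_band_probs: dict[str, float] = Field(
        default_factory=lambda: {"<18": 0.014, "18-44": 0.215, "45-64": 0.351, ">=65": 0.420}
    )
    reporter_probs: dict[str, float] = Field(
        default_factory=lambda: {"consumer": 0.45, "healthcare_professional": 0.55}
    )
    reporter_probs_by_drug: dict[str, dict[str, float]] = Field(default_factory=dict)
    outcome_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "death": 0.02,
            "life_threatening": 0.02,
            "hospitalization": 0.10,
            "disability": 0.005,
            "congenital_anomaly": 0.001,
            "required_intervention": 0.02,
            "other": 0.15,
            "non_serious": 0.684,
        }
    )
    outcome_probs_by_drug: dict[str, dict[str, float]] = Field(default_factory=dict)
    country_probs: dict[str, float] = Field(
        default_factory=lambda: {"US": 0.9, "other": 0.1}
    )
    missing_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "sex": 0.05,
            "age": 0.12,
            "reporter": 0.02,
            "country": 0.15,
            "event_date": 0.05,
        }
    )
    duplicate_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    multidrug_rate: float = Field(default=0.004, ge=0.0, lt=1.0)
    padding_pt: str = "Drug ineffective"
    concomitant_pool: list[str] = Field(
        default_factory=lambda: [
            "Paracetamol",
            "Atorvastatin",
            "Metformin",
            "Levothyroxine",
            "Omeprazole",
            "Amlodipine",
            "Aspirin",
            "Vitamin D",
            "Lisinopril",
            "Simvastatin",
            "Losartan",
            "Gabapentin",
            "Sertraline",
            "Albuterol",
            "Furosemide",
            "Prednisone",
        ]
    )
    concomitant_max: int = Field(default=3, ge=0)
    date_start: datetime.date = datetime.date(2022, 1, 1)
    date_days: int = Field(default=400, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        total = sum(d.marginal for d in self.drugs)
        if total > 1.0 + 1e-9:
            raise ValueError(f"drug marginals sum to {total} > 1")
        if self.duplicate_rate + self.multidrug_rate >= 1.0:
            raise ValueError("duplicate_rate + multidrug_rate must be < 1")
        drug_labels = {canon(d.label) for d in self.drugs}
        pt_labels = {canon(p.label) for p in self.pt_universe}
        for eff in self.effects:
            if canon(eff.drug) not in drug_labels:
                raise ValueError(f"effect references unknown drug {eff.drug!r}")
            if canon(eff.pt) not in pt_labels:
                raise ValueError(f"effect references unknown PT {eff.pt!r}")
        for name, probs in [
            ("sex_probs", self.sex_probs),
            ("age_band_probs", self.age_band_probs),
            ("reporter_probs", self.reporter_probs),
            ("outcome_probs", self.outcome_probs),
            ("country_probs", self.country_probs),
            *((f"reporter_probs_by_drug[{k}]", v) for k, v in self.reporter_probs_by_drug.items()),
            *((f"outcome_probs_by_drug[{k}]", v) for k, v in self.outcome_probs_by_drug.items()),
        ]:
            vals = list(probs.values())
            if not vals or any(v < 0 for v in vals) or sum(vals) <= 0:
                raise ValueError(f"{name}: probabilities must be >= 0 with positive sum")
        for key, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {key!r} outside [0, 1]")
        for band in self.age_band_probs:
            if band not in _AGE_BAND_RANGES:
                raise ValueError(f"unknown age band {band!r}")
        return self


@dataclass
class TruthLedger:
    """Ground truth for one generated dataset.

    ``effects`` holds the injected true log odds ratios per (drug, PT);
    ``duplicate_pairs`` the (original, duplicate) case-ID pairs; and
    ``multidrug_ids`` the case IDs given a second COVID-19 drug.
    """

    effects: dict[tuple[str, str], float] = dc_field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str]] = dc_field(default_factory=list)
    multidrug_ids: list[str] = dc_field(default_factory=list)

    @property
    def duplicate_case_ids(self) -> set[str]:
        return {dup for _, dup in self.duplicate_pairs}

    def to_json(self, path) -> None:
        data = {
            "effects": [
                {"drug": d, "pt": p, "log_or": v} for (d, p), v in self.effects.items()
            ],
            "duplicate_pairs": [list(pair) for pair in self.duplicate_pairs],
            "multidrug_ids": list(self.multidrug_ids),
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        data = json.loads(Path(path).read_text())
        return cls(
            effects={(e["drug"], e["pt"]): e["log_or"] for e in data["effects"]},
            duplicate_pairs=[tuple(p) for p in data["duplicate_pairs"]],
            multidrug_ids=list(data["multidrug_ids"]),
        )


def _draw_categorical(rng, categories, probs, size):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(categories), size=size, p=p)
    return idx


def _ingredient_map() -> dict[str, tuple[str, ...]]:
    cat = default_catalog()
    return {canon(d.label): d.ingredients for d in cat.drugs}


def _products_for(label: str, ing_map: dict) -> list[Product]:
    ings = ing_map.get(canon(label))
    if ings is None:
        return [Product(name=label, role="suspected")]
    return [
        Product(name=i.title(), active_ingredient=i, role="suspected") for i in ings
    ]


def generate(config: SynthConfig) -> tuple[ReportSet, TruthLedger]:
    """Generate a synthetic ReportSet and its ground-truth ledger.

    Reproducible: the same (config, seed) yields identical output. Duplicate
    copies match their original exactly on the eight dedup fields and carry a
    lexicographically larger case ID, so deduplication keeping the smallest
    case ID removes precisely the injected copies.
    """
    rng = np.random.default_rng(config.seed)
    ledger = TruthLedger(
        effects={(e.drug, e.pt): e.log_or for e in config.effects}
    )
    n = config.n_reports
    if n == 0:
        return ReportSet(provenance=Provenance(n_raw=0)), ledger

    drug_labels = [d.label for d in config.drugs]
    D = len(drug_labels)
    none_p = max(0.0, 1.0 - sum(d.marginal for d in config.drugs))
    drug_p = np.array([d.marginal for d in config.drugs] + [none_p])
    drug_idx = rng.choice(D + 1, size=n, p=drug_p / drug_p.sum())  # D == no COVID drug

    pt_labels = [p.label for p in config.pt_universe]
    P = len(pt_labels)
    base_logit = logit(np.array([p.baseline for p in config.pt_universe]))
    theta = np.zeros((D + 1, P))
    drug_pos = {canon(lbl): i for i, lbl in enumerate(drug_labels)}
    pt_pos = {canon(lbl): j for j, lbl in enumerate(pt_labels)}
    for eff in config.effects:
        theta[drug_pos[canon(eff.drug)], pt_pos[canon(eff.pt)]] = eff.log_or
    probmat = expit(base_logit[None, :] + theta)
    mention = rng.random((n, P)) < probmat[drug_idx]

    miss = config.missing_rates

    sex_cats = list(config.sex_probs)
    sex_idx = _draw_categorical(rng, sex_cats, list(config.sex_probs.values()), n)
    sex_missing = rng.random(n) < miss.get("sex", 0.0)

    band_cats = list(config.age_band_probs)
    band_idx = _draw_categorical(rng, band_cats, list(config.age_band_probs.values()), n)
    lo = np.array([_AGE_BAND_RANGES[b][0] for b in band_cats])
    hi = np.array([_AGE_BAND_RANGES[b][1] for b in band_cats])
    ages = lo[band_idx] + np.floor(
        rng.random(n) * (hi[band_idx] - lo[band_idx] + 1)
    ).astype(int)
    age_missing = rng.random(n) < miss.get("age", 0.0)

    rep_cats = list(config.reporter_probs)
    rep_idx = _draw_categorical(rng, rep_cats, list(config.reporter_probs.values()), n)
    reporter = np.array(rep_cats, dtype=object)[rep_idx]
    for lbl, probs in config.reporter_probs_by_drug.items():
        if canon(lbl) not in drug_pos:
            raise ValueError(f"reporter override for unknown drug {lbl!r}")
        mask = drug_idx == drug_pos[canon(lbl)]
        cats = list(probs)
        idx = _draw_categorical(rng, cats, list(probs.values()), int(mask.sum()))
        reporter[mask] = np.array(cats, dtype=object)[idx]
    reporter_missing = rng.random(n) < miss.get("reporter", 0.0)

    out_cats = list(config.outcome_probs)
    out_idx = _draw_categorical(rng, out_cats, list(config.outcome_probs.values()), n)
    outcome_cat = np.array(out_cats, dtype=object)[out_idx]
    for lbl, probs in config.outcome_probs_by_drug.items():
        if canon(lbl) not in drug_pos:
            raise ValueError(f"outcome override for unknown drug {lbl!r}")
        mask = drug_idx == drug_pos[canon(lbl)]
        cats = list(probs)
        idx = _draw_categorical(rng, cats, list(probs.values()), int(mask.sum()))
        outcome_cat[mask] = np.array(cats, dtype=object)[idx]
    outcome_u = rng.random(n)

    ctry_cats = list(config.country_probs)
    ctry_idx = _draw_categorical(rng, ctry_cats, list(config.country_probs.values()), n)
    other_ctry = rng.integers(0, len(_OTHER_COUNTRIES), size=n)
    country_missing = rng.random(n) < miss.get("country", 0.0)

    day_offsets = rng.integers(0, config.date_days, size=n)
    date_missing = rng.random(n) < miss.get("event_date", 0.0)

    n_con = rng.binomial(config.concomitant_max, 0.6, size=n)
    noncovid_idx = rng.integers(0, len(_NON_COVID_SUSPECTS), size=n)

    ing_map = _ingredient_map()
    reports: list[Report] = []
    for i in range(n):
        if drug_idx[i] < D:
            prods = _products_for(drug_labels[drug_idx[i]], ing_map)
        else:
            prods = [Product(name=_NON_COVID_SUSPECTS[noncovid_idx[i]], role="suspected")]
        if n_con[i] > 0:
            picks = rng.choice(len(config.concomitant_pool), size=n_con[i], replace=False)
            prods += [
                Product(name=config.concomitant_pool[j], role="concomitant")
                for j in sorted(picks)
            ]
        reac = [pt_labels[j] for j in np.flatnonzero(mention[i])]
        if not reac:
            reac = [config.padding_pt]
        cat = outcome_cat[i]
        if cat == "non_serious":
            outcomes = frozenset() if outcome_u[i] < _NONSERIOUS_EMPTY_RATE else frozenset({cat})
        elif cat != "other" and outcome_u[i] < _SERIOUS_EXTRA_RATE:
            outcomes = frozenset({cat, "other"})
        else:
            outcomes = frozenset({cat})
        country = UNSPECIFIED
        if not country_missing[i]:
            country = (
                "US" if ctry_cats[ctry_idx[i]] == "US" else _OTHER_COUNTRIES[other_ctry[i]]
            )
        reports.append(
            Report(
                case_id=f"C{i:07d}",
                products=prods,
                reactions=reac,
                sex=UNSPECIFIED if sex_missing[i] else sex_cats[sex_idx[i]],
                age_years=None if age_missing[i] else float(ages[i]),
                reporter_type=UNSPECIFIED if reporter_missing[i] else reporter[i],
                country=country,
                event_date=None
                if date_missing[i]
                else config.date_start + datetime.timedelta(days=int(day_offsets[i])),
                outcomes=outcomes,
            )
        )

    # Multi-drug injection: add a second, ingredient-disjoint COVID drug.
    n_multi = int(round(config.multidrug_rate * n))
    eligible = np.flatnonzero(drug_idx < D)
    if n_multi > 0 and D >= 2 and eligible.size > 0:
        chosen = rng.choice(eligible, size=min(n_multi, eligible.size), replace=False)
        for i in sorted(chosen):
            own = drug_labels[drug_idx[i]]
            own_ings = set(ing_map.get(canon(own), (canon(own),)))
            others = [
                lbl
                for lbl in drug_labels
                if canon(lbl) != canon(own)
                and not (set(ing_map.get(canon(lbl), (canon(lbl),))) & own_ings)
            ]
            if not others:
                continue
            second = others[rng.integers(0, len(others))]
            sus = [p for p in reports[i].products if p.role == "suspected"]
            con = [p for p in reports[i].products if p.role == "concomitant"]
            reports[i].products = sus + _products_for(second, ing_map) + con
            ledger.multidrug_ids.append(reports[i].case_id)

    # Duplicate injection: exact copy of the eight matching fields, new case ID.
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup > 0:
        chosen = rng.choice(n, size=min(n_dup, n), replace=False)
        dup_rep_idx = _draw_categorical(
            rng, rep_cats, list(config.reporter_probs.values()), len(chosen)
        )
        for k, i in enumerate(sorted(chosen)):
            orig = reports[i]
            dup_id = f"{orig.case_id}D1"
            reports.append(
                Report(
                    case_id=dup_id,
                    products=[
                        Product(p.name, p.active_ingredient, p.role)
                        for p in orig.products
                    ],
                    reactions=list(orig.reactions),
                    sex=orig.sex,
                    age_years=orig.age_years,
                    reporter_type=rep_cats[dup_rep_idx[k]],  # versions may differ here
                    country=orig.country,
                    event_date=orig.event_date,
                    outcomes=orig.outcomes,
                )
            )
            ledger.duplicate_pairs.append((orig.case_id, dup_id))

    perm = rng.permutation(len(reports))
    reports = [reports[i] for i in perm]
    return ReportSet(reports=reports, provenance=Provenance(n_raw=len(reports))), ledger


def sample_fourfold(
    n: int,
    drug_p: float,
    baseline: float,
    log_or: float,
    rng: np.random.Generator,
    reps: int = 1,
) -> np.ndarray:
    """Draw 2x2 tables from the generator's marginal law for one drug-PT pair.

    Marginalising the report-level model over everything except one drug and
    one PT gives: n_drug ~ Bin(n, drug_p); n11 ~ Bin(n_drug, p1) with
    p1 = expit(logit(baseline) + log_or); n21 ~ Bin(n - n_drug, baseline).
    Returns an integer array of shape (reps, 4) ordered (n11, n12, n21, n22).
    """
    p1 = float(expit(logit(baseline) + log_or))
    n_drug = rng.binomial(n, drug_p, size=reps)
    n11 = rng.binomial(n_drug, p1)
    n21 = rng.binomial(n - n_drug, baseline)
    return np.stack([n11, n_drug - n11, n21, (n - n_drug) - n21], axis=1)


def _baseline_for(p_target: float, odds_ratio: float) -> float:
    """Comparator-group baseline giving the stated target-group share at this OR."""
    odds_t = p_target / (1.0 - p_target)
    odds_b = odds_t / odds_ratio
    return odds_b / (1.0 + odds_b)


#: (PT label, target-group mention share, true odds ratio vs other drugs)
#: used by the paperlike preset. The three recurrence-family effects use the
#: published ROR point estimates; remaining shares follow the published
#: top-events table with modest assumed odds ratios.
_PAPERLIKE_PTS: list[tuple[str, float, float]] = [
    ("COVID-19", 0.4354, 1.15),
    ("Disease recurrence", 0.4043, 212.3),
    ("Symptom recurrence", 0.027, 62.1),
    ("Therapeutic product effect incomplete", 0.027, 55.5),
    ("Dysgeusia", 0.1755, 8.0),
    ("Product taste abnormal", 0.012, 12.0),
    ("Diarrhoea", 0.0880, 1.5),
    ("Nausea", 0.0531, 1.2),
    ("Cough", 0.0527, 1.0),
    ("Fatigue", 0.0483, 1.0),
    ("Headache", 0.0477, 1.2),
    ("Nasal congestion", 0.0418, 2.0),
    ("Oropharyngeal pain", 0.0341, 1.5),
    ("Rhinorrhoea", 0.0302, 1.5),
    ("Pyrexia", 0.0299, 1.0),
    ("Vomiting", 0.0288, 1.2),
    ("Incorrect dose administered", 0.0288, 2.0),
    ("Malaise", 0.0276, 1.0),
    ("Drug ineffective", 0.06, 1.0),
]

#: Suspected-drug marginals of the paperlike preset (shares of 29,888
#: analysed dashboard reports; the small remainder has no COVID-19 drug).
_PAPERLIKE_DRUGS: list[tuple[str, int]] = [
    ("Nirmatrelvir/Ritonavir", 11997),
    ("Casirivimab/Imdevimab", 4478),
    ("Remdesivir", 4047),
    ("Bamlanivimab", 3889),
    ("Bamlanivimab/Etesevimab", 1968),
    ("Sotrovimab", 1032),
    ("Baricitinib", 652),
    ("Bebtelovimab", 621),
    ("Cilgavimab/Tixagevimab", 466),
    ("Tocilizumab", 253),
]
_PAPERLIKE_TOTAL = 29888


def preset_paperlike(n_reports: int = 20000, seed: int = 0) -> SynthConfig:
    """Configuration emulating the published dashboard extract.

    Drug marginals follow the published drug ranking shares; demographics and
    outcome mixes follow the published characteristics table (target drug
    reported mostly by consumers with overwhelmingly non-serious outcomes,
    other drugs mostly by healthcare professionals); the disease-recurrence
    family of PTs carries the published ROR point estimates as true effects.
    """
    target = TARGET_DRUG
    drugs = [
        DrugSpec(label=lbl, marginal=count / _PAPERLIKE_TOTAL)
        for lbl, count in _PAPERLIKE_DRUGS
    ]
    pts, effects = [], []
    for label, p_target, odds_ratio in _PAPERLIKE_PTS:
        pts.append(PTSpec(label=label, baseline=_baseline_for(p_target, odds_ratio)))
        if odds_ratio != 1.0:
            effects.append(
                EffectSpec(drug=target, pt=label, log_or=float(np.log(odds_ratio)))
            )
    return SynthConfig(
        n_reports=n_reports,
        seed=seed,
        drugs=drugs,
        pt_universe=pts,
        effects=effects,
        sex_probs={"female": 0.551, "male": 0.449},
        age_band_probs={"<18": 0.0137, "18-44": 0.2150, "45-64": 0.3513, ">=65": 0.4200},
        reporter_probs={"consumer": 0.1475, "healthcare_professional": 0.8525},
        reporter_probs_by_drug={
            target: {"consumer": 0.7143, "healthcare_professional": 0.2857}
        },
        outcome_probs={
            "death": 0.1023,
            "life_threatening": 0.0437,
            "hospitalization": 0.2485,
            "disability": 0.0046,
            "congenital_anomaly": 0.0003,
            "required_intervention": 0.0474,
            "other": 0.2604,
            "non_serious": 0.2928,
        },
        outcome_probs_by_drug={
            target: {
                "death": 0.0049,
                "life_threatening": 0.0051,
                "hospitalization": 0.0283,
                "disability": 0.0040,
                "congenital_anomaly": 0.0,
                "required_intervention": 0.0024,
                "other": 0.0787,
                "non_serious": 0.8766,
            }
        },
        country_probs={"US": 0.9394, "other": 0.0606},
        missing_rates={
            "sex": 0.0551,
            "age": 0.1241,
            "reporter": 0.0211,
            "country": 0.1524,
            "event_date": 0.05,
        },
        duplicate_rate=0.05,
        multidrug_rate=0.004,
    )


__all__ = [
    "SynthConfig",
    "DrugSpec",
    "PTSpec",
    "EffectSpec",
    "TruthLedger",
    "generate",
    "sample_fourfold",
    "preset_paperlike",
    "TARGET_DRUG",
]
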