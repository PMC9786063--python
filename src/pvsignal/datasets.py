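"""Bundled reference data.

Summary tables from a published pharmacovigilance analysis of the FAERS
COVID-19 EUA public dashboard (extract cut-off 2022-07-29; 31,491 raw
reports, 30,001 after deduplication, 113 excluded for multiple suspected
COVID-19 drugs, 29,888 analysed). Each table ships both the report counts
and the percentages printed in the publication, so the package's percentage
arithmetic can be validated against the published display values while being
recomputed from the counts.

Also exposes loaders for the packaged drug catalogue and the PT->SOC fixture
vocabulary that stands in for licensed MedDRA.
"""

from __future__ import annotations

from importlib import resources

from .model_io import Vocabulary, load_vocabulary
from .preprocess import DrugCatalog, default_catalog

#: Total analysed reports and the preprocessing waypoints.
N_RAW = 31491
N_AFTER_DEDUP = 30001
N_EXCLUDED_MULTIDRUG = 113
N_ANALYZED = 29888

#: Report counts of the two comparison groups.
N_TARGET = 11997  # nirmatrelvir/ritonavir as suspected drug
N_OTHER = 17891  # any other COVID-19 drug as suspected drug

TARGET_DRUG = "Nirmatrelvir/Ritonavir"

#: Drug ranking: (drug, reports, printed percent of 29,888).
DRUG_RANKING: list[tuple[str, int, float]] = [
    ("Nirmatrelvir/Ritonavir", 11997, 40.14),
    ("Casirivimab/Imdevimab", 4478, 14.98),
    ("Remdesivir", 4047, 13.54),
    ("Bamlanivimab", 3889, 13.01),
    ("Bamlanivimab/Etesevimab", 1968, 6.58),
    ("Sotrovimab", 1032, 3.45),
    ("Baricitinib", 652, 2.18),
    ("Bebtelovimab", 621, 2.08),
    ("Cilgavimab/Tixagevimab", 466, 1.56),
    ("Tocilizumab", 253, 0.85),
]

#: Characteristics of the two groups: section -> [(label, count, printed %)].
CHARACTERISTICS_TARGET: dict[str, list[tuple[str, int, float]]] = {
    "sex": [("female", 7138, 59.50), ("male", 4082, 34.03), ("unspecified", 777, 6.48)],
    "age": [
        ("<18", 27, 0.23),
        ("18-44", 2357, 19.65),
        ("45-64", 3887, 32.40),
        (">=65", 4132, 34.44),
        ("unspecified", 1594, 13.29),
    ],
    "reporter": [
        ("consumer", 8542, 71.20),
        ("healthcare_professional", 3415, 28.47),
        ("unspecified", 40, 0.33),
    ],
    "country": [("US", 10553, 87.96), ("other", 818, 6.82), ("unspecified", 626, 5.22)],
    "outcome": [
        ("death", 59, 0.49),
        ("life_threatening", 61, 0.51),
        ("required_intervention", 29, 0.24),
        ("disability", 48, 0.40),
        ("hospitalization", 339, 2.83),
        ("congenital_anomaly", 0, 0.00),
        ("other", 944, 7.87),
        ("non_serious", 10517, 87.66),
    ],
}

CHARACTERISTICS_OTHER: dict[str, list[tuple[str, int, float]]] = {
    "sex": [("female", 8430, 47.12), ("male", 8590, 48.01), ("unspecified", 871, 4.87)],
    "age": [
        ("<18", 331, 1.85),
        ("18-44", 3272, 18.29),
        ("45-64", 5309, 29.67),
        (">=65", 6864, 38.37),
        ("unspecified", 2115, 11.82),
    ],
    "reporter": [
        ("consumer", 2551, 14.26),
        ("healthcare_professional", 14749, 82.44),
        ("unspecified", 591, 3.30),
    ],
    "country": [
        ("US", 13245, 74.03),
        ("other", 718, 4.01),
        ("unspecified", 3928, 21.96),
    ],
    "outcome": [
        ("death", 1831, 10.23),
        ("life_threatening", 782, 4.37),
        ("required_intervention", 848, 4.74),
        ("disability", 83, 0.46),
        ("hospitalization", 4446, 24.85),
        ("congenital_anomaly", 5, 0.03),
        ("other", 4658, 26.04),
        ("non_serious", 5238, 29.28),
    ],
}

#: Median reported ages (not recomputable from the count tables).
MEDIAN_AGE_TARGET = 60
MEDIAN_AGE_OTHER = 62

#: Top reported events for the target drug: (PT, SOC, reports, printed %).
TOP_EVENTS: list[tuple[str, str, int, float]] = [
    ("COVID-19", "Infections and infestations", 5224, 43.54),
    ("Disease Recurrence", "General disorders and administration site conditions", 4850, 40.43),
    ("Dysgeusia", "Nervous system disorders", 2106, 17.55),
    ("Diarrhoea", "Gastrointestinal disorders", 1056, 8.80),
    ("Nausea", "Gastrointestinal disorders", 637, 5.31),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 632, 5.27),
    ("Fatigue", "General disorders and administration site conditions", 579, 4.83),
    ("Headache", "Nervous system disorders", 572, 4.77),
    ("Nasal Congestion", "Respiratory, thoracic and mediastinal disorders", 501, 4.18),
    ("Oropharyngeal Pain", "Respiratory, thoracic and mediastinal disorders", 409, 3.41),
    ("Rhinorrhoea", "Respiratory, thoracic and mediastinal disorders", 362, 3.02),
    ("Pyrexia", "General disorders and administration site conditions", 359, 2.99),
    ("Vomiting", "Gastrointestinal disorders", 346, 2.88),
    ("Incorrect Dose Administered", "Injury, poisoning and procedural complications", 345, 2.88),
    ("Malaise", "General disorders and administration site conditions", 331, 2.76),
]

#: Outcomes among the target drug's disease-recurrence reports
#: (denominator 4850): (outcome, count, printed %).
RECURRENCE_OUTCOMES: list[tuple[str, int, float]] = [
    ("death", 1, 0.02),
    ("life_threatening", 4, 0.08),
    ("disability", 9, 0.19),
    ("hospitalization", 45, 0.93),
    ("other", 88, 1.81),
    ("non_serious", 4703, 96.97),
]
N_RECURRENCE = 4850

#: Printed male-to-female reporting ratios.
SEX_RATIO_TARGET_PRINTED = 0.57
SEX_RATIO_OTHER_PRINTED = 1.02

#: Headline disproportionality results (ROR, CI low, CI high).
RECURRENCE_ROR_PRINTED = (212.01, 162.85, 276.01)
RECURRENCE_ROR_HCP_PRINTED = (421.38, 273.60, 648.99)


def load_default_catalog() -> DrugCatalog:
    """The packaged ten-drug COVID-19 EUA catalogue."""
    return default_catalog()


def load_default_vocabulary() -> Vocabulary:
    """The packaged PT->SOC fixture vocabulary (stand-in for MedDRA)."""
    ref = resources.files("pvsignal.data").joinpath("vocabulary.csv")
    with resources.as_file(ref) as path:
        return load_vocabulary(path)


__all__ = [
    "N_RAW",
    "N_AFTER_DEDUP",
    "N_EXCLUDED_MULTIDRUG",
    "N_ANALYZED",
    "N_TARGET",
    "N_OTHER",
    "N_RECURRENCE",
    "TARGET_DRUG",
    "DRUG_RANKING",
    "CHARACTERISTICS_TARGET",
    "CHARACTERISTICS_OTHER",
    "MEDIAN_AGE_TARGET",
    "MEDIAN_AGE_OTHER",
    "TOP_EVENTS",
    "RECURRENCE_OUTCOMES",
    "SEX_RATIO_TARGET_PRINTED",
    "SEX_RATIO_OTHER_PRINTED",
    "RECURRENCE_ROR_PRINTED",
    "RECURRENCE_ROR_HCP_PRINTED",
    "load_default_catalog",
    "load_default_vocabulary",
]
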