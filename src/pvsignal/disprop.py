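"""Reporting odds ratio (ROR) disproportionality analysis.

For a target drug D and target event PT E, the analysed reports are cross
classified into the 2x2 table

    =================  ==========  =================
    .                  event E     all other events
    =================  ==========  =================
    drug D             n11         n12
    all other drugs    n21         n22
    =================  ==========  =================

with the REPORT as the counting unit: a report counts in row 1 when its
canonical suspected COVID-19 drug equals D, and in column 1 when any of its
reaction PTs equals E (case-insensitive; a PT listed twice still counts the
report once). The ROR is the cross-product ratio

    ROR = (n11 * n22) / (n12 * n21)

with the Woolf log-normal 95% confidence interval

    exp( ln ROR  +/-  z * sqrt(1/n11 + 1/n12 + 1/n21 + 1/n22) ).

A drug-event pair is flagged as a signal when n11 >= 3 and the lower CI
limit exceeds 1. When a cell is zero the default Haldane-Anscombe correction
adds 0.5 to every cell (flagged via ``corrected``); with ``correction="none"``
the result is returned as NaN rather than raising.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import norm

from .model_io import ReportSet, canon
from .preprocess import DrugCatalog, assign_canonical

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 3


@dataclass(frozen=True)
class FourFold:
    """2x2 drug-by-event contingency counts (reports as counting unit)."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n21", "n22"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_drug(self) -> int:
        return self.n11 + self.n12

    @property
    def n_other(self) -> int:
        return self.n21 + self.n22

    @property
    def n_event(self) -> int:
        return self.n11 + self.n21

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def swap_rows(self) -> "FourFold":
        return FourFold(self.n21, self.n22, self.n11, self.n12)

    def swap_cols(self) -> "FourFold":
        return FourFold(self.n12, self.n11, self.n22, self.n21)


@dataclass
class RORResult:
    """Point estimate, Woolf CI and signal flag for one drug-event pair."""

    drug: str
    pt: str
    table: FourFold
    ror: float
    ci_low: float
    ci_high: float
    is_signal: bool
    corrected: bool
    alpha: float = 0.05
    min_count: int = DEFAULT_MIN_COUNT


def ror(
    table: FourFold,
    alpha: float = 0.05,
    correction: str = "halves_if_zero",
    drug: str = "",
    pt: str = "",
    min_count: int = DEFAULT_MIN_COUNT,
) -> RORResult:
    """ROR point estimate with Woolf (log-normal) confidence interval.

    Parameters
    ----------
    table
        The 2x2 counts. Both row margins must be positive.
    alpha
        Two-sided CI level (0.05 gives the 95% interval).
    correction
        ``"halves_if_zero"`` adds 0.5 to every cell when any cell is zero
        (Haldane-Anscombe) and sets ``corrected``; ``"none"`` returns NaN
        estimates for zero-cell tables instead of raising.

    The signal flag uses the *observed* co-report count ``table.n11`` (never
    the corrected one) and the computed lower CI bound.
    """
    if correction not in ("none", "halves_if_zero"):
        raise ValueError(f"unknown correction {correction!r}")
    if table.n_drug == 0 or table.n_other == 0:
        raise ValueError("both row margins of the 2x2 table must be positive")
    cells = [float(table.n11), float(table.n12), float(table.n21), float(table.n22)]
    corrected = False
    if any(c == 0.0 for c in cells):
        if correction == "none":
            return RORResult(
                drug=drug, pt=pt, table=table,
                ror=math.nan, ci_low=math.nan, ci_high=math.nan,
                is_signal=False, corrected=False, alpha=alpha, min_count=min_count,
            )
        cells = [c + 0.5 for c in cells]
        corrected = True
    a, b, c, d = cells
    estimate = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = float(norm.ppf(1.0 - alpha / 2.0))
    log_ror = math.log(estimate)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)
    return RORResult(
        drug=drug,
        pt=pt,
        table=table,
        ror=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        is_signal=(table.n11 >= min_count and ci_low > 1.0),
        corrected=corrected,
        alpha=alpha,
        min_count=min_count,
    )


def is_signal(result: RORResult, min_count: int = DEFAULT_MIN_COUNT) -> bool:
    """Signal rule: observed co-report count >= min_count and CI low > 1."""
    return result.table.n11 >= min_count and result.ci_low > 1.0


def build_contingency(
    reports: ReportSet,
    target_drug: str,
    target_pt: str,
    catalog: DrugCatalog,
    labels: Optional[Sequence[Optional[str]]] = None,
) -> FourFold:
    """Build the 2x2 table for one (drug, PT) pair from preprocessed reports.

    The comparator rows are *all other analysed reports* (any report whose
    canonical drug differs from the target, including reports with no
    catalogued COVID-19 drug).
    """
    if not catalog.has_label(target_drug):
        raise ValueError(f"target drug {target_drug!r} not in catalog")
    if labels is None:
        labels = assign_canonical(reports, catalog)
    tdrug = canon(target_drug)
    tpt = canon(target_pt)
    n11 = n12 = n21 = n22 = 0
    for rep, label in zip(reports, labels):
        has_drug = label is not None and canon(label) == tdrug
        has_pt = tpt in rep.reaction_set()
        if has_drug:
            if has_pt:
                n11 += 1
            else:
                n12 += 1
        elif has_pt:
            n21 += 1
        else:
            n22 += 1
    return FourFold(n11, n12, n21, n22)


def _sort_results(results: list[RORResult]) -> list[RORResult]:
    """Signals first by descending ROR, then the rest by descending n11."""

    def key(r: RORResult):
        ror_key = r.ror if math.isfinite(r.ror) else -math.inf
        return (
            not r.is_signal,
            -ror_key if r.is_signal else 0.0,
            -r.table.n11,
            -ror_key,
            canon(r.pt),
        )

    return sorted(results, key=key)


def scan(
    reports: ReportSet,
    target_drug: str,
    catalog: DrugCatalog,
    pts: Optional[Sequence[str]] = None,
    min_count: int = DEFAULT_MIN_COUNT,
    alpha: float = 0.05,
    correction: str = "halves_if_zero",
) -> list[RORResult]:
    """ROR scan of one target drug against every PT (or a given PT list).

    Returns one :class:`RORResult` per PT with at least one co-report
    (n11 >= 1), ordered deterministically: signals by descending ROR, then
    non-signals by descending co-report count, ties broken by PT label.
    """
    if not catalog.has_label(target_drug):
        raise ValueError(f"target drug {target_drug!r} not in catalog")
    labels = assign_canonical(reports, catalog)
    tdrug = canon(target_drug)
    is_target = [lbl is not None and canon(lbl) == tdrug for lbl in labels]
    n = len(reports)
    n_drug = sum(is_target)

    # first-seen display label per canonical PT
    display: dict[str, str] = {}
    for rep in reports:
        for raw in rep.reactions:
            display.setdefault(canon(raw), raw.strip())
    if pts is None:
        universe = sorted(display)
    else:
        universe = []
        for raw in pts:
            display.setdefault(canon(raw), str(raw).strip())
            universe.append(canon(raw))

    n11_counts = {pt: 0 for pt in universe}
    npt_counts = {pt: 0 for pt in universe}
    wanted = set(universe)
    for rep, target in zip(reports, is_target):
        for pt in rep.reaction_set() & wanted:
            npt_counts[pt] += 1
            if target:
                n11_counts[pt] += 1

    results = []
    for pt in universe:
        n11 = n11_counts[pt]
        if n11 < 1:
            continue
        npt = npt_counts[pt]
        table = FourFold(n11, n_drug - n11, npt - n11, n - n_drug - (npt - n11))
        results.append(
            ror(
                table,
                alpha=alpha,
                correction=correction,
                drug=target_drug,
                pt=display[pt],
                min_count=min_count,
            )
        )
    return _sort_results(results)


def _stratum_filters(age_cut: float = 65.0) -> dict[str, dict]:
    return {
        "age": {
            f"age<{age_cut:g}": lambda r, c=age_cut: r.age_years is not None and r.age_years < c,
            f"age>={age_cut:g}": lambda r, c=age_cut: r.age_years is not None and r.age_years >= c,
        },
        "sex": {
            "sex=male": lambda r: r.sex == "male",
            "sex=female": lambda r: r.sex == "female",
        },
        "reporter": {
            "reporter=hcp": lambda r: r.reporter_type == "healthcare_professional",
        },
    }


def stratified_scan(
    reports: ReportSet,
    target_drug: str,
    catalog: DrugCatalog,
    strata: Sequence[str] = ("age", "sex", "reporter"),
    age_cut: float = 65.0,
    **scan_kwargs,
) -> dict[str, list[RORResult]]:
    """Subset / sensitivity scans: age (<65 vs >=65), sex, HCP-only reporter.

    Each stratum's scan is self-contained: all four cells of every table come
    from reports inside the stratum only, and reports with a missing
    stratifier are dropped from that stratified analysis (and only there).
    An empty stratum yields an empty scan with a warning.
    """
    filters = _stratum_filters(age_cut)
    unknown = [s for s in strata if s not in filters]
    if unknown:
        raise ValueError(f"unknown strata {unknown}; choose from {sorted(filters)}")
    out: dict[str, list[RORResult]] = {}
    for group in strata:
        for name, pred in filters[group].items():
            subset = [r for r in reports if pred(r)]
            if not subset:
                logger.warning("stratum %s is empty; emitting empty scan", name)
                out[name] = []
                continue
            out[name] = scan(
                ReportSet(reports=subset), target_drug, catalog, **scan_kwargs
            )
    return out


__all__ = [
    "FourFold",
    "RORResult",
    "ror",
    "is_signal",
    "build_contingency",
    "scan",
    "stratified_scan",
    "DEFAULT_MIN_COUNT",
]
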