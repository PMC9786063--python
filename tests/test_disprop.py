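"""ROR estimation, Woolf CI, signal rule, scans and stratified variants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from pvsignal.disprop import (
    FourFold,
    RORResult,
    build_contingency,
    is_signal,
    ror,
    scan,
    stratified_scan,
)
from pvsignal.model_io import ReportSet, canon
from pvsignal.preprocess import assign_canonical, dedup_reports, exclude_multidrug
from pvsignal.synthgen import (
    EffectSpec,
    SynthConfig,
    generate,
    sample_fourfold,
)

from conftest import make_report


def brute_force_table(reports, labels, target_drug, target_pt):
    """Independent O(N) scan: recount the four cells report by report."""
    n11 = n12 = n21 = n22 = 0
    for rep, label in zip(reports, labels):
        has_drug = label is not None and canon(label) == canon(target_drug)
        has_pt = canon(target_pt) in {canon(x) for x in rep.reactions}
        if has_drug and has_pt:
            n11 += 1
        elif has_drug:
            n12 += 1
        elif has_pt:
            n21 += 1
        else:
            n22 += 1
    return FourFold(n11, n12, n21, n22)


class TestBuildContingency:
    def test_four_report_example(self, four_report_set, catalog):
        table = build_contingency(four_report_set, "Remdesivir", "x", catalog)
        assert table == FourFold(1, 1, 1, 1)

    def test_absent_pt_gives_empty_event_column(self, four_report_set, catalog):
        table = build_contingency(four_report_set, "Remdesivir", "zzz", catalog)
        assert table.n11 == 0 and table.n21 == 0
        assert table.n12 == 2 and table.n22 == 2

    def test_unknown_drug_is_hard_error(self, four_report_set, catalog):
        with pytest.raises(ValueError, match="not in catalog"):
            build_contingency(four_report_set, "Quinine", "x", catalog)

    def test_matches_brute_force_on_synthetic_sets(self, catalog):
        for seed in range(5):
            rs, _ = generate(SynthConfig(n_reports=200, seed=seed))
            clean, _ = dedup_reports(rs)
            clean, _ = exclude_multidrug(clean, catalog)
            labels = assign_canonical(clean, catalog)
            pts = sorted({canon(x) for r in clean for x in r.reactions})
            for drug in ("Nirmatrelvir/Ritonavir", "Remdesivir", "Sotrovimab"):
                for pt in pts:
                    got = build_contingency(clean, drug, pt, catalog)
                    assert got == brute_force_table(clean, labels, drug, pt)


class TestRor:
    def test_balanced_table_is_unity(self):
        res = ror(FourFold(10, 10, 10, 10))
        assert res.ror == pytest.approx(1.0)
        # CI symmetric about 1 on the log scale
        assert res.ci_low == pytest.approx(1.0 / res.ci_high, rel=1e-12)

    def test_hand_arithmetic_example(self):
        res = ror(FourFold(10, 90, 5, 895))
        assert res.ror == pytest.approx((10 / 90) / (5 / 895), rel=1e-12)
        assert res.ror == pytest.approx(19.888888888888889, rel=1e-12)
        # independent log/sqrt evaluation of the Woolf interval
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 895)
        z = 1.959963984540054
        assert res.ci_low == pytest.approx(math.exp(math.log(res.ror) - z * se), rel=1e-12)
        assert res.ci_high == pytest.approx(math.exp(math.log(res.ror) + z * se), rel=1e-12)

    def test_matches_statsmodels_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cells = rng.integers(1, 500, size=4)
            table = FourFold(*map(int, cells))
            res = ror(table)
            sm = Table2x2(np.array(cells, dtype=float).reshape(2, 2))
            assert res.ror == pytest.approx(sm.oddsratio, rel=1e-10)
            lo, hi = sm.oddsratio_confint(alpha=0.05)
            assert res.ci_low == pytest.approx(lo, rel=1e-10)
            assert res.ci_high == pytest.approx(hi, rel=1e-10)

    def test_zero_cell_without_correction_is_nan(self):
        res = ror(FourFold(0, 100, 5, 895), correction="none")
        assert math.isnan(res.ror) and math.isnan(res.ci_low)
        assert not res.is_signal and not res.corrected

    def test_zero_cell_haldane_correction(self):
        res = ror(FourFold(0, 100, 5, 895), correction="halves_if_zero")
        assert res.corrected
        assert math.isfinite(res.ror) and res.ror > 0
        expected = (0.5 * 895.5) / (100.5 * 5.5)
        assert res.ror == pytest.approx(expected, rel=1e-12)

    def test_empty_row_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ror(FourFold(0, 0, 5, 895))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 1000)] * 4))
    def test_swap_reciprocity(self, cells):
        """Swapping drug rows (or event columns) inverts the ROR exactly."""
        table = FourFold(*cells)
        base = ror(table)
        rows = ror(table.swap_rows())
        cols = ror(table.swap_cols())
        for inv in (rows, cols):
            assert inv.ror * base.ror == pytest.approx(1.0, rel=1e-12)
            assert inv.ci_low == pytest.approx(1.0 / base.ci_high, rel=1e-12)
            assert inv.ci_high == pytest.approx(1.0 / base.ci_low, rel=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_ci_width_shrinks_as_sqrt_k(self, k):
        base = ror(FourFold(12, 40, 9, 100))
        scaled = ror(FourFold(12 * k, 40 * k, 9 * k, 100 * k))
        width = math.log(base.ci_high) - math.log(base.ci_low)
        width_k = math.log(scaled.ci_high) - math.log(scaled.ci_low)
        assert width_k == pytest.approx(width / math.sqrt(k), rel=1e-12)


class TestSignalRule:
    @pytest.mark.parametrize(
        "n11, ci_low, expected",
        [
            (2, 5.0, False),   # below the co-report count threshold
            (50, 0.99, False),  # CI lower bound does not exceed 1
            (3, 1.01, True),    # boundary satisfied
            (3, 1.0, False),    # strict inequality on the CI bound
        ],
    )
    def test_boundaries(self, n11, ci_low, expected):
        result = RORResult(
            drug="D", pt="p", table=FourFold(n11, 10, 10, 10),
            ror=ci_low * 2, ci_low=ci_low, ci_high=ci_low * 4,
            is_signal=expected, corrected=False,
        )
        assert is_signal(result, min_count=3) is expected

    def test_flag_set_by_ror_computation(self):
        # large association, n11 >= 3 -> flagged
        assert ror(FourFold(30, 70, 10, 890)).is_signal
        # same association diluted below the count threshold
        assert not ror(FourFold(2, 5, 10, 983)).is_signal


class TestScan:
    def test_single_pt_universe(self, catalog):
        reports = [
            make_report("C1", (("Remdesivir", "remdesivir"),), reactions=("Nausea",)),
            make_report("C2", (("Sotrovimab", "sotrovimab"),), reactions=("Nausea",)),
        ]
        results = scan(ReportSet(reports=reports), "Remdesivir", catalog)
        assert len(results) == 1
        assert results[0].pt == "Nausea"

    def test_equals_per_pt_composition(self, catalog):
        rs, _ = generate(SynthConfig(n_reports=300, seed=2))
        clean, _ = dedup_reports(rs)
        clean, _ = exclude_multidrug(clean, catalog)
        results = scan(clean, "Remdesivir", catalog)
        for res in results:
            table = build_contingency(clean, "Remdesivir", res.pt, catalog)
            assert res.table == table
            assert res.ror == pytest.approx(ror(table).ror, rel=1e-12)

    def test_deterministic_ordering_signals_first(self, catalog):
        rs, _ = generate(
            SynthConfig(
                n_reports=2000,
                seed=4,
                duplicate_rate=0.0,
                multidrug_rate=0.0,
                effects=[
                    EffectSpec(drug="Remdesivir", pt="Dysgeusia", log_or=math.log(10)),
                    EffectSpec(drug="Remdesivir", pt="Rash", log_or=math.log(4)),
                ],
            )
        )
        results = scan(rs, "Remdesivir", catalog)
        flags = [r.is_signal for r in results]
        assert flags == sorted(flags, reverse=True)  # signals lead
        sig_rors = [r.ror for r in results if r.is_signal]
        assert sig_rors == sorted(sig_rors, reverse=True)
        rest_n11 = [r.table.n11 for r in results if not r.is_signal]
        assert rest_n11 == sorted(rest_n11, reverse=True)

    def test_injected_effect_is_top_signal_across_seeds(self, catalog):
        """A strong injected association should dominate the scan ranking."""
        hits = 0
        runs = 60
        for seed in range(runs):
            cfg = SynthConfig(
                n_reports=1500,
                seed=seed,
                duplicate_rate=0.0,
                multidrug_rate=0.0,
                effects=[
                    EffectSpec(
                        drug="Nirmatrelvir/Ritonavir",
                        pt="Disease recurrence",
                        log_or=math.log(20),
                    )
                ],
            )
            rs, _ = generate(cfg)
            results = scan(rs, "Nirmatrelvir/Ritonavir", catalog)
            if results and canon(results[0].pt) == "disease recurrence":
                hits += 1
        assert hits >= 0.95 * runs

    def test_null_calibration(self):
        """With no true effect the signal rule fires in <= ~2.5% of tables."""
        rng = np.random.default_rng(123)
        tables = sample_fourfold(5000, 0.4, 0.05, 0.0, rng, reps=2000)
        fired = sum(
            ror(FourFold(*map(int, row))).is_signal for row in tables
        )
        assert fired / 2000 <= 0.035


class TestStratifiedScan:
    def test_empty_stratum_and_complement_equal_full(self, catalog):
        reports = [
            make_report(f"C{i}", (("Remdesivir", "remdesivir"),), reactions=("Nausea",), age=70.0)
            for i in range(6)
        ] + [
            make_report(f"D{i}", (("Sotrovimab", "sotrovimab"),), reactions=("Rash",), age=71.0)
            for i in range(6)
        ]
        rs = ReportSet(reports=reports)
        strata = stratified_scan(rs, "Remdesivir", catalog, strata=("age",))
        assert strata["age<65"] == []
        full = scan(rs, "Remdesivir", catalog)
        assert [(r.pt, r.table) for r in strata["age>=65"]] == [
            (r.pt, r.table) for r in full
        ]

    def test_sex_strata_partition_n11(self, catalog):
        rs, _ = generate(SynthConfig(n_reports=1200, seed=6, duplicate_rate=0.0, multidrug_rate=0.0))
        full = {canon(r.pt): r.table.n11 for r in scan(rs, "Remdesivir", catalog)}
        strata = stratified_scan(rs, "Remdesivir", catalog, strata=("sex",))
        unspec = ReportSet(reports=[r for r in rs if r.sex == "unspecified"])
        unspec_scan = {
            canon(r.pt): r.table.n11 for r in scan(unspec, "Remdesivir", catalog)
        }
        for pt, n11 in full.items():
            total = sum(
                {canon(r.pt): r.table.n11 for r in strata[name]}.get(pt, 0)
                for name in ("sex=male", "sex=female")
            ) + unspec_scan.get(pt, 0)
            assert total == n11

    def test_hcp_sensitivity_consistent_when_reporting_is_independent(self, catalog):
        """Reporter-independent effects: HCP-only ln ROR within 3 SE of full."""
        cfg = SynthConfig(
            n_reports=20000,
            seed=8,
            duplicate_rate=0.0,
            multidrug_rate=0.0,
            effects=[
                EffectSpec(drug="Remdesivir", pt="Dysgeusia", log_or=math.log(5))
            ],
        )
        rs, _ = generate(cfg)
        full = {canon(r.pt): r for r in scan(rs, "Remdesivir", catalog)}
        strata = stratified_scan(rs, "Remdesivir", catalog, strata=("reporter",))
        hcp = {canon(r.pt): r for r in strata["reporter=hcp"]}
        res_full, res_hcp = full["dysgeusia"], hcp["dysgeusia"]
        t = res_hcp.table
        se_hcp = math.sqrt(1 / t.n11 + 1 / t.n12 + 1 / t.n21 + 1 / t.n22)
        assert abs(math.log(res_hcp.ror) - math.log(res_full.ror)) < 3 * se_hcp
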