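"""Closed-form disproportionality statistics against frozen values and oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal import signal_stats as ss
from pvsignal._util import round_half_up

T = ss.ContingencyTable(10, 90, 100, 9900, term="example")
INDEP = ss.ContingencyTable(5, 5, 5, 5)


class TestClosedForms:
    def test_ror_frozen_example(self):
        # exp(ln 11 ± 1.96·0.3481553) = (5.5601, 21.7645), confirmed by the
        # statsmodels Table2x2 oracle below
        est, lo, hi = ss.ror(T)
        assert round_half_up(est) == 11.00
        assert round_half_up(lo) == 5.56
        assert round_half_up(hi) == 21.76

    def test_prr_and_chi2_frozen_example(self):
        est, chi2 = ss.prr(T)
        assert round_half_up(est) == 10.00
        assert round_half_up(chi2) == 74.45

    def test_ic_frozen_example(self):
        ic, ic025 = ss.ic(T)
        assert round_half_up(ic) == 2.72
        assert round_half_up(ic025) == 1.65

    def test_ebgm_frozen_example(self):
        est, lo = ss.ebgm_simple(T)
        assert round_half_up(est) == 9.18
        assert round_half_up(lo) == 5.18

    def test_independence_table_all_ones(self):
        assert ss.ror(INDEP)[0] == pytest.approx(1.0)
        est, chi2 = ss.prr(INDEP)
        assert est == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert ss.ebgm_simple(INDEP)[0] == pytest.approx(1.0)

    def test_ror_inverted_by_swapping_diagonals(self):
        swapped = ss.ContingencyTable(T.b, T.a, T.d, T.c)
        assert ss.ror(swapped)[0] == pytest.approx(1 / ss.ror(T)[0])

    def test_chi2_invariant_under_transpose(self):
        transposed = ss.ContingencyTable(T.a, T.c, T.b, T.d)
        assert ss.chi_square(transposed) == pytest.approx(ss.chi_square(T))

    def test_ic_zero_when_observed_equals_expected(self):
        t = ss.ContingencyTable(10, 90, 90, 810)  # E = 100*100/1000 = 10 = a
        assert ss.ic(t)[0] == pytest.approx(0.0)

    def test_zero_cell_raises_without_correction(self):
        t = ss.ContingencyTable(5, 10, 0, 100)
        with pytest.raises(ss.ZeroCellError, match="correct"):
            ss.ror(t)
        est, lo, hi = ss.ror(t, correct_zero_cells=True)
        assert est > 0 and lo < est < hi

    def test_ic_defined_at_a_zero(self):
        ic, ic025 = ss.ic(ss.ContingencyTable(0, 10, 5, 100))
        assert math.isfinite(ic) and ic025 < ic


tables = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 5000)
)


class TestProperties:
    @given(tables)
    def test_direction_agreement(self, cells):
        """(ROR−1), (PRR−1), (EBGM−1) and IC's sign all follow sign(ad−bc)."""
        t = ss.ContingencyTable(*cells)
        sign = np.sign(t.a * t.d - t.b * t.c)
        assert np.sign(ss.ror(t)[0] - 1) == sign
        assert np.sign(round(ss.prr(t)[0] - 1, 12)) == sign
        assert np.sign(round(ss.ebgm_simple(t)[0] - 1, 12)) == sign
        assert np.sign(round(ss.ic(t)[0], 9)) == np.sign(round(t.a - t.expected, 9))

    @given(st.integers(0, 10_000))
    def test_ic025_strictly_below_ic(self, a):
        t = ss.ContingencyTable(a, 50, 50, 1000)
        ic, ic025 = ss.ic(t)
        assert ic025 < ic

    @given(tables)
    def test_ror_bounds_bracket_estimate(self, cells):
        est, lo, hi = ss.ror(ss.ContingencyTable(*cells))
        assert lo <= est <= hi


class TestAgainstLibraryOracles:
    def test_ror_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(42)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 400, size=4)
            t = ss.ContingencyTable(int(a), int(b), int(c), int(d))
            est, lo, hi = ss.ror(t)
            tab = sm.Table2x2([[a, b], [c, d]])
            assert est == pytest.approx(tab.oddsratio, rel=1e-12)
            # statsmodels uses the unrounded 0.975 quantile; ours is 1.96
            sm_lo, sm_hi = tab.oddsratio_confint(0.05)
            assert lo == pytest.approx(sm_lo, rel=1e-3)
            assert hi == pytest.approx(sm_hi, rel=1e-3)

    def test_chi2_matches_scipy(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(43)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 400, size=4)
            t = ss.ContingencyTable(int(a), int(b), int(c), int(d))
            stat = chi2_contingency([[a, b], [c, d]], correction=False).statistic
            assert ss.chi_square(t) == pytest.approx(stat, rel=1e-10)


class TestSignalRule:
    def test_all_four_criteria_met(self):
        # strong gastrointestinal-style row: every bound clears its threshold
        flags, signal = ss.evaluate_flags(
            a=3387, ror_lo95=3.96, prr_value=2.64, chi2=4210.2, ic025=1.34, ebgm05=2.52
        )
        assert all(flags.values()) and signal

    def test_partial_criteria_not_a_signal(self):
        # PRR below 2 and EBGM05 below 2 even though ROR/IC flag
        flags, signal = ss.evaluate_flags(
            a=4052, ror_lo95=2.00, prr_value=1.47, chi2=995.27, ic025=0.50, ebgm05=1.40
        )
        assert flags["ror"] and flags["ic"]
        assert not flags["prr"] and not flags["ebgm"] and not signal

    def test_protective_row_zero_flags(self):
        flags, signal = ss.evaluate_flags(
            a=1061, ror_lo95=0.87, prr_value=0.94, chi2=5.67, ic025=-0.19, ebgm05=0.88
        )
        assert not any(flags.values()) and not signal

    def test_min_count_gates_ror_and_prr(self):
        flags, _ = ss.evaluate_flags(
            a=2, ror_lo95=5.0, prr_value=8.0, chi2=30.0, ic025=1.0, ebgm05=3.0, min_count=3
        )
        assert not flags["ror"] and not flags["prr"]


class TestContingencyAndScreen:
    def test_build_contingency_enumeration(self):
        events = pd.DataFrame({
            "caseid": ["t1", "t2", "o1"],
            "pt": ["X", "X", "Y"],
            "soc": ["S", "S", "S"],
        })
        t = ss.build_contingency(events, {"t1", "t2"}, term="X", level="pt")
        assert (t.a, t.b, t.c, t.d, t.N) == (2, 0, 0, 1, 3)

    def test_empty_target_set(self):
        events = pd.DataFrame({"caseid": ["o1"], "pt": ["X"], "soc": ["S"]})
        t = ss.build_contingency(events, set(), term="X")
        assert t.a == 0 and t.b == 0

    def test_screen_flags_planted_signal(self):
        from pvsignal import faers_io, synthetic

        catalog = [(f"BG_{i:02d}", f"SOC_{i % 5}", 0.10) for i in range(20)]
        catalog.append(("Planted term", "SOC_0", 0.02))
        cfg = synthetic.SimConfig(
            n_cases=6000, target_drug_share=0.1, pt_catalog=catalog,
            effect_map={"Planted term": 8.0}, onset_map={"default": (16.57, 0.28)},
            duplicate_rate=0.0, deleted_rate=0.0, seed=3,
        )
        cohort = synthetic.generate_cohort(cfg)
        events = faers_io.map_pt_to_soc(cohort.tables["reac"], cohort.dictionary)
        target = faers_io.extract_target_cases(cohort.tables["drug"], ["rucaparib"])
        results = ss.screen(events, target, level="pt")
        row = results.set_index("term").loc["Planted term"]
        assert bool(row["signal"])
        assert results.attrs["n_signals"] >= 1

    def test_screen_min_count_above_all_counts_is_empty(self):
        events = pd.DataFrame({
            "caseid": ["1", "2"], "pt": ["X", "Y"], "soc": ["S", "S"],
        })
        out = ss.screen(events, {"1"}, min_count=99)
        assert len(out) == 0 and out.attrs["n_signals"] == 0

    def test_screen_sorted_by_soc_then_descending_count(self, small_cohort):
        from pvsignal import faers_io

        _, cohort = small_cohort
        events = faers_io.map_pt_to_soc(cohort.tables["reac"], cohort.dictionary)
        target = faers_io.extract_target_cases(cohort.tables["drug"], ["rucaparib"])
        out = ss.screen(events, target, level="pt")
        for _, grp in out.groupby("soc", sort=False):
            assert grp["a"].is_monotonic_decreasing
        assert list(out["soc"]) == sorted(out["soc"])
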