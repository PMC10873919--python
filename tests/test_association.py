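"""Odds-ratio machinery: codings, continuity correction, Wald intervals."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from felhcm import catalog
from felhcm.association import (
    CaseControlAssociation,
    InheritanceModel,
    TwoByTwo,
    allele_frequency,
    collapse,
    evaluate_association,
    format_ci,
    format_or,
    odds_ratio,
    ps4_check,
    stern_style_or,
)
from felhcm.datatypes import AnalysisConfig, GenotypeCounts

A = InheritanceModel.ALLELIC
R = InheritanceModel.RECESSIVE
D = InheritanceModel.DOMINANT


class TestAlleleFrequency:
    def test_breed_stratified_value(self):
        # largest tabulated breed block: q = (1444 + 150) / (2 * 14027)
        assert allele_frequency(GenotypeCounts(12508, 1444, 75)) == pytest.approx(
            0.0568, abs=5e-5
        )

    def test_bounds(self):
        assert allele_frequency(GenotypeCounts(10, 0, 0)) == 0.0
        assert allele_frequency(GenotypeCounts(0, 0, 7)) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            allele_frequency(GenotypeCounts(0, 0, 0))


class TestCollapse:
    def test_allelic_hand_count(self):
        t = collapse(GenotypeCounts(8, 3, 9), GenotypeCounts(10, 6, 1), A)
        assert t.cells() == (21, 19, 8, 26)

    def test_recessive_hand_count(self):
        t = collapse(GenotypeCounts(8, 3, 9), GenotypeCounts(10, 6, 1), R)
        assert t.cells() == (9, 11, 1, 16)

    def test_dominant_hand_count(self):
        t = collapse(GenotypeCounts(8, 3, 9), GenotypeCounts(10, 6, 1), D)
        assert t.cells() == (12, 8, 7, 10)

    def test_all_zero(self):
        t = collapse(GenotypeCounts(0, 0, 0), GenotypeCounts(0, 0, 0), A)
        assert t.cells() == (0, 0, 0, 0)

    @given(
        case=st.tuples(*[st.integers(0, 20)] * 3),
        control=st.tuples(*[st.integers(0, 20)] * 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_margins_preserved(self, case, control):
        gc, gk = GenotypeCounts(*case), GenotypeCounts(*control)
        for model, per_animal in ((A, 2), (R, 1), (D, 1)):
            t = collapse(gc, gk, model)
            assert t.a + t.b == per_animal * gc.total
            assert t.c + t.d == per_animal * gk.total


class TestOddsRatio:
    def test_uncorrected_wald(self, cfg):
        est = odds_ratio(collapse(GenotypeCounts(8, 3, 9), GenotypeCounts(10, 6, 1), A), cfg)
        assert est.or_point == pytest.approx(3.59, abs=5e-3)
        assert est.ci_low == pytest.approx(1.31, abs=5e-3)
        assert est.ci_high == pytest.approx(9.83, abs=5e-3)
        assert est.significant and not est.corrected

    def test_zero_cell_triggers_correction(self, cfg):
        # variant-allele count zero in controls: (Wt 8, Vt 10) vs (Wt 14, Vt 0)
        est = odds_ratio(TwoByTwo(10, 8, 0, 14, A), cfg)
        assert est.corrected
        assert est.or_point == pytest.approx(35.82, abs=5e-3)
        assert est.ci_low == pytest.approx(1.85, abs=5e-3)
        assert est.ci_high == pytest.approx(692, abs=0.5)

    def test_symmetric_table(self, cfg):
        est = odds_ratio(TwoByTwo(5, 5, 5, 5, A), cfg)
        assert est.or_point == 1.0
        assert est.ci_low * est.ci_high == pytest.approx(1.0)
        assert not est.significant

    def test_policy_always_and_never(self):
        t = TwoByTwo(5, 5, 5, 5, A)
        always = odds_ratio(t, AnalysisConfig(haldane_policy="always"))
        assert always.corrected
        zero = TwoByTwo(5, 0, 5, 5, A)
        with pytest.raises(ValueError):
            odds_ratio(zero, AnalysisConfig(haldane_policy="never"))
        ok = odds_ratio(zero, AnalysisConfig(haldane_policy="auto"))
        assert ok.corrected

    @given(cells=st.tuples(*[st.integers(1, 6)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_matches_definition_oracle(self, cells):
        # odds of exposure in cases over odds of exposure in controls
        a, b, c, d = cells
        est = odds_ratio(TwoByTwo(a, b, c, d, A), AnalysisConfig())
        assert est.or_point == pytest.approx((a / b) / (c / d))
        assert not est.corrected

    @given(cells=st.tuples(*[st.integers(0, 12)] * 4))
    @settings(max_examples=150, deadline=None)
    def test_swapping_arms_inverts(self, cells):
        a, b, c, d = cells
        cfg = AnalysisConfig()
        est = odds_ratio(TwoByTwo(a, b, c, d, A), cfg)
        swapped = odds_ratio(TwoByTwo(c, d, a, b, A), cfg)
        assert swapped.or_point == pytest.approx(1.0 / est.or_point)
        assert swapped.ci_low == pytest.approx(1.0 / est.ci_high)
        assert swapped.ci_high == pytest.approx(1.0 / est.ci_low)

    @given(cells=st.tuples(*[st.integers(1, 15)] * 4), idx=st.integers(0, 3))
    @settings(max_examples=150, deadline=None)
    def test_ci_width_shrinks_with_data(self, cells, idx):
        cfg = AnalysisConfig()
        bigger = list(cells)
        bigger[idx] += 1
        w0 = odds_ratio(TwoByTwo(*cells, A), cfg)
        w1 = odds_ratio(TwoByTwo(*bigger, A), cfg)
        assert math.log(w1.ci_high / w1.ci_low) <= math.log(w0.ci_high / w0.ci_low) + 1e-12

    @given(cells=st.tuples(*[st.integers(1, 25)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_cross_check_against_statsmodels(self, cells):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        a, b, c, d = cells
        est = odds_ratio(TwoByTwo(a, b, c, d, A), AnalysisConfig())
        table = sm.Table2x2(np.array([[a, b], [c, d]]))
        assert est.or_point == pytest.approx(table.oddsratio)
        lo, hi = table.oddsratio_confint(0.05)
        # identical formula; only the critical value differs (1.96 vs exact)
        assert math.log(est.ci_low) == pytest.approx(math.log(lo), abs=2e-3)
        assert math.log(est.ci_high) == pytest.approx(math.log(hi), abs=2e-3)

    def test_significance_iff_ci_excludes_one(self):
        rng = np.random.default_rng(4)
        cfg = AnalysisConfig()
        for _ in range(50):
            cells = rng.integers(0, 15, size=4)
            est = odds_ratio(TwoByTwo(*map(float, cells), A), cfg)
            assert est.significant == (not est.ci_low <= 1.0 <= est.ci_high)


class TestEvaluateAssociation:
    def test_model_order_and_values(self, cfg):
        ests = evaluate_association(GenotypeCounts(8, 3, 9), GenotypeCounts(10, 6, 1), cfg)
        assert [e.model for e in ests] == [A, R, D]
        assert [round(e.or_point, 2) for e in ests] == [3.59, 13.09, 2.14]

    def test_protective_and_null_variants(self, cfg):
        ests = evaluate_association(GenotypeCounts(12, 25, 16), GenotypeCounts(6, 17, 8), cfg)
        assert [round(e.or_point, 2) for e in ests] == [1.02, 1.24, 0.82]
        ests = evaluate_association(GenotypeCounts(8, 4, 2), GenotypeCounts(10, 3, 1), cfg)
        assert [round(e.or_point, 2) for e in ests] == [1.84, 2.17, 1.88]


class TestHomozygoteContrast:
    def test_point_value(self, cfg):
        est = stern_style_or(GenotypeCounts(8, 3, 9), GenotypeCounts(10, 6, 1), cfg)
        assert est.or_point == pytest.approx(11.25)

    def test_zero_homozygote_path_finite(self, cfg):
        est = stern_style_or(GenotypeCounts(5, 5, 0), GenotypeCounts(5, 5, 0), cfg)
        assert est.corrected and math.isfinite(est.or_point)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_het_dropped_coding(self, seed, cfg):
        rng = np.random.default_rng(seed)
        case = GenotypeCounts(*map(int, rng.integers(1, 20, 3)))
        control = GenotypeCounts(*map(int, rng.integers(1, 20, 3)))
        est = stern_style_or(case, control, cfg)
        direct = odds_ratio(
            TwoByTwo(case.n_vtvt, case.n_wtwt, control.n_vtvt, control.n_wtwt, R), cfg
        )
        assert est.or_point == pytest.approx(direct.or_point)


class TestPs4Check:
    def test_fulfilled_via_recessive_only(self, cfg):
        ests = evaluate_association(GenotypeCounts(8, 3, 9), GenotypeCounts(10, 6, 1), cfg)
        fulfilled, witness = ps4_check(ests, cfg)
        assert fulfilled and witness is R  # allelic 3.59 significant but <= 5

    def test_not_fulfilled_without_signal(self, cfg):
        ests = evaluate_association(GenotypeCounts(12, 25, 16), GenotypeCounts(6, 17, 8), cfg)
        assert ps4_check(ests, cfg) == (False, None)

    def test_null_ors(self, cfg):
        ests = evaluate_association(GenotypeCounts(5, 5, 5), GenotypeCounts(5, 5, 5), cfg)
        assert ps4_check(ests, cfg) == (False, None)

    def test_empty_rejected(self, cfg):
        with pytest.raises(ValueError):
            ps4_check([], cfg)


class TestModelResultsInterface:
    def test_fit_and_summary(self, cfg):
        counts = catalog.case_control_counts()[catalog.A31P]
        res = CaseControlAssociation(counts[1], counts[2], cfg).fit()
        assert res.n == 37
        assert res.by_model(R).or_point == pytest.approx(13.09, abs=5e-3)
        text = res.summary()
        assert "3.59" in text and "13.09" in text and "fulfilled via RECESSIVE" in text
        frame = res.to_frame()
        assert list(frame["model"]) == ["ALLELIC", "RECESSIVE", "DOMINANT"]


def test_report_formatting():
    assert format_or(3.5921) == "3.59"
    assert format_or(691.83) == "692"
    assert format_or(3.0) == "3"
    assert format_ci(1.8549, 691.83) == "[1.85–692]"
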