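"""Evidence vocabulary, combining rules, and frequency criteria."""

import math

import pytest
from conftest import (
    assert_combine_matches_oracle,
    enumerate_bounded_counts,
    evidence_from_counts,
)

from felhcm.acmg import (
    Category,
    Criterion,
    Direction,
    EvidenceSet,
    Stage,
    Strength,
    TvSpec,
    af_criterion_acmg,
    af_criterion_tv,
    classify_two_stage,
    combine,
    tv_from_parameters,
)
from felhcm.datatypes import AnalysisConfig


def ev(*codes: str) -> EvidenceSet:
    return EvidenceSet("x", [Criterion(c) for c in codes])


class TestCriterionVocabulary:
    @pytest.mark.parametrize(
        "code,direction,strength",
        [
            ("PVS1", Direction.PATHOGENIC, Strength.VERY_STRONG),
            ("PS4", Direction.PATHOGENIC, Strength.STRONG),
            ("PM2", Direction.PATHOGENIC, Strength.MODERATE),
            ("PP3", Direction.PATHOGENIC, Strength.SUPPORTING),
            ("BA1", Direction.BENIGN, Strength.STAND_ALONE),
            ("BS1", Direction.BENIGN, Strength.STRONG),
            ("BP4", Direction.BENIGN, Strength.SUPPORTING),
            ("PM2*", Direction.PATHOGENIC, Strength.MODERATE),
            ("BS1*", Direction.BENIGN, Strength.STRONG),
            ("BA1*", Direction.BENIGN, Strength.STAND_ALONE),
        ],
    )
    def test_prefix_defaults(self, code, direction, strength):
        c = Criterion(code)
        assert c.direction is direction and c.strength is strength

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="PS9"):
            Criterion("PS9")

    def test_strength_override(self):
        weak_ps4 = Criterion("PS4").with_strength(Strength.SUPPORTING)
        # downgraded case-count evidence alone no longer reaches pathogenic
        assert combine(ev("PS3", "PP2").adding(weak_ps4)).category is Category.LIKELY_PATHOGENIC

    def test_frequency_families_mutually_exclusive(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            ev("PM2", "BS1*")
        with pytest.raises(ValueError, match="at most one"):
            ev("PM2", "BA1")
        with pytest.raises(ValueError, match="duplicate"):
            ev("PP3", "PP3")


class TestCombine:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (("PS4", "PS3", "PP2"), Category.PATHOGENIC),
            (("PS3", "PP3", "PP2"), Category.LIKELY_PATHOGENIC),
            (("PP2",), Category.VUS),
            ((), Category.VUS),
            (("PS4", "PP3", "PS1", "PM5", "PP2"), Category.PATHOGENIC),
            (("BA1",), Category.BENIGN),
            (("PP3", "BS1*"), Category.VUS),
            (("PVS1", "PM1"), Category.LIKELY_PATHOGENIC),
            (("PVS1", "PS1"), Category.PATHOGENIC),
            (("BS2", "BS3"), Category.BENIGN),
            (("BS2", "BP1"), Category.LIKELY_BENIGN),
            (("BP1", "BP2"), Category.LIKELY_BENIGN),
            (("PS1", "PM1", "BS2", "BS3"), Category.VUS),  # conflict
            (("PS1", "PM1", "BA1"), Category.BENIGN),  # stand-alone overrides
        ],
    )
    def test_rule_outcomes(self, codes, expected):
        assert combine(ev(*codes)).category is expected

    def test_exhaustive_against_rule_oracle(self):
        assert assert_combine_matches_oracle() == 2160

    def test_pathogenic_monotonicity(self):
        order = {
            Category.PATHOGENIC: 2,
            Category.LIKELY_PATHOGENIC: 1,
            Category.VUS: 0,
        }
        additions = [(1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)]
        for counts in enumerate_bounded_counts():
            pvs, ps, pm, pp, ba, bs, bp = counts
            if ba or bs or bp:
                continue
            base = order[combine(evidence_from_counts(*counts)).category]
            for dv, ds, dm, dp in additions:
                bigger = (pvs + dv, ps + ds, pm + dm, pp + dp, 0, 0, 0)
                if bigger[0] > 1 or bigger[1] > 4 or bigger[2] > 5 or bigger[3] > 5:
                    continue
                after = order[combine(evidence_from_counts(*bigger)).category]
                assert after >= base, (counts, bigger)


class TestFrequencyCriteria:
    def test_fixed_cutoff(self, cfg):
        assert af_criterion_acmg(0.2263, cfg).code == "BA1"
        assert af_criterion_acmg(0.024, cfg).code == "PM2"
        assert af_criterion_acmg(0.05, cfg) is None

    def test_fixed_cutoff_domain(self, cfg):
        with pytest.raises(ValueError):
            af_criterion_acmg(1.5, cfg)

    def test_tv_threshold(self):
        assert af_criterion_tv(0.056, TvSpec(tv=0.17)).code == "PM2*"
        assert af_criterion_tv(0.2732, TvSpec(tv=0.27)).code == "BS1*"
        assert af_criterion_tv(0.0, TvSpec(tv=0.02)).code == "PM2*"
        assert af_criterion_tv(0.27, TvSpec(tv=0.27)).code == "PM2*"  # at-threshold

    def test_tv_never_assigns_stand_alone(self):
        for af in (0.0, 0.3, 0.9):
            assert af_criterion_tv(af, TvSpec(tv=0.2)).code != "BA1*"


class TestTvFormula:
    def test_recessive_closed_form(self):
        spec = TvSpec(prevalence=0.04, max_allelic_contribution=1.0, penetrance=1.0,
                      inheritance="RECESSIVE")
        assert tv_from_parameters(spec) == pytest.approx(0.2)

    def test_penetrance_scaling(self):
        base = dict(prevalence=0.03, max_allelic_contribution=0.5)
        dom1 = tv_from_parameters(TvSpec(**base, penetrance=0.8, inheritance="DOMINANT"))
        dom2 = tv_from_parameters(TvSpec(**base, penetrance=0.4, inheritance="DOMINANT"))
        assert dom2 == pytest.approx(2 * dom1)
        rec1 = tv_from_parameters(TvSpec(**base, penetrance=0.8, inheritance="RECESSIVE"))
        rec2 = tv_from_parameters(TvSpec(**base, penetrance=0.4, inheritance="RECESSIVE"))
        assert rec2 == pytest.approx(math.sqrt(2) * rec1)

    def test_zero_penetrance_rejected(self):
        with pytest.raises(ValueError):
            tv_from_parameters(
                TvSpec(prevalence=0.03, max_allelic_contribution=1.0, penetrance=0.0,
                       inheritance="DOMINANT")
            )

    def test_matches_hwe_algebra_oracle(self):
        # independent re-derivation: find the largest q such that the share
        # of disease attributable to the risk genotype class stays credible
        for prev in (0.005, 0.03, 0.15):
            for contrib in (0.1, 0.5, 1.0):
                for pen in (0.25, 0.5, 1.0):
                    # recessive: q^2 * pen = prev * contrib
                    q_rec = math.sqrt(prev * contrib / pen)
                    got = tv_from_parameters(
                        TvSpec(prevalence=prev, max_allelic_contribution=contrib,
                               penetrance=pen, inheritance="RECESSIVE")
                    )
                    assert got == pytest.approx(min(q_rec, 1.0))
                    # dominant (rare-allele carriers ~ 2q): 2q * pen = prev * contrib
                    q_dom = prev * contrib / (2 * pen)
                    got = tv_from_parameters(
                        TvSpec(prevalence=prev, max_allelic_contribution=contrib,
                               penetrance=pen, inheritance="DOMINANT")
                    )
                    assert got == pytest.approx(min(q_dom, 1.0))

    def test_clipped_to_one(self):
        spec = TvSpec(prevalence=1.0, max_allelic_contribution=1.0, penetrance=0.05,
                      inheritance="DOMINANT")
        assert tv_from_parameters(spec) == 1.0


class TestTwoStage:
    def test_common_variant_flips_only_under_fixed_cutoff(self, cfg):
        stages = classify_two_stage(ev("PS4", "PS3", "PP2"), 0.056, TvSpec(tv=0.17), cfg)
        assert stages[Stage.INITIAL].category is Category.PATHOGENIC
        assert stages[Stage.ACMG_AF].category is Category.BENIGN
        assert stages[Stage.TV_AF].category is Category.PATHOGENIC

    def test_insufficient_evidence_stays_vus_under_tv(self, cfg):
        stages = classify_two_stage(ev("PP2"), 0.2263, TvSpec(tv=0.40), cfg)
        assert [stages[s].category for s in Stage] == [
            Category.VUS,
            Category.BENIGN,
            Category.VUS,
        ]

    def test_above_tv_adds_benign_but_not_enough(self, cfg):
        stages = classify_two_stage(ev(), 0.2732, TvSpec(tv=0.27), cfg)
        assert stages[Stage.TV_AF].category is Category.VUS
        assert stages[Stage.ACMG_AF].category is Category.BENIGN

    def test_base_with_frequency_rejected(self, cfg):
        with pytest.raises(ValueError):
            classify_two_stage(ev("PM2"), 0.01, TvSpec(tv=0.2), cfg)

    def test_stage_tags(self, cfg):
        stages = classify_two_stage(ev("PP3"), 0.5187, TvSpec(tv=0.15), cfg)
        assert [c.stage for c in stages.values()] == list(Stage)
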