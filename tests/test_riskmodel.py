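"""rCM nine-group classifier, treatment allocation, and population model."""

import itertools

import numpy as np
import pytest

from conftest import make_cohort, make_profile, make_record
from mbrisk.cohort import Group, Histology, MStage, Subgroup
from mbrisk.riskmodel import (
    Allocation,
    AllocationModel,
    RiskGroup,
    Stratum,
    allocate_treatment,
    classify,
    classify_g3g4,
    classify_shh,
    classify_wnt,
    expected_population_survival,
    reference_allocation_model,
    tier_rank,
)
from mbrisk.simulate import CohortConfig, generate_cohort
from mbrisk.survival import SurvivalSample, km_estimate


def shh_profile(pid="P1", **kw):
    return make_profile(pid, group=Group.SHH, **kw)


def g34_profile(pid="P1", group=Group.G3, subgroup=Subgroup.G34_1, **kw):
    return make_profile(pid, group=group, subgroup=subgroup, **kw)


class TestClassifySHH:
    def test_tp53_mutation_is_very_high_risk(self):
        a = classify_shh(shh_profile(tp53_mut=True), MStage.M0, Histology.CLASSIC)
        assert a.risk_group == RiskGroup.SHH_VHR
        assert "TP53 mutation" in a.triggering_features

    def test_isolated_mycn_amplification_is_average_risk(self):
        a = classify_shh(shh_profile(mycn_amp=True), MStage.M0, Histology.CLASSIC)
        assert a.risk_group == RiskGroup.SHH_AR
        assert "MYCN amplification" in a.triggering_features

    def test_vhr_takes_precedence_over_ar_features(self):
        a = classify_shh(shh_profile(mycn_amp=True), MStage.M_PLUS, Histology.CLASSIC)
        assert a.risk_group == RiskGroup.SHH_VHR

    def test_no_risk_features_is_low_risk(self):
        a = classify_shh(shh_profile(), MStage.M0, Histology.CLASSIC)
        assert a.risk_group == RiskGroup.SHH_LR

    def test_decisive_unknown_blocks_classification(self):
        a = classify_shh(shh_profile(tp53_mut=None), MStage.M0, Histology.CLASSIC)
        assert a.risk_group == RiskGroup.UNCLASSIFIABLE
        assert "tp53_mut" in a.blocking_features

    def test_non_decisive_unknown_does_not_block(self):
        # TP53 already forces VHR; unknown GLI2 cannot change the tier
        a = classify_shh(shh_profile(tp53_mut=True, gli2_amp=None), MStage.M0, Histology.CLASSIC)
        assert a.risk_group == RiskGroup.SHH_VHR

    def test_wrong_group_rejected(self):
        with pytest.raises(ValueError):
            classify_shh(make_profile("P1", group=Group.G3), MStage.M0, Histology.CLASSIC)


class TestClassifyG34:
    def test_m0_subgroup7_is_low_risk(self):
        a = classify_g3g4(g34_profile(subgroup=Subgroup.G34_7), MStage.M0)
        assert a.risk_group == RiskGroup.G34_LR

    def test_metastatic_subgroup2_is_very_high_risk(self):
        a = classify_g3g4(g34_profile(subgroup=Subgroup.G34_2), MStage.M_PLUS)
        assert a.risk_group == RiskGroup.G34_VHR

    def test_myc_amplification_overrides_favorable_subgroup(self):
        a = classify_g3g4(g34_profile(subgroup=Subgroup.G34_7, myc_amp=True), MStage.M0)
        assert a.risk_group == RiskGroup.G34_VHR

    def test_metastatic_without_vhr_features_is_high_risk(self):
        a = classify_g3g4(g34_profile(subgroup=Subgroup.G34_8), MStage.M_PLUS)
        assert a.risk_group == RiskGroup.G34_HR

    def test_m0_without_lr_or_vhr_features_is_average_risk(self):
        a = classify_g3g4(g34_profile(subgroup=Subgroup.G34_5), MStage.M0)
        assert a.risk_group == RiskGroup.G34_AR

    def test_wca_fr_phenotype_gives_low_risk_when_m0(self):
        a = classify_g3g4(
            g34_profile(group=Group.G4, subgroup=Subgroup.G34_6, wca_fr=True), MStage.M0
        )
        assert a.risk_group == RiskGroup.G34_LR

    def test_unknown_subgroup_is_decisive_for_m0_nonamplified(self):
        prof = make_profile("P1", group=Group.G3, subgroup=Subgroup.NONE)
        a = classify_g3g4(prof, MStage.M0)
        assert a.risk_group == RiskGroup.UNCLASSIFIABLE
        assert "subgroup" in a.blocking_features


class TestClassifyWNT:
    def test_m0_is_low_risk(self):
        a = classify_wnt(make_profile("P1", group=Group.WNT), MStage.M0)
        assert a.risk_group == RiskGroup.WNT_LR

    def test_metastatic_is_high_risk_with_assumption_note(self):
        a = classify_wnt(make_profile("P1", group=Group.WNT), MStage.M_PLUS)
        assert a.risk_group == RiskGroup.WNT_HR
        assert any("assumption" in n for n in a.notes)

    def test_unknown_m_stage_is_unclassifiable(self):
        a = classify_wnt(make_profile("P1", group=Group.WNT), MStage.UNKNOWN)
        assert a.risk_group == RiskGroup.UNCLASSIFIABLE


def test_classify_dispatches_by_group_and_handles_unknown():
    cohort = make_cohort(
        (make_record("W"), make_profile("W", group=Group.WNT)),
        (make_record("S"), make_profile("S", group=Group.SHH)),
        (make_record("T"), make_profile("T", group=Group.G3, subgroup=Subgroup.G34_3)),
        (make_record("F"), make_profile("F", group=Group.G4, subgroup=Subgroup.G34_7)),
    )
    groups = [a.risk_group for a in classify(cohort)]
    assert groups == [RiskGroup.WNT_LR, RiskGroup.SHH_LR, RiskGroup.G34_VHR, RiskGroup.G34_LR]
    assert classify(make_cohort()) == []
    unknown = make_cohort((make_record("U"), make_profile("U", group=Group.UNKNOWN)))
    (a,) = classify(unknown)
    assert a.risk_group == RiskGroup.UNCLASSIFIABLE
    assert a.allocation == Allocation.NONE
    assert a.blocking_features == ["group"]


# ---------------------------------------------------------------------------
# Lattice properties: independent nested-if oracles re-derive each tier.

def _shh_oracle(tp53, gli2, m, lca, mycn, p17):
    if tp53 or gli2 or m:
        return RiskGroup.SHH_VHR
    if lca or mycn or p17:
        return RiskGroup.SHH_AR
    return RiskGroup.SHH_LR


def _g34_oracle(sub, myc, m, wca):
    if sub == 3 or myc or (m and sub == 2):
        return RiskGroup.G34_VHR
    if not m and (sub == 7 or wca):
        return RiskGroup.G34_LR
    if m:
        return RiskGroup.G34_HR
    return RiskGroup.G34_AR


def test_shh_lattice_exhaustive_exclusive_and_matches_oracle():
    for tp53, gli2, m, lca, mycn, p17 in itertools.product([False, True], repeat=6):
        prof = shh_profile(tp53_mut=tp53, gli2_amp=gli2, mycn_amp=mycn, arm_17p_loss=p17)
        a = classify_shh(
            prof,
            MStage.M_PLUS if m else MStage.M0,
            Histology.LCA if lca else Histology.CLASSIC,
        )
        assert a.risk_group == _shh_oracle(tp53, gli2, m, lca, mycn, p17)
        assert a.risk_group != RiskGroup.UNCLASSIFIABLE


def test_g34_lattice_exhaustive_exclusive_and_matches_oracle():
    for sub, myc, m, wca, group in itertools.product(
        range(1, 9), [False, True], [False, True], [False, True], [Group.G3, Group.G4]
    ):
        prof = g34_profile(group=group, subgroup=Subgroup(f"G34_{sub}"), myc_amp=myc, wca_fr=wca)
        a = classify_g3g4(prof, MStage.M_PLUS if m else MStage.M0)
        assert a.risk_group == _g34_oracle(sub, myc, m, wca)
        assert a.risk_group != RiskGroup.UNCLASSIFIABLE


def test_adding_vhr_feature_never_lowers_the_tier():
    for tp53, gli2, m, lca, mycn, p17 in itertools.product([False, True], repeat=6):
        base = _shh_oracle(tp53, gli2, m, lca, mycn, p17)
        for flipped in (
            _shh_oracle(True, gli2, m, lca, mycn, p17),
            _shh_oracle(tp53, True, m, lca, mycn, p17),
            _shh_oracle(tp53, gli2, True, lca, mycn, p17),
        ):
            assert tier_rank(flipped) >= tier_rank(base)
    for sub, myc, m, wca in itertools.product(range(1, 9), [False, True], [False, True], [False, True]):
        base = _g34_oracle(sub, myc, m, wca)
        assert tier_rank(_g34_oracle(sub, True, m, wca)) >= tier_rank(base)
        assert tier_rank(_g34_oracle(3, myc, m, wca)) >= tier_rank(base)


@pytest.mark.parametrize(
    "risk, expected",
    [
        (RiskGroup.WNT_LR, Allocation.LDCSI_REGIMEN),
        (RiskGroup.WNT_HR, Allocation.HDCSI_REGIMEN),
        (RiskGroup.SHH_LR, Allocation.LDCSI_REGIMEN),
        (RiskGroup.SHH_AR, Allocation.SDCSI_REGIMEN),
        (RiskGroup.SHH_VHR, Allocation.NOVEL_THERAPY),
        (RiskGroup.G34_LR, Allocation.LDCSI_REGIMEN),
        (RiskGroup.G34_AR, Allocation.SDCSI_REGIMEN),
        (RiskGroup.G34_HR, Allocation.HDCSI_REGIMEN),
        (RiskGroup.G34_VHR, Allocation.HDCSI_CARBO_REGIMEN),
    ],
)
def test_allocation_map(risk, expected):
    from mbrisk.riskmodel import RiskAssignment

    assert allocate_treatment(RiskAssignment("P", risk)) == expected


def test_unclassifiable_gets_no_allocation_with_warning():
    from mbrisk.riskmodel import RiskAssignment

    with pytest.warns(UserWarning):
        assert allocate_treatment(RiskAssignment("P", RiskGroup.UNCLASSIFIABLE)) == Allocation.NONE


class TestAllocationModel:
    def test_single_stratum(self):
        m = AllocationModel(strata=(Stratum("only", 1.0, 0.9),))
        assert expected_population_survival(m) == pytest.approx(0.9)

    def test_reference_five_strata_weighted_sum(self):
        # 0.40x0.90 + 0.25x0.80 + 0.20x0.60 + 0.10x0.60 + 0.05x0.40 = 0.76
        assert expected_population_survival(reference_allocation_model()) == pytest.approx(0.76)

    def test_two_equal_strata(self):
        m = AllocationModel(strata=(Stratum("a", 0.5, 0.5), Stratum("b", 0.5, 0.7)))
        assert expected_population_survival(m) == pytest.approx(0.6)

    def test_fractions_must_sum_to_one(self):
        m = AllocationModel(strata=(Stratum("a", 0.5, 0.5),))
        with pytest.raises(ValueError, match="sum to 1"):
            expected_population_survival(m)


def test_survival_ordering_across_g34_tiers_on_synthetic_cohort():
    cohort, _ = generate_cohort(CohortConfig(n=4000, seed=13))
    assignments = {a.patient_id: a.risk_group for a in classify(cohort)}
    pfs5 = {}
    for tier in (RiskGroup.G34_LR, RiskGroup.G34_AR, RiskGroup.G34_HR, RiskGroup.G34_VHR):
        t, e = [], []
        for rec, _prof in cohort:
            if assignments[rec.patient_id] == tier and rec.has_pfs:
                t.append(rec.pfs_months)
                e.append(rec.pfs_event)
        curve = km_estimate(SurvivalSample(np.asarray(t), np.asarray(e)))
        pfs5[tier] = curve.survival_at(60.0)
    assert pfs5[RiskGroup.G34_LR] > pfs5[RiskGroup.G34_AR] > pfs5[RiskGroup.G34_HR] > pfs5[RiskGroup.G34_VHR]
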