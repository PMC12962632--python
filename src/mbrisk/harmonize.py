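"""Cross-trial cohort harmonization.

Patients from the three source trials (ACNS0331 average-risk, ACNS0332
high-risk, SJMB03 mixed-risk) are placed into six analysis categories
defined by trial, metastatic stage, residual status, histology and
craniospinal-irradiation (CSI) arm, or excluded when their attribute
combination has no cross-trial analogue (M0 LC/A on SJMB03/ACNS0332,
M0R+ on SJMB03/ACNS0332).  The six analysis categories merge into four
treatment categories (LDCSI, SDCSI, HDCSI without carboplatin, HDCSI
with carboplatin) for outcome comparisons.

Unknown histology is treated as non-LC/A for category eligibility (the
trials stratified on reported histology); such assignments are flagged.
Protocol-ineligible combinations (e.g. a metastatic ACNS0331 record)
raise a validation error rather than being silently excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    CohortTable,
    CSIArm,
    Group,
    Histology,
    MStage,
    PatientRecord,
    RStatus,
    Subgroup,
    Trial,
    ValidationError,
)
from .survival import LogrankResult, SurvivalCurve, SurvivalSample, km_estimate, logrank_test


class CrossTrialCategory(enum.StrEnum):
    ACNS0331_LDCSI = "ACNS0331_LDCSI"
    ACNS0331_SDCSI = "ACNS0331_SDCSI"
    SJMB03_SDCSI = "SJMB03_SDCSI"
    SJMB03_HDCSI = "SJMB03_HDCSI"
    ACNS0332_HDCSI = "ACNS0332_HDCSI"
    ACNS0332_HDCSI_CARBO = "ACNS0332_HDCSI_Carbo"
    EXCLUDED = "EXCLUDED"


class TreatmentCategory(enum.StrEnum):
    LDCSI = "LDCSI"
    SDCSI = "SDCSI"
    HDCSI_NO_CARBO = "HDCSI_NoCarbo"
    HDCSI_CARBO = "HDCSI_Carbo"
    NONE = "none"


@dataclass
class CategoryAssignment:
    patient_id: str
    category: CrossTrialCategory
    rule: str
    histology_imputed: bool = False


def assign_category(p: PatientRecord) -> CategoryAssignment:
    """Assign a patient to exactly one cross-trial analysis category.

    Rules are applied in a fixed order; each assignment carries the
    matched rule label (or, for exclusions, the exclusion reason).
    """
    p.validate()
    histology_imputed = p.histology == Histology.UNKNOWN
    is_lca = p.histology == Histology.LCA

    def excluded(reason: str) -> CategoryAssignment:
        return CategoryAssignment(
            p.patient_id, CrossTrialCategory.EXCLUDED, reason, histology_imputed
        )

    if p.trial == Trial.ACNS0331:
        if p.m_stage == MStage.M_PLUS or p.r_status == RStatus.R_PLUS or is_lca:
            raise ValidationError(
                f"{p.patient_id}: high-risk attributes are protocol-ineligible on ACNS0331"
            )
        if p.csi_arm == CSIArm.HDCSI:
            raise ValidationError(f"{p.patient_id}: HDCSI was not an ACNS0331 arm")
        if p.m_stage == MStage.UNKNOWN:
            return excluded("unknown m_stage")
        if p.r_status == RStatus.UNKNOWN:
            return excluded("unknown r_status")
        if p.csi_arm == CSIArm.LDCSI:
            return CategoryAssignment(
                p.patient_id,
                CrossTrialCategory.ACNS0331_LDCSI,
                "ACNS0331, M0R0 non-LC/A, LDCSI",
                histology_imputed,
            )
        if p.csi_arm == CSIArm.SDCSI:
            return CategoryAssignment(
                p.patient_id,
                CrossTrialCategory.ACNS0331_SDCSI,
                "ACNS0331, M0R0 non-LC/A, SDCSI",
                histology_imputed,
            )
        return excluded("unknown csi_arm")

    if p.trial == Trial.SJMB03:
        if p.m_stage == MStage.M_PLUS:
            return CategoryAssignment(
                p.patient_id,
                CrossTrialCategory.SJMB03_HDCSI,
                "SJMB03, M+, HDCSI",
                histology_imputed,
            )
        if p.m_stage == MStage.UNKNOWN:
            return excluded("unknown m_stage")
        if p.r_status == RStatus.R_PLUS:
            return excluded("M0R+ on SJMB03")
        if p.r_status == RStatus.UNKNOWN:
            return excluded("unknown r_status")
        if is_lca:
            return excluded("M0 LC/A on SJMB03")
        if p.csi_arm == CSIArm.SDCSI:
            return CategoryAssignment(
                p.patient_id,
                CrossTrialCategory.SJMB03_SDCSI,
                "SJMB03, M0R0 non-LC/A, SDCSI",
                histology_imputed,
            )
        if p.csi_arm == CSIArm.UNKNOWN:
            return excluded("unknown csi_arm")
        return excluded("no matching rule")

    # ACNS0332
    if p.m_stage == MStage.M_PLUS:
        if p.carboplatin is None:
            return excluded("unknown carboplatin")
        if p.carboplatin:
            return CategoryAssignment(
                p.patient_id,
                CrossTrialCategory.ACNS0332_HDCSI_CARBO,
                "ACNS0332, M+, HDCSI with carboplatin",
                histology_imputed,
            )
        return CategoryAssignment(
            p.patient_id,
            CrossTrialCategory.ACNS0332_HDCSI,
            "ACNS0332, M+, HDCSI without carboplatin",
            histology_imputed,
        )
    if p.m_stage == MStage.UNKNOWN:
        return excluded("unknown m_stage")
    if is_lca:
        return excluded("M0 LC/A on ACNS0332")
    if p.r_status == RStatus.R_PLUS:
        return excluded("M0R+ on ACNS0332")
    if p.r_status == RStatus.UNKNOWN:
        return excluded("unknown r_status")
    return excluded("no matching rule")


_TREATMENT_MAP = {
    CrossTrialCategory.ACNS0331_LDCSI: TreatmentCategory.LDCSI,
    CrossTrialCategory.ACNS0331_SDCSI: TreatmentCategory.SDCSI,
    CrossTrialCategory.SJMB03_SDCSI: TreatmentCategory.SDCSI,
    CrossTrialCategory.SJMB03_HDCSI: TreatmentCategory.HDCSI_NO_CARBO,
    CrossTrialCategory.ACNS0332_HDCSI: TreatmentCategory.HDCSI_NO_CARBO,
    CrossTrialCategory.ACNS0332_HDCSI_CARBO: TreatmentCategory.HDCSI_CARBO,
    CrossTrialCategory.EXCLUDED: TreatmentCategory.NONE,
}


def treatment_category(c: CrossTrialCategory) -> TreatmentCategory:
    return _TREATMENT_MAP[c]


def assign_categories(cohort: CohortTable) -> list[CategoryAssignment]:
    return [assign_category(rec) for rec, _ in cohort]


def category_counts(assignments: list[CategoryAssignment]) -> dict[str, int]:
    counts = {str(c): 0 for c in CrossTrialCategory}
    for a in assignments:
        counts[str(a.category)] += 1
    return counts


# ---------------------------------------------------------------------------
# Cross-trial outcome comparison

_SUBGROUP_ALIASES = {f"G3/G4-{i}": Subgroup(f"G34_{i}") for i in range(1, 9)}
_SUBGROUP_ALIASES.update({f"SHH-{i}": Subgroup(f"SHH_{i}") for i in range(1, 5)})


@dataclass
class ComparisonReport:
    arms: tuple[TreatmentCategory, TreatmentCategory]
    stratum: str
    n_per_arm: dict[str, int]
    curves: dict[str, SurvivalCurve]
    logrank: LogrankResult
    pfs_5yr: dict[str, float]
    worse_arm: str | None
    notes: list[str] = field(default_factory=list)


def _stratum_filter(stratum: str):
    if stratum == "all":
        return lambda prof: True
    try:
        group = Group(stratum)
        return lambda prof: prof.group == group
    except ValueError:
        pass
    label = _SUBGROUP_ALIASES.get(stratum, stratum)
    try:
        sub = Subgroup(label)
    except ValueError:
        raise ValueError(f"unknown stratum {stratum!r}") from None
    return lambda prof: prof.subgroup == sub


def cross_trial_comparison(
    cohort: CohortTable,
    arms: tuple[TreatmentCategory, TreatmentCategory],
    stratum: str = "all",
) -> ComparisonReport:
    """Compare progression-free survival between two treatment
    categories, optionally within a molecular group or subgroup
    (stratum "all", a group name, or a subgroup such as "G3/G4-5").

    Returns per-arm ns and Kaplan-Meier curves with the log-rank
    statistic; deterministic for fixed input.
    """
    keep = _stratum_filter(stratum)
    samples: dict[str, SurvivalSample] = {}
    for arm in arms:
        times, events = [], []
        for rec, prof in cohort:
            if not keep(prof) or not rec.has_pfs or rec.pfs_months <= 0:
                continue
            if treatment_category(assign_category(rec).category) == arm:
                times.append(rec.pfs_months)
                events.append(rec.pfs_event)
        if not times:
            raise ValueError(f"no usable patients in arm {arm}")
        samples[str(arm)] = SurvivalSample(np.asarray(times), np.asarray(events))
    names = list(samples)
    lr = logrank_test([samples[a] for a in names])
    curves = {a: km_estimate(samples[a]) for a in names}
    pfs5 = {a: curves[a].survival_at(60.0) for a in names}
    worse = min(names, key=lambda a: pfs5[a]) if pfs5[names[0]] != pfs5[names[1]] else None
    notes = []
    if stratum in ("G3/G4-5", "G34_5") and TreatmentCategory.HDCSI_CARBO in arms:
        notes.append(
            "carboplatin showed worse PFS in G3/G4-5 in the source cohorts; the "
            "rCM allocation does not act on this signal"
        )
    return ComparisonReport(
        arms=arms,
        stratum=stratum,
        n_per_arm={a: len(samples[a]) for a in names},
        curves=curves,
        logrank=lr,
        pfs_5yr=pfs5,
        worse_arm=worse,
        notes=notes,
    )
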