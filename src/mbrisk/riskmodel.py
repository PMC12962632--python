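"""The revised clinico-molecular (rCM) nine-group risk classifier and
its treatment-allocation / population-survival model.

Risk tiers per molecular group:

* WNT: low-risk (M0) vs high-risk (M+).  The high-risk definition and
  its HDCSI allocation are modelling assumptions (the source trials
  gave no explicit WNT high-risk rule); assignments carry a note.
* SHH: very-high-risk iff TP53 mutation, GLI2 amplification, or
  metastatic disease; else average-risk iff LC/A histology, MYCN
  amplification, or 17p loss; else low-risk.
* G3/G4: very-high-risk iff subgroup 3, MYC amplification, or
  metastatic subgroup 2; else low-risk iff M0 with subgroup 7 or the
  WCA-FR phenotype; else high-risk iff M+; else average-risk.

Precedence is VHR-first in every scheme (subgroup-3 or MYC-amplified
disease is very-high-risk regardless of otherwise favorable features).
Unknown feature values block classification only when they are
decisive, i.e. when the assigned tier could change under some
resolution of the unknowns; the blocking features are named on the
assignment.  The rules are held in data (`RuleSet`), so comparator
schemes can be plugged in, but only the rCM rules ship.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable

from .cohort import (
    CohortTable,
    Group,
    Histology,
    MolecularProfile,
    MStage,
    PatientRecord,
    Subgroup,
)


class RiskGroup(enum.StrEnum):
    WNT_LR = "WNT_LR"
    WNT_HR = "WNT_HR"
    SHH_LR = "SHH_LR"
    SHH_AR = "SHH_AR"
    SHH_VHR = "SHH_VHR"
    G34_LR = "G34_LR"
    G34_AR = "G34_AR"
    G34_HR = "G34_HR"
    G34_VHR = "G34_VHR"
    UNCLASSIFIABLE = "unclassifiable"


class Allocation(enum.StrEnum):
    LDCSI_REGIMEN = "LDCSI_regimen"
    SDCSI_REGIMEN = "SDCSI_regimen"
    HDCSI_REGIMEN = "HDCSI_regimen"
    HDCSI_CARBO_REGIMEN = "HDCSI_Carbo_regimen"
    NOVEL_THERAPY = "novel_therapy"
    NONE = "none"


_TIER_RANK = {"LR": 0, "AR": 1, "HR": 2, "VHR": 3}


def tier_rank(risk_group: RiskGroup) -> int:
    """Severity order LR < AR < HR < VHR < unclassifiable (used for
    oncoprint column sorting and monotonicity checks)."""
    if risk_group == RiskGroup.UNCLASSIFIABLE:
        return 4
    return _TIER_RANK[str(risk_group).split("_")[-1]]


@dataclass
class RiskAssignment:
    patient_id: str
    risk_group: RiskGroup
    triggering_features: list[str] = field(default_factory=list)
    allocation: Allocation = Allocation.NONE
    blocking_features: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Rule:
    tier: str
    label: str
    predicate: Callable[[dict], bool]


@dataclass(frozen=True)
class RuleSet:
    """Ordered risk rules over fully observed feature dicts.

    ``feature_domains`` maps feature name -> tuple of possible values,
    used to resolve unknowns by enumeration.  ``default_tier`` applies
    when no rule fires.
    """

    name: str
    rules: tuple[Rule, ...]
    feature_domains: dict[str, tuple]
    default_tier: str

    def tier_of(self, values: dict) -> tuple[str, list[str]]:
        for rule in self.rules:
            if rule.predicate(values):
                matched = [
                    r.label
                    for r in self.rules
                    if r.tier == rule.tier and r.predicate(values)
                ]
                return rule.tier, matched
        return self.default_tier, []

    def resolve(self, values: dict) -> tuple[str | None, list[str], list[str]]:
        """Tier under unknown-aware evaluation.

        Returns (tier, triggering labels, blocking features); tier is
        None when unknowns are decisive.
        """
        unknown = [f for f, v in values.items() if v is None]
        if not unknown:
            tier, labels = self.tier_of(values)
            return tier, labels, []
        domains = [self.feature_domains[f] for f in unknown]
        outcomes: dict[tuple, str] = {}
        for combo in itertools.product(*domains):
            full = dict(values)
            full.update(zip(unknown, combo))
            outcomes[combo] = self.tier_of(full)[0]
        tiers = set(outcomes.values())
        if len(tiers) == 1:
            tier = tiers.pop()
            # report only the rule labels certain to hold under every resolution
            certain = [
                r.label
                for r in self.rules
                if r.tier == tier
                and all(
                    r.predicate({**values, **dict(zip(unknown, combo))})
                    for combo in itertools.product(*domains)
                )
            ]
            return tier, certain, []
        blocking = []
        for f, dom in zip(unknown, domains):
            others = [u for u in unknown if u != f]
            other_domains = [self.feature_domains[u] for u in others]
            for combo in itertools.product(*other_domains):
                base = dict(values)
                base.update(zip(others, combo))
                seen = set()
                for v in dom:
                    base[f] = v
                    seen.add(self.tier_of(base)[0])
                if len(seen) > 1:
                    blocking.append(f)
                    break
        return None, [], blocking


_BOOL = (False, True)

SHH_RULES = RuleSet(
    name="rCM-SHH",
    rules=(
        Rule("VHR", "TP53 mutation", lambda v: v["tp53_mut"]),
        Rule("VHR", "GLI2 amplification", lambda v: v["gli2_amp"]),
        Rule("VHR", "metastatic disease", lambda v: v["m_plus"]),
        Rule("AR", "LC/A histology", lambda v: v["lca"]),
        Rule("AR", "MYCN amplification", lambda v: v["mycn_amp"]),
        Rule("AR", "17p loss", lambda v: v["arm_17p_loss"]),
    ),
    feature_domains={
        "tp53_mut": _BOOL,
        "gli2_amp": _BOOL,
        "m_plus": _BOOL,
        "lca": _BOOL,
        "mycn_amp": _BOOL,
        "arm_17p_loss": _BOOL,
    },
    default_tier="LR",
)

G34_RULES = RuleSet(
    name="rCM-G3/G4",
    rules=(
        Rule("VHR", "subgroup G3/G4-3", lambda v: v["subgroup"] == 3),
        Rule("VHR", "MYC amplification", lambda v: v["myc_amp"]),
        Rule("VHR", "M+ with subgroup G3/G4-2", lambda v: v["m_plus"] and v["subgroup"] == 2),
        Rule("LR", "M0 with subgroup G3/G4-7", lambda v: not v["m_plus"] and v["subgroup"] == 7),
        Rule("LR", "M0 with WCA-FR phenotype", lambda v: not v["m_plus"] and v["wca_fr"]),
        Rule("HR", "M+ without very-high-risk features", lambda v: v["m_plus"]),
    ),
    feature_domains={
        "subgroup": tuple(range(1, 9)),
        "myc_amp": _BOOL,
        "m_plus": _BOOL,
        "wca_fr": _BOOL,
    },
    default_tier="AR",
)

WNT_RULES = RuleSet(
    name="rCM-WNT",
    rules=(
        Rule("HR", "metastatic disease", lambda v: v["m_plus"]),
        Rule("LR", "non-metastatic disease", lambda v: not v["m_plus"]),
    ),
    feature_domains={"m_plus": _BOOL},
    default_tier="LR",
)

_ALLOCATION_MAP: dict[RiskGroup, Allocation] = {
    RiskGroup.WNT_LR: Allocation.LDCSI_REGIMEN,
    RiskGroup.WNT_HR: Allocation.HDCSI_REGIMEN,
    RiskGroup.SHH_LR: Allocation.LDCSI_REGIMEN,
    RiskGroup.SHH_AR: Allocation.SDCSI_REGIMEN,
    RiskGroup.SHH_VHR: Allocation.NOVEL_THERAPY,
    RiskGroup.G34_LR: Allocation.LDCSI_REGIMEN,
    RiskGroup.G34_AR: Allocation.SDCSI_REGIMEN,
    RiskGroup.G34_HR: Allocation.HDCSI_REGIMEN,
    RiskGroup.G34_VHR: Allocation.HDCSI_CARBO_REGIMEN,
}

_WNT_NOTE = (
    "WNT high-risk definition (M+) and its HDCSI allocation are modelling assumptions"
)


def _tri(v):
    return None if v is None else bool(v)


def _m_plus(m_stage: MStage):
    if m_stage == MStage.UNKNOWN:
        return None
    return m_stage == MStage.M_PLUS


def _lca(histology: Histology):
    if histology == Histology.UNKNOWN:
        return None
    return histology == Histology.LCA


def _subgroup_number(subgroup: Subgroup):
    if subgroup == Subgroup.NONE:
        return None
    label = str(subgroup)
    if not label.startswith("G34_"):
        return None
    return int(label.split("_")[1])


def _finish(pid: str, prefix: str, tier, labels, blocking, notes=()) -> RiskAssignment:
    if tier is None:
        a = RiskAssignment(
            patient_id=pid,
            risk_group=RiskGroup.UNCLASSIFIABLE,
            blocking_features=blocking,
            notes=list(notes),
        )
    else:
        a = RiskAssignment(
            patient_id=pid,
            risk_group=RiskGroup(f"{prefix}_{tier}"),
            triggering_features=labels,
            notes=list(notes),
        )
    a.allocation = allocate_treatment(a)
    return a


def classify_shh(
    profile: MolecularProfile, m_stage: MStage, histology: Histology
) -> RiskAssignment:
    if profile.group != Group.SHH:
        raise ValueError(f"classify_shh requires group SHH, got {profile.group}")
    values = {
        "tp53_mut": _tri(profile.tp53_mut),
        "gli2_amp": _tri(profile.gli2_amp),
        "m_plus": _m_plus(m_stage),
        "lca": _lca(histology),
        "mycn_amp": _tri(profile.mycn_amp),
        "arm_17p_loss": _tri(profile.arm_17p_loss),
    }
    tier, labels, blocking = SHH_RULES.resolve(values)
    return _finish(profile.patient_id, "SHH", tier, labels, blocking)


def classify_g3g4(profile: MolecularProfile, m_stage: MStage) -> RiskAssignment:
    if profile.group not in (Group.G3, Group.G4):
        raise ValueError(f"classify_g3g4 requires group G3 or G4, got {profile.group}")
    values = {
        "subgroup": _subgroup_number(profile.subgroup),
        "myc_amp": _tri(profile.myc_amp),
        "m_plus": _m_plus(m_stage),
        "wca_fr": _tri(profile.wca_fr),
    }
    tier, labels, blocking = G34_RULES.resolve(values)
    return _finish(profile.patient_id, "G34", tier, labels, blocking)


def classify_wnt(profile: MolecularProfile, m_stage: MStage) -> RiskAssignment:
    if profile.group != Group.WNT:
        raise ValueError(f"classify_wnt requires group WNT, got {profile.group}")
    values = {"m_plus": _m_plus(m_stage)}
    tier, labels, blocking = WNT_RULES.resolve(values)
    return _finish(profile.patient_id, "WNT", tier, labels, blocking, notes=(_WNT_NOTE,))


def classify_patient(record: PatientRecord, profile: MolecularProfile) -> RiskAssignment:
    if profile.group == Group.WNT:
        return classify_wnt(profile, record.m_stage)
    if profile.group == Group.SHH:
        return classify_shh(profile, record.m_stage, record.histology)
    if profile.group in (Group.G3, Group.G4):
        return classify_g3g4(profile, record.m_stage)
    return RiskAssignment(
        patient_id=profile.patient_id,
        risk_group=RiskGroup.UNCLASSIFIABLE,
        blocking_features=["group"],
        allocation=Allocation.NONE,
    )


def classify(cohort: CohortTable) -> list[RiskAssignment]:
    """Classify every patient; unknown molecular group yields an
    unclassifiable assignment, deterministically."""
    return [classify_patient(rec, prof) for rec, prof in cohort]


def allocate_treatment(assignment: RiskAssignment) -> Allocation:
    if assignment.risk_group == RiskGroup.UNCLASSIFIABLE:
        warnings.warn(
            f"{assignment.patient_id}: unclassifiable risk; no treatment allocation",
            stacklevel=2,
        )
        return Allocation.NONE
    return _ALLOCATION_MAP[assignment.risk_group]


# ---------------------------------------------------------------------------
# Population-level allocation model

@dataclass(frozen=True)
class Stratum:
    label: str
    fraction: float
    survival: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("stratum fraction must lie in [0, 1]")
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("stratum survival must lie in [0, 1]")


@dataclass(frozen=True)
class AllocationModel:
    strata: tuple[Stratum, ...]


def expected_population_survival(model: AllocationModel) -> float:
    """Population-weighted expected survival: sum of fraction x survival.

    The stratum fractions must partition the population (sum to 1)."""
    total = sum(s.fraction for s in model.strata)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"stratum fractions must sum to 1, got {total}")
    return sum(s.fraction * s.survival for s in model.strata)


def reference_allocation_model() -> AllocationModel:
    """The proposed risk-adapted deployment: per-stratum population
    fractions and expected survival floors for the five treatment
    strata (LDCSI, SDCSI, HDCSI, HDCSI with carboplatin, novel therapy).
    """
    return AllocationModel(
        strata=(
            Stratum("LDCSI_regimen", 0.40, 0.90),
            Stratum("SDCSI_regimen", 0.25, 0.80),
            Stratum("HDCSI_regimen", 0.20, 0.60),
            Stratum("HDCSI_Carbo_regimen", 0.10, 0.60),
            Stratum("novel_therapy", 0.05, 0.40),
        )
    )


def allocation_fractions(assignments: list[RiskAssignment]) -> dict[str, float]:
    """Observed fraction of a cohort per treatment allocation."""
    if not assignments:
        return {}
    counts: dict[str, int] = {}
    for a in assignments:
        counts[str(a.allocation)] = counts.get(str(a.allocation), 0) + 1
    n = len(assignments)
    return {k: v / n for k, v in sorted(counts.items())}
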