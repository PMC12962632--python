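"""Harmonized trial-participant data model and tab-delimited interchange.

One row per patient joins clinical staging/treatment attributes
(`PatientRecord`) with molecular annotations (`MolecularProfile`).
Missing values are the literal string ``NA`` on disk and a distinct
unknown state in memory (`None` for tri-state flags, an ``unknown``/
``none`` enum member otherwise); no operation silently coerces unknown
to a concrete category.  Survival times are stored in months, so the
commonly reported 5-year horizon is t = 60.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .cnv import ChromCall, TriState, wca_fr_from_calls

NA = "NA"


class CohortError(Exception):
    """Base class for cohort-table failures."""


class SchemaError(CohortError):
    pass


class IntegrityError(CohortError):
    pass


class ParseError(CohortError):
    pass


class ValidationError(CohortError):
    pass


class Trial(enum.StrEnum):
    ACNS0331 = "ACNS0331"
    ACNS0332 = "ACNS0332"
    SJMB03 = "SJMB03"


class MStage(enum.StrEnum):
    M0 = "M0"
    M_PLUS = "M_plus"
    UNKNOWN = "unknown"


class RStatus(enum.StrEnum):
    R0 = "R0"
    R_PLUS = "R_plus"
    UNKNOWN = "unknown"


class Histology(enum.StrEnum):
    CLASSIC = "classic"
    DESMOPLASTIC = "desmoplastic"
    LCA = "LCA"
    OTHER = "other"
    UNKNOWN = "unknown"


class CSIArm(enum.StrEnum):
    LDCSI = "LDCSI"
    SDCSI = "SDCSI"
    HDCSI = "HDCSI"
    UNKNOWN = "unknown"


class BoostField(enum.StrEnum):
    IFRT = "IFRT"
    PFRT = "PFRT"
    UNKNOWN = "unknown"


class Group(enum.StrEnum):
    WNT = "WNT"
    SHH = "SHH"
    G3 = "G3"
    G4 = "G4"
    UNKNOWN = "unknown"


class Subgroup(enum.StrEnum):
    SHH_1 = "SHH_1"
    SHH_2 = "SHH_2"
    SHH_3 = "SHH_3"
    SHH_4 = "SHH_4"
    G34_1 = "G34_1"
    G34_2 = "G34_2"
    G34_3 = "G34_3"
    G34_4 = "G34_4"
    G34_5 = "G34_5"
    G34_6 = "G34_6"
    G34_7 = "G34_7"
    G34_8 = "G34_8"
    NONE = "none"


SHH_SUBGROUPS = frozenset({Subgroup.SHH_1, Subgroup.SHH_2, Subgroup.SHH_3, Subgroup.SHH_4})
G34_SUBGROUPS = frozenset(
    {
        Subgroup.G34_1,
        Subgroup.G34_2,
        Subgroup.G34_3,
        Subgroup.G34_4,
        Subgroup.G34_5,
        Subgroup.G34_6,
        Subgroup.G34_7,
        Subgroup.G34_8,
    }
)


@dataclass
class PatientRecord:
    patient_id: str
    trial: Trial
    age_years: float | None = None
    m_stage: MStage = MStage.UNKNOWN
    r_status: RStatus = RStatus.UNKNOWN
    histology: Histology = Histology.UNKNOWN
    csi_arm: CSIArm = CSIArm.UNKNOWN
    carboplatin: TriState = None
    boost_field: BoostField = BoostField.UNKNOWN
    pfs_months: float | None = None
    pfs_event: int | None = None
    os_months: float | None = None
    os_event: int | None = None

    def validate(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        for name in ("age_years", "pfs_months", "os_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.patient_id}: {name} must be non-negative")
        for name in ("pfs_event", "os_event"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValidationError(f"{self.patient_id}: {name} must be 0 or 1")
        if (
            self.pfs_months is not None
            and self.os_months is not None
            and self.pfs_months > self.os_months + 1e-9
        ):
            raise ValidationError(
                f"{self.patient_id}: pfs_months exceeds os_months"
            )
        if self.carboplatin is True and self.trial != Trial.ACNS0332:
            raise ValidationError(
                f"{self.patient_id}: carboplatin was only given on ACNS0332"
            )
        if self.csi_arm == CSIArm.LDCSI and self.trial != Trial.ACNS0331:
            raise ValidationError(
                f"{self.patient_id}: LDCSI was only given on ACNS0331"
            )

    @property
    def has_pfs(self) -> bool:
        """Usable for progression-free-survival analyses."""
        return self.pfs_months is not None and self.pfs_event is not None

    @property
    def has_os(self) -> bool:
        return self.os_months is not None and self.os_event is not None


@dataclass
class MolecularProfile:
    patient_id: str
    group: Group = Group.UNKNOWN
    subgroup: Subgroup = Subgroup.NONE
    tp53_mut: TriState = None
    gli2_amp: TriState = None
    mycn_amp: TriState = None
    myc_amp: TriState = None
    chrom_calls: dict[str, ChromCall] = field(default_factory=dict)
    arm_17p_loss: TriState = None
    wca_fr: TriState = None

    def __post_init__(self) -> None:
        if self.wca_fr is None:
            self.wca_fr = self._derived_wca_fr()

    def _derived_wca_fr(self) -> TriState:
        return wca_fr_from_calls(
            self.chrom_calls.get("7", ChromCall.UNKNOWN),
            self.chrom_calls.get("8", ChromCall.UNKNOWN),
            self.chrom_calls.get("11", ChromCall.UNKNOWN),
        )

    def validate(self) -> None:
        if self.subgroup in SHH_SUBGROUPS and self.group != Group.SHH:
            raise ValidationError(
                f"{self.patient_id}: SHH subgroup with group {self.group}"
            )
        if self.subgroup in G34_SUBGROUPS and self.group not in (Group.G3, Group.G4):
            raise ValidationError(
                f"{self.patient_id}: G3/G4 subgroup with group {self.group}"
            )
        derived = self._derived_wca_fr()
        if self.wca_fr is None:
            self.wca_fr = derived
        elif derived is not None and self.wca_fr != derived:
            raise ValidationError(
                f"{self.patient_id}: wca_fr inconsistent with chromosome calls"
            )


@dataclass
class CohortTable:
    records: list[tuple[PatientRecord, MolecularProfile]] = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> None:
        seen: set[str] = set()
        for rec, prof in self.records:
            if rec.patient_id in seen:
                raise IntegrityError(f"duplicated patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            if prof.patient_id != rec.patient_id:
                raise IntegrityError(
                    f"molecular profile {prof.patient_id!r} does not match "
                    f"patient {rec.patient_id!r}"
                )
            rec.validate()
            prof.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [rec.patient_id for rec, _ in self.records]


# ---------------------------------------------------------------------------
# Tab-delimited interchange

MANDATORY_COLUMNS = [
    "patient_id",
    "trial",
    "age_years",
    "m_stage",
    "r_status",
    "histology",
    "csi_arm",
    "carboplatin",
    "boost_field",
    "group",
    "subgroup",
    "tp53_mut",
    "gli2_amp",
    "mycn_amp",
    "myc_amp",
    "chr7_call",
    "chr8_call",
    "chr11_call",
    "arm_17p_loss",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
]

_FLAG_COLUMNS = ("carboplatin", "tp53_mut", "gli2_amp", "mycn_amp", "myc_amp", "arm_17p_loss")


def _parse_enum(cls, cell: str, row: int, col: str, unknown):
    if cell == NA:
        return unknown
    try:
        return cls(cell)
    except ValueError:
        raise ParseError(
            f"row {row}: unrecognized value {cell!r} in column {col!r}"
        ) from None


def _parse_flag(cell: str, row: int, col: str) -> TriState:
    if cell == NA:
        return None
    if cell == "1":
        return True
    if cell == "0":
        return False
    raise ParseError(f"row {row}: flag column {col!r} must be 1/0/NA, got {cell!r}")


def _parse_float(cell: str, row: int, col: str) -> float | None:
    if cell == NA:
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"row {row}: non-numeric value {cell!r} in column {col!r}") from None


def _parse_event(cell: str, row: int, col: str) -> int | None:
    if cell == NA:
        return None
    if cell in ("0", "1"):
        return int(cell)
    raise ParseError(f"row {row}: event column {col!r} must be 0/1/NA, got {cell!r}")


def read_cohort_tsv(path, provenance: str | None = None) -> CohortTable:
    """Read a patient table.  ``NA`` cells map to the unknown state;
    row order is preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[tuple[PatientRecord, MolecularProfile]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        pid = row["patient_id"]
        trial = _parse_enum(Trial, row["trial"], i, "trial", None)
        if trial is None:
            raise ParseError(f"row {i}: trial may not be NA")
        rec = PatientRecord(
            patient_id=pid,
            trial=trial,
            age_years=_parse_float(row["age_years"], i, "age_years"),
            m_stage=_parse_enum(MStage, row["m_stage"], i, "m_stage", MStage.UNKNOWN),
            r_status=_parse_enum(RStatus, row["r_status"], i, "r_status", RStatus.UNKNOWN),
            histology=_parse_enum(
                Histology, row["histology"], i, "histology", Histology.UNKNOWN
            ),
            csi_arm=_parse_enum(CSIArm, row["csi_arm"], i, "csi_arm", CSIArm.UNKNOWN),
            carboplatin=_parse_flag(row["carboplatin"], i, "carboplatin"),
            boost_field=_parse_enum(
                BoostField, row["boost_field"], i, "boost_field", BoostField.UNKNOWN
            ),
            pfs_months=_parse_float(row["pfs_months"], i, "pfs_months"),
            pfs_event=_parse_event(row["pfs_event"], i, "pfs_event"),
            os_months=_parse_float(row["os_months"], i, "os_months"),
            os_event=_parse_event(row["os_event"], i, "os_event"),
        )
        prof = MolecularProfile(
            patient_id=pid,
            group=_parse_enum(Group, row["group"], i, "group", Group.UNKNOWN),
            subgroup=_parse_enum(
                Subgroup, row["subgroup"], i, "subgroup", Subgroup.NONE
            ),
            tp53_mut=_parse_flag(row["tp53_mut"], i, "tp53_mut"),
            gli2_amp=_parse_flag(row["gli2_amp"], i, "gli2_amp"),
            mycn_amp=_parse_flag(row["mycn_amp"], i, "mycn_amp"),
            myc_amp=_parse_flag(row["myc_amp"], i, "myc_amp"),
            chrom_calls={
                "7": _parse_enum(ChromCall, row["chr7_call"], i, "chr7_call", ChromCall.UNKNOWN),
                "8": _parse_enum(ChromCall, row["chr8_call"], i, "chr8_call", ChromCall.UNKNOWN),
                "11": _parse_enum(ChromCall, row["chr11_call"], i, "chr11_call", ChromCall.UNKNOWN),
            },
            arm_17p_loss=_parse_flag(row["arm_17p_loss"], i, "arm_17p_loss"),
        )
        records.append((rec, prof))
    table = CohortTable(
        records=records, provenance=provenance if provenance is not None else str(path)
    )
    table.validate()
    return table


def _fmt_flag(v: TriState) -> str:
    if v is None:
        return NA
    return "1" if v else "0"


def _fmt_enum(v, unknown) -> str:
    return NA if v == unknown else str(v)


def _fmt_num(v) -> str:
    if v is None:
        return NA
    return repr(float(v)) if not float(v).is_integer() else str(int(v))


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """String-valued frame in the interchange vocabulary (NA literal)."""
    rows = []
    for rec, prof in cohort:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "trial": str(rec.trial),
                "age_years": _fmt_num(rec.age_years),
                "m_stage": _fmt_enum(rec.m_stage, MStage.UNKNOWN),
                "r_status": _fmt_enum(rec.r_status, RStatus.UNKNOWN),
                "histology": _fmt_enum(rec.histology, Histology.UNKNOWN),
                "csi_arm": _fmt_enum(rec.csi_arm, CSIArm.UNKNOWN),
                "carboplatin": _fmt_flag(rec.carboplatin),
                "boost_field": _fmt_enum(rec.boost_field, BoostField.UNKNOWN),
                "group": _fmt_enum(prof.group, Group.UNKNOWN),
                "subgroup": str(prof.subgroup),
                "tp53_mut": _fmt_flag(prof.tp53_mut),
                "gli2_amp": _fmt_flag(prof.gli2_amp),
                "mycn_amp": _fmt_flag(prof.mycn_amp),
                "myc_amp": _fmt_flag(prof.myc_amp),
                "chr7_call": _fmt_enum(prof.chrom_calls.get("7", ChromCall.UNKNOWN), ChromCall.UNKNOWN),
                "chr8_call": _fmt_enum(prof.chrom_calls.get("8", ChromCall.UNKNOWN), ChromCall.UNKNOWN),
                "chr11_call": _fmt_enum(prof.chrom_calls.get("11", ChromCall.UNKNOWN), ChromCall.UNKNOWN),
                "arm_17p_loss": _fmt_flag(prof.arm_17p_loss),
                "pfs_months": _fmt_num(rec.pfs_months),
                "pfs_event": _fmt_num(rec.pfs_event),
                "os_months": _fmt_num(rec.os_months),
                "os_event": _fmt_num(rec.os_event),
            }
        )
    return pd.DataFrame(rows, columns=MANDATORY_COLUMNS)


def write_cohort_tsv(cohort: CohortTable, path) -> None:
    cohort.validate()
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Oncoprint export

ONCOPRINT_FEATURES = frozenset(MANDATORY_COLUMNS) - {"patient_id"}

_GROUP_ORDER = {Group.WNT: 0, Group.SHH: 1, Group.G3: 2, Group.G4: 3, Group.UNKNOWN: 4}


def oncoprint_matrix(cohort: CohortTable, feature_order: list[str]) -> pd.DataFrame:
    """Feature-by-patient categorical matrix for oncoprint-style display.

    Columns are sorted by rCM risk tier (LR < AR < HR < VHR <
    unclassifiable), then molecular group (WNT < SHH < G3 < G4 <
    unknown), then patient_id; rows follow ``feature_order``.
    """
    unknown_features = [f for f in feature_order if f not in ONCOPRINT_FEATURES]
    if unknown_features:
        raise SchemaError(f"unknown feature name(s): {', '.join(unknown_features)}")
    from .riskmodel import tier_rank, classify  # deferred: avoids import cycle

    frame = cohort_to_frame(cohort)
    if len(frame) == 0:
        return pd.DataFrame(index=feature_order)
    assignments = {a.patient_id: a for a in classify(cohort)}

    def sort_key(item):
        rec, prof = item
        a = assignments[rec.patient_id]
        return (tier_rank(a.risk_group), _GROUP_ORDER[prof.group], rec.patient_id)

    ordered = sorted(cohort.records, key=sort_key)
    frame = frame.set_index("patient_id")
    cols = [rec.patient_id for rec, _ in ordered]
    return frame.loc[cols, feature_order].T
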