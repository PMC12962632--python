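"""Synthetic cohorts and copy-number profiles.

Three generators make every analysis module testable without any
external download:

* :func:`generate_cohort` draws patients with the published molecular
  group mix (WNT 131/898, SHH 151/898, G3 220/898, G4 396/898),
  configurable subgroup and feature prevalences, rCM risk assigned by
  the packaged classifier, exponential (optionally Weibull)
  progression-free-survival times parameterized by per-risk-group
  target 5-year PFS, and independent uniform administrative censoring.
* :func:`generate_reference_roster` deterministically reproduces the
  six cross-trial category compositions at their published sizes
  (86/276/177/97/80/87) plus the 95 excluded records; only the totals
  are asserted against published counts — the four-way split of the
  excluded records is arbitrary.
* :func:`generate_segment_profile` builds SEG-style profiles with
  large (~25 Mb) noisy background segments and planted events carrying
  their exact log2 shift, so focal-event recovery is deterministic.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .cnv import ChromCall, Segment, SegmentProfile
from .cohort import (
    BoostField,
    CohortTable,
    CSIArm,
    Group,
    Histology,
    MolecularProfile,
    MStage,
    PatientRecord,
    RStatus,
    Subgroup,
    Trial,
)
from .genome import AUTOSOMES, CHROM_SIZES
from .riskmodel import RiskGroup, classify_patient

_MONTHS_5YR = 60.0


def _default_group_probs() -> dict[str, float]:
    return {"WNT": 131 / 898, "SHH": 151 / 898, "G3": 220 / 898, "G4": 396 / 898}


def _default_subgroup_probs() -> dict[str, dict[int, float]]:
    # Round values consistent with the published oncoprints; config, not claims.
    return {
        "SHH": {1: 0.25, 2: 0.30, 3: 0.25, 4: 0.20},
        "G3": {1: 0.15, 2: 0.20, 3: 0.20, 4: 0.20, 5: 0.10, 6: 0.05, 7: 0.05, 8: 0.05},
        "G4": {1: 0.05, 2: 0.05, 3: 0.05, 4: 0.10, 5: 0.15, 6: 0.20, 7: 0.20, 8: 0.20},
    }


def _default_prevalence() -> dict[str, dict[str, float]]:
    return {
        "WNT": {"m_plus": 0.10, "lca": 0.05, "r_plus": 0.05},
        "SHH": {
            "tp53_mut": 0.15,
            "gli2_amp": 0.08,
            "mycn_amp": 0.10,
            "arm_17p_loss": 0.20,
            "lca": 0.15,
            "m_plus": 0.15,
            "r_plus": 0.08,
        },
        "G3": {
            "myc_amp": 0.17,
            "m_plus": 0.45,
            "lca": 0.15,
            "wca_fr": 0.10,
            "arm_17p_loss": 0.20,
            "r_plus": 0.10,
        },
        "G4": {
            "myc_amp": 0.05,
            "m_plus": 0.35,
            "lca": 0.05,
            "wca_fr": 0.25,
            "arm_17p_loss": 0.40,
            "r_plus": 0.10,
        },
    }


def _default_risk_pfs5() -> dict[str, float]:
    # Target 5-year PFS per rCM risk group; the G34_VHR level is
    # carboplatin-dependent (~0.65 with vs ~0.35 without) and SHH_VHR
    # sits near 0.25.
    return {
        "WNT_LR": 0.95,
        "WNT_HR": 0.85,
        "SHH_LR": 0.90,
        "SHH_AR": 0.80,
        "SHH_VHR": 0.25,
        "G34_LR": 0.90,
        "G34_AR": 0.80,
        "G34_HR": 0.60,
        "G34_VHR_carbo": 0.65,
        "G34_VHR_nocarbo": 0.35,
        "unclassifiable": 0.75,
    }


@dataclass
class CohortConfig:
    n: int = 898
    seed: int = 0
    group_probs: dict[str, float] = field(default_factory=_default_group_probs)
    subgroup_probs: dict[str, dict[int, float]] = field(
        default_factory=_default_subgroup_probs
    )
    prevalence: dict[str, dict[str, float]] = field(default_factory=_default_prevalence)
    risk_pfs5: dict[str, float] = field(default_factory=_default_risk_pfs5)
    # Optional per-subgroup carboplatin overrides for G3/G4:
    # subgroup number -> (pfs5 with carbo, pfs5 without carbo)
    subgroup_carbo_pfs5: dict[int, tuple[float, float]] = field(default_factory=dict)
    censor_window: tuple[float, float] = (36.0, 120.0)
    weibull_shape: float = 1.0  # 1.0 = exponential
    post_progression_mean_months: float = 18.0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name, probs in [("group_probs", self.group_probs)] + [
            (f"subgroup_probs[{g}]", p) for g, p in self.subgroup_probs.items()
        ]:
            vals = list(probs.values())
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for g, feats in self.prevalence.items():
            for f, v in feats.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"prevalence[{g}][{f}] must lie in [0, 1]")
        for k, v in self.risk_pfs5.items():
            if not 0 < v < 1:
                raise ValueError(f"risk_pfs5[{k}] must lie in (0, 1)")
        if self.censor_window[0] <= 0 or self.censor_window[0] > self.censor_window[1]:
            raise ValueError("censor_window must be 0 < lo <= hi")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GeneratorReport:
    n: int
    seed: int
    config_hash: str
    group_counts: dict[str, int]
    subgroup_counts: dict[str, int]
    risk_counts: dict[str, int]
    feature_counts: dict[str, int]


def _pfs_scale(pfs5: float, shape: float) -> float:
    # S(t) = exp(-(t/lam)^k)  =>  lam = 60 / (-ln S5)^(1/k)
    return _MONTHS_5YR / (-np.log(pfs5)) ** (1.0 / shape)


def _target_pfs5(cfg: CohortConfig, risk: RiskGroup, subgroup_num: int | None, carbo: bool) -> float:
    if subgroup_num is not None and subgroup_num in cfg.subgroup_carbo_pfs5:
        with_c, without_c = cfg.subgroup_carbo_pfs5[subgroup_num]
        return with_c if carbo else without_c
    if risk == RiskGroup.G34_VHR:
        key = "G34_VHR_carbo" if carbo else "G34_VHR_nocarbo"
        return cfg.risk_pfs5[key]
    return cfg.risk_pfs5[str(risk)]


def generate_cohort(cfg: CohortConfig) -> tuple[CohortTable, GeneratorReport]:
    """Draw a synthetic cohort; identical config and seed reproduce the
    cohort byte-for-byte."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records = []
    group_counts: dict[str, int] = {}
    subgroup_counts: dict[str, int] = {}
    risk_counts: dict[str, int] = {}
    feature_counts: dict[str, int] = {}

    group_names = list(cfg.group_probs)
    group_p = np.array([cfg.group_probs[g] for g in group_names])

    for i in range(cfg.n):
        pid = f"SYN-{i:04d}"
        group = Group(group_names[int(rng.choice(len(group_names), p=group_p))])
        prev = cfg.prevalence.get(str(group), {})

        def draw(feature: str) -> bool:
            hit = bool(rng.random() < prev.get(feature, 0.0))
            if hit:
                feature_counts[feature] = feature_counts.get(feature, 0) + 1
            return hit

        subgroup = Subgroup.NONE
        sub_num: int | None = None
        if str(group) in cfg.subgroup_probs:
            sp = cfg.subgroup_probs[str(group)]
            nums = list(sp)
            sub_num = int(nums[int(rng.choice(len(nums), p=np.array([sp[k] for k in nums])))])
            prefix = "SHH" if group == Group.SHH else "G34"
            subgroup = Subgroup(f"{prefix}_{sub_num}")
            subgroup_counts[str(subgroup)] = subgroup_counts.get(str(subgroup), 0) + 1
        if group == Group.SHH:
            sub_num = None  # subgroup number only steers G3/G4 hazards

        m_plus = draw("m_plus")
        lca = draw("lca")
        r_plus = draw("r_plus")
        tp53 = draw("tp53_mut")
        gli2 = draw("gli2_amp")
        mycn = draw("mycn_amp")
        myc = draw("myc_amp")
        wca = draw("wca_fr")
        p17 = draw("arm_17p_loss")

        # chromosome-level calls consistent with the WCA-FR phenotype
        triad = {"7": ChromCall.NEUTRAL, "8": ChromCall.NEUTRAL, "11": ChromCall.NEUTRAL}
        wanted = [("7", ChromCall.GAIN), ("8", ChromCall.LOSS), ("11", ChromCall.LOSS)]
        if wca:
            k = 2 + int(rng.random() < 0.5)
            for j in sorted(rng.choice(3, size=k, replace=False)):
                chrom, call = wanted[j]
                triad[chrom] = call
        elif rng.random() < 0.2:
            chrom, call = wanted[int(rng.choice(3))]
            triad[chrom] = call

        if lca:
            histology = Histology.LCA
        elif group == Group.SHH:
            histology = (
                Histology.DESMOPLASTIC if rng.random() < 0.3 else Histology.CLASSIC
            )
        else:
            histology = Histology.CLASSIC

        high_risk = m_plus or r_plus or lca
        if high_risk:
            trial = Trial.SJMB03 if rng.random() < 0.5 else Trial.ACNS0332
        else:
            trial = Trial(["ACNS0331", "SJMB03", "ACNS0332"][int(rng.choice(3, p=[0.45, 0.45, 0.10]))])
            if trial == Trial.ACNS0332:
                # ACNS0332 required a high-risk feature; make it LC/A
                lca = True
                histology = Histology.LCA
                high_risk = True

        carbo: bool | None = False
        if trial == Trial.ACNS0331:
            csi = CSIArm.LDCSI if rng.random() < 0.25 else CSIArm.SDCSI
            boost = BoostField.IFRT if rng.random() < 0.5 else BoostField.PFRT
        elif trial == Trial.SJMB03:
            csi = CSIArm.HDCSI if (m_plus or r_plus) else CSIArm.SDCSI
            boost = BoostField.IFRT
        else:
            csi = CSIArm.HDCSI
            boost = BoostField.PFRT
            carbo = bool(rng.random() < 0.5)

        record = PatientRecord(
            patient_id=pid,
            trial=trial,
            age_years=round(float(rng.uniform(3.0, 21.0)), 1),
            m_stage=MStage.M_PLUS if m_plus else MStage.M0,
            r_status=RStatus.R_PLUS if r_plus else RStatus.R0,
            histology=histology,
            csi_arm=csi,
            carboplatin=carbo,
            boost_field=boost,
        )
        profile = MolecularProfile(
            patient_id=pid,
            group=group,
            subgroup=subgroup,
            tp53_mut=tp53,
            gli2_amp=gli2,
            mycn_amp=mycn,
            myc_amp=myc,
            chrom_calls=dict(triad),
            arm_17p_loss=p17,
        )
        profile.validate()

        assignment = classify_patient(record, profile)
        g34_sub = sub_num if group in (Group.G3, Group.G4) else None
        pfs5 = _target_pfs5(cfg, assignment.risk_group, g34_sub, bool(carbo))
        scale = _pfs_scale(pfs5, cfg.weibull_shape)
        t_prog = float(scale * rng.weibull(cfg.weibull_shape))
        t_prog = max(t_prog, 0.1)
        censor = float(rng.uniform(*cfg.censor_window))
        post = float(rng.exponential(cfg.post_progression_mean_months))
        t_death = t_prog + post
        record.pfs_months = round(min(t_prog, censor), 1)
        record.pfs_event = int(t_prog <= censor)
        record.os_months = round(min(t_death, censor), 1)
        record.os_event = int(t_death <= censor)
        if record.os_months < record.pfs_months:  # rounding guard
            record.os_months = record.pfs_months

        group_counts[str(group)] = group_counts.get(str(group), 0) + 1
        risk_counts[str(assignment.risk_group)] = (
            risk_counts.get(str(assignment.risk_group), 0) + 1
        )
        records.append((record, profile))

    table = CohortTable(records=records, provenance=f"synthetic(seed={cfg.seed})")
    table.validate()
    report = GeneratorReport(
        n=cfg.n,
        seed=cfg.seed,
        config_hash=cfg.hash(),
        group_counts=group_counts,
        subgroup_counts=subgroup_counts,
        risk_counts=risk_counts,
        feature_counts=feature_counts,
    )
    return table, report


# ---------------------------------------------------------------------------
# Deterministic reference roster

_CATEGORY_BLOCKS: list[tuple[int, dict]] = [
    (86, dict(trial=Trial.ACNS0331, csi=CSIArm.LDCSI, m=MStage.M0, r=RStatus.R0, hist=Histology.CLASSIC, carbo=False)),
    (276, dict(trial=Trial.ACNS0331, csi=CSIArm.SDCSI, m=MStage.M0, r=RStatus.R0, hist=Histology.CLASSIC, carbo=False)),
    (177, dict(trial=Trial.SJMB03, csi=CSIArm.SDCSI, m=MStage.M0, r=RStatus.R0, hist=Histology.CLASSIC, carbo=False)),
    (97, dict(trial=Trial.SJMB03, csi=CSIArm.HDCSI, m=MStage.M_PLUS, r=RStatus.R0, hist=Histology.CLASSIC, carbo=False)),
    (80, dict(trial=Trial.ACNS0332, csi=CSIArm.HDCSI, m=MStage.M_PLUS, r=RStatus.R0, hist=Histology.CLASSIC, carbo=False)),
    (87, dict(trial=Trial.ACNS0332, csi=CSIArm.HDCSI, m=MStage.M_PLUS, r=RStatus.R0, hist=Histology.CLASSIC, carbo=True)),
    # 95 excluded; the published total is 95 — the four-way split is arbitrary
    (24, dict(trial=Trial.SJMB03, csi=CSIArm.SDCSI, m=MStage.M0, r=RStatus.R0, hist=Histology.LCA, carbo=False)),
    (24, dict(trial=Trial.ACNS0332, csi=CSIArm.HDCSI, m=MStage.M0, r=RStatus.R0, hist=Histology.LCA, carbo=False)),
    (24, dict(trial=Trial.SJMB03, csi=CSIArm.HDCSI, m=MStage.M0, r=RStatus.R_PLUS, hist=Histology.CLASSIC, carbo=False)),
    (23, dict(trial=Trial.ACNS0332, csi=CSIArm.HDCSI, m=MStage.M0, r=RStatus.R_PLUS, hist=Histology.CLASSIC, carbo=False)),
]

_ROSTER_GROUP_COUNTS = {Group.WNT: 131, Group.SHH: 151, Group.G3: 220, Group.G4: 396}


def generate_reference_roster() -> CohortTable:
    """Deterministic 898-patient roster reproducing the six cross-trial
    category compositions and the published group totals; no randomness."""
    groups: list[Group] = []
    for g, count in _ROSTER_GROUP_COUNTS.items():
        groups.extend([g] * count)
    records = []
    i = 0
    for size, attrs in _CATEGORY_BLOCKS:
        for _ in range(size):
            pid = f"REF-{i:04d}"
            rec = PatientRecord(
                patient_id=pid,
                trial=attrs["trial"],
                age_years=7.0,
                m_stage=attrs["m"],
                r_status=attrs["r"],
                histology=attrs["hist"],
                csi_arm=attrs["csi"],
                carboplatin=attrs["carbo"],
                boost_field=BoostField.UNKNOWN,
                pfs_months=60.0,
                pfs_event=0,
                os_months=72.0,
                os_event=0,
            )
            prof = MolecularProfile(patient_id=pid, group=groups[i])
            records.append((rec, prof))
            i += 1
    table = CohortTable(records=records, provenance="reference-roster")
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Synthetic segment profiles

@dataclass(frozen=True)
class PlantedEvent:
    chrom: str
    start: int
    end: int
    log2_shift: float


def generate_segment_profile(
    sample_id: str,
    planted_events: list[tuple[str, int, int, float]] | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    target_segment_bp: int = 25_000_000,
) -> SegmentProfile:
    """Background segments at log2 0 + Gaussian noise, split into
    roughly ``target_segment_bp`` chunks (all well above the 10 Mb
    focal cap, so background noise cannot masquerade as a focal event);
    planted events become their own segments carrying the exact shift.
    """
    rng = np.random.default_rng(seed)
    planted: dict[str, list[PlantedEvent]] = {}
    for chrom, start, end, shift in planted_events or []:
        ev = PlantedEvent(chrom=str(chrom), start=int(start), end=int(end), log2_shift=float(shift))
        if ev.chrom not in CHROM_SIZES:
            raise ValueError(f"unknown chromosome {ev.chrom!r}")
        if not 0 <= ev.start < ev.end <= CHROM_SIZES[ev.chrom]:
            raise ValueError(f"planted event outside chr{ev.chrom} bounds")
        planted.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in planted.items():
        evs.sort(key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping planted events on chr{chrom}")

    segments: list[Segment] = []

    def add_background(chrom: str, start: int, end: int) -> None:
        length = end - start
        if length <= 0:
            return
        n_chunks = max(1, round(length / target_segment_bp))
        edges = np.linspace(start, end, n_chunks + 1).astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                segments.append(
                    Segment(
                        chrom=chrom,
                        start=int(a),
                        end=int(b),
                        n_probes=max(1, (b - a) // 50_000),
                        log2_ratio=float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0,
                    )
                )

    for chrom in AUTOSOMES:
        pos = 0
        for ev in planted.get(chrom, []):
            add_background(chrom, pos, ev.start)
            segments.append(
                Segment(
                    chrom=chrom,
                    start=ev.start,
                    end=ev.end,
                    n_probes=max(1, (ev.end - ev.start) // 50_000),
                    log2_ratio=ev.log2_shift,
                )
            )
            pos = ev.end
        add_background(chrom, pos, CHROM_SIZES[chrom])
    return SegmentProfile(sample_id=sample_id, segments=segments)
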