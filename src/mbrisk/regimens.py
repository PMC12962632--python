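"""Protocol regimen definitions and cumulative per-drug dose accounting.

The three source trials' chemotherapy plans are transcribed into a
packaged YAML config (``data/regimens.yaml``).  Accounting is per body
surface area (mg/m2) as prescribed: absolute mg caps and age-based
adjustments depend on patient size and are out of scope.  Randomized
add-on phases (ACNS0332 carboplatin chemoradiation, isotretinoin) are
tagged and can be included or dropped at load time; the carboplatin arm
is included by default because it defines the HDCSI+carboplatin
treatment category, while isotretinoin (no survival benefit) is off by
default.  CSI dose ranges and boost clinical-target-volume margins are
carried as metadata only and never enter dose arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml


@dataclass(frozen=True)
class Administration:
    drug: str
    dose_mg_m2: float
    count: int

    def __post_init__(self) -> None:
        if self.dose_mg_m2 <= 0:
            raise ValueError("dose must be positive")
        if self.count < 1:
            raise ValueError("administration count must be at least 1")


@dataclass(frozen=True)
class Phase:
    label: str
    administrations: tuple[Administration, ...]
    cycles: int = 1
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycle count must be at least 1")


@dataclass(frozen=True)
class RegimenSpec:
    regimen_id: str
    phases: tuple[Phase, ...]
    metadata: dict = field(default_factory=dict)


def load_regimens(
    include_carboplatin: bool = True,
    include_isotretinoin: bool = False,
) -> dict[str, RegimenSpec]:
    """Load the packaged regimen definitions."""
    text = resources.files("mbrisk.data").joinpath("regimens.yaml").read_text()
    raw = yaml.safe_load(text)
    keep_arms = {None}
    if include_carboplatin:
        keep_arms.add("carboplatin")
    if include_isotretinoin:
        keep_arms.add("isotretinoin")
    regimens: dict[str, RegimenSpec] = {}
    for rid, spec in raw["regimens"].items():
        phases = []
        for ph in spec["phases"]:
            if ph.get("arm") not in keep_arms:
                continue
            phases.append(
                Phase(
                    label=ph["label"],
                    cycles=int(ph.get("cycles", 1)),
                    arm=ph.get("arm"),
                    administrations=tuple(
                        Administration(
                            drug=a["drug"],
                            dose_mg_m2=float(a["dose_mg_m2"]),
                            count=int(a["count"]),
                        )
                        for a in ph["administrations"]
                    ),
                )
            )
        regimens[rid] = RegimenSpec(
            regimen_id=rid, phases=tuple(phases), metadata=spec.get("metadata", {})
        )
    return regimens


def cumulative_dose(regimen: RegimenSpec, drug: str) -> float:
    """Cumulative prescribed dose (mg/m2) of ``drug`` over all phases;
    0 when the regimen does not use the drug."""
    total = 0.0
    for phase in regimen.phases:
        for adm in phase.administrations:
            if adm.drug == drug:
                total += adm.dose_mg_m2 * adm.count * phase.cycles
    return total


def dose_ratio(regimen_a: RegimenSpec, regimen_b: RegimenSpec, drug: str) -> float:
    """Fold difference cumulative_dose(A) / cumulative_dose(B)."""
    denom = cumulative_dose(regimen_b, drug)
    if denom == 0:
        raise ZeroDivisionError(
            f"{regimen_b.regimen_id} prescribes no {drug}; ratio undefined"
        )
    return cumulative_dose(regimen_a, drug) / denom


def drugs_in(regimens: list[RegimenSpec]) -> list[str]:
    seen: list[str] = []
    for r in regimens:
        for phase in r.phases:
            for adm in phase.administrations:
                if adm.drug not in seen:
                    seen.append(adm.drug)
    return seen


def dose_table(regimens: list[RegimenSpec]) -> pd.DataFrame:
    """Complete drug x regimen cumulative-dose matrix (mg/m2), zeros for
    absent drugs."""
    drugs = drugs_in(regimens)
    data = {
        r.regimen_id: [cumulative_dose(r, drug) for drug in drugs] for r in regimens
    }
    return pd.DataFrame(data, index=pd.Index(drugs, name="drug"))
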