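import numpy as np
import pytest

from mbrisk.cnv import ChromCall
from mbrisk.cohort import (
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


def make_record(pid="P1", trial=Trial.SJMB03, **kw):
    defaults = dict(
        age_years=8.0,
        m_stage=MStage.M0,
        r_status=RStatus.R0,
        histology=Histology.CLASSIC,
        csi_arm=CSIArm.SDCSI,
        carboplatin=False,
        boost_field=BoostField.IFRT,
        pfs_months=60.0,
        pfs_event=0,
        os_months=72.0,
        os_event=0,
    )
    defaults.update(kw)
    return PatientRecord(patient_id=pid, trial=trial, **defaults)


def make_profile(pid="P1", group=Group.G4, **kw):
    defaults = dict(
        subgroup=Subgroup.NONE,
        tp53_mut=False,
        gli2_amp=False,
        mycn_amp=False,
        myc_amp=False,
        chrom_calls={"7": ChromCall.NEUTRAL, "8": ChromCall.NEUTRAL, "11": ChromCall.NEUTRAL},
        arm_17p_loss=False,
    )
    defaults.update(kw)
    return MolecularProfile(patient_id=pid, group=group, **defaults)


def make_cohort(*pairs, provenance="test"):
    table = CohortTable(records=list(pairs), provenance=provenance)
    table.validate()
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
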