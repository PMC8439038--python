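import numpy as np
import pytest

from seroindex.cutoffs import Cutoff
from seroindex.elisa import PlateRun, ReplicateGroup, WellRole
from seroindex.records import SubjectRecord


def make_group(ods, sample_id="S1", antigen_id="cit-DL", role=WellRole.ANTIGEN):
    return ReplicateGroup(sample_id=sample_id, antigen_id=antigen_id,
                          role=role, ods=list(ods))


def make_plate(
    sample_nets=((0.9, 1.0, 1.1),),
    backgrounds=((0.2, 0.2, 0.2),),
    secondary=(0.05, 0.05, 0.05),
    positive=(1.0, 1.0, 1.0),
    plate_id="P1",
):
    groups = []
    for i, (ag, bg) in enumerate(zip(sample_nets, backgrounds)):
        sid = f"S{i + 1}"
        groups.append(make_group(ag, sample_id=sid))
        groups.append(make_group(bg, sample_id=sid, antigen_id="",
                                 role=WellRole.BACKGROUND))
    return PlateRun(
        plate_id=plate_id,
        groups=groups,
        secondary_control=make_group(secondary, sample_id="", antigen_id="",
                                     role=WellRole.SECONDARY_CONTROL),
        positive_control=make_group(positive, sample_id="", antigen_id="",
                                    role=WellRole.POSITIVE_CONTROL),
    )


def make_cutoff(threshold, marker="cit", reference="healthy_controls", target=0.98):
    return Cutoff(marker_id=marker, reference_label=reference,
                  target_specificity=target, threshold=threshold,
                  achieved_specificity=target, reference_n=100)


def make_record(subject_id="S1", cohort="eira", cit=0.5, native=0.2, **kw):
    return SubjectRecord(subject_id=subject_id, cohort=cohort,
                         cit_net=cit, native_net=native, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
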