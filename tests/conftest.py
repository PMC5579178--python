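"""Shared fixtures: worked-example nodules and small hand-built cohorts.

The worked-example nodules carry the published diameter measurements of
six illustrative screen-detected nodules (three benign, three
malignant) whose category assignments under each system are known, plus
three nodules used to illustrate between-definition size variation.
Perpendicular axial diameters are back-solved from the mean axial
diameter (d_perp = 2 * d_meanAxial - d_longest).
"""

import pytest

from nodulerisk import (
    Calcification,
    NoduleRecord,
    NoduleType,
    ParticipantRecord,
    Sex,
    build_cohort,
)


def make_nodule(
    nodule_id="n1",
    participant_id="p1",
    type=NoduleType.SOLID,
    is_pfn=False,
    calcification=Calcification.NONE,
    spiculated=False,
    upper_lobe=False,
    d_longest_axial=10.0,
    d_perp_axial=None,
    d_mean_axial=None,
    volume=None,
    d_mean3d=None,
    d_longest_axial_solid=None,
    d_perp_axial_solid=None,
    d_mean_axial_solid=None,
    d_mean3d_solid=None,
    malignant=False,
):
    """NoduleRecord builder accepting a mean axial diameter directly."""
    if d_mean_axial is not None:
        d_perp_axial = 2.0 * d_mean_axial - d_longest_axial
    if d_perp_axial is None:
        d_perp_axial = d_longest_axial
    if d_mean_axial_solid is not None:
        d_perp_axial_solid = (
            2.0 * d_mean_axial_solid - d_longest_axial_solid
        )
    if volume is None and d_mean3d is None:
        d_mean3d = d_perp_axial  # any value <= longest works for tests
    return NoduleRecord(
        nodule_id=nodule_id,
        participant_id=participant_id,
        type=type,
        is_pfn=is_pfn,
        calcification=calcification,
        spiculated=spiculated,
        upper_lobe=upper_lobe,
        d_longest_axial=d_longest_axial,
        d_perp_axial=d_perp_axial,
        volume=volume,
        d_mean3d=d_mean3d,
        d_longest_axial_solid=d_longest_axial_solid,
        d_perp_axial_solid=d_perp_axial_solid,
        d_mean3d_solid=d_mean3d_solid,
        malignant=malignant,
    )


def make_participant(
    participant_id="p1",
    age=60.0,
    sex=Sex.MALE,
    family_history_lung_cancer=False,
    emphysema=False,
    nodule_count_additional=0,
    has_cancer=False,
):
    return ParticipantRecord(
        participant_id=participant_id,
        age=age,
        sex=sex,
        family_history_lung_cancer=family_history_lung_cancer,
        emphysema=emphysema,
        nodule_count_additional=nodule_count_additional,
        has_cancer=has_cancer,
    )


#: The six worked-example nodules with their published measurements and
#: the expected Lung-RADS / NCCN categories (each under the system's
#: own size definition: MEAN_3D for Lung-RADS, MEAN_AXIAL for NCCN).
WORKED_EXAMPLES = {
    "A": dict(
        kwargs=dict(
            type=NoduleType.GROUND_GLASS,
            d_longest_axial=10.0,
            d_mean3d=9.4,
            d_mean_axial=8.8,
            malignant=False,
        ),
        lung_rads="2",
        nccn="3",
    ),
    "B": dict(
        kwargs=dict(
            type=NoduleType.PART_SOLID,
            d_longest_axial=9.4,
            d_mean3d=8.5,
            d_mean_axial=8.8,
            d_longest_axial_solid=7.2,
            d_mean3d_solid=6.2,
            d_mean_axial_solid=6.0,
            malignant=False,
        ),
        lung_rads="4A",
        nccn="6",
    ),
    "C": dict(
        kwargs=dict(
            type=NoduleType.SOLID,
            d_longest_axial=10.5,
            d_mean3d=8.4,
            d_mean_axial=9.1,
            malignant=False,
        ),
        lung_rads="4A",
        nccn="6",
    ),
    "D": dict(
        kwargs=dict(
            type=NoduleType.GROUND_GLASS,
            d_longest_axial=12.4,
            d_mean3d=9.8,
            d_mean_axial=11.7,
            malignant=True,
        ),
        lung_rads="2",
        nccn="4",
    ),
    "E": dict(
        kwargs=dict(
            type=NoduleType.PART_SOLID,
            d_longest_axial=17.4,
            d_mean3d=14.7,
            d_mean_axial=15.7,
            d_longest_axial_solid=7.1,
            d_mean3d_solid=5.2,
            d_mean_axial_solid=6.3,
            malignant=True,
        ),
        lung_rads="3",
        nccn="6",
    ),
    "F": dict(
        kwargs=dict(
            type=NoduleType.SOLID,
            d_longest_axial=15.2,
            d_mean3d=13.5,
            d_mean_axial=13.2,
            malignant=True,
        ),
        lung_rads="4A",
        nccn="6",
    ),
    # solid benign nodule that is NCCN risk-dominant in the
    # three-different-dominants example
    "G": dict(
        kwargs=dict(
            type=NoduleType.SOLID,
            d_longest_axial=6.6,
            d_mean_axial=6.1,
            d_mean3d=5.8,
            malignant=False,
        ),
        nccn="5",
    ),
}


@pytest.fixture
def worked_nodules():
    return {
        key: make_nodule(nodule_id=key, **entry["kwargs"])
        for key, entry in WORKED_EXAMPLES.items()
    }


@pytest.fixture
def small_cohort():
    """Two participants / three nodules; one cancer case."""
    nodules = [
        make_nodule(
            "n1", "p1", d_longest_axial=14.0, d_perp_axial=11.0,
            d_mean3d=10.5, malignant=True, spiculated=True,
        ),
        make_nodule(
            "n2", "p1", d_longest_axial=5.0, d_perp_axial=4.0, d_mean3d=4.2,
        ),
        make_nodule(
            "n3", "p2", type=NoduleType.PART_SOLID, d_longest_axial=9.0,
            d_perp_axial=7.0, volume=113.097335529233,
            d_longest_axial_solid=4.5, d_perp_axial_solid=3.5,
            d_mean3d_solid=3.0,
        ),
    ]
    participants = [
        make_participant(
            "p1", age=66.0, sex=Sex.FEMALE, emphysema=True,
            nodule_count_additional=1, has_cancer=True,
        ),
        make_participant("p2", age=55.0, family_history_lung_cancer=True),
    ]
    return build_cohort(participants, nodules)
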