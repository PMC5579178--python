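"""Typed domain records for screening cohorts.

A cohort is a set of participants, each carrying one or more
screen-detected pulmonary nodules measured on a baseline low-dose CT.
Records hold measurements only (no images): axial diameters from
segmentation, a volumetric mean diameter, morphology flags and the
participant covariates required by the PanCan malignancy-risk model.

All lengths are millimetres, volumes cubic millimetres.  Units are
fixed; there is no auto-detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional


class CohortError(ValueError):
    """Base class for cohort data problems."""


class SchemaError(CohortError):
    """Input table does not match the documented schema."""


class ValidationError(CohortError):
    """A record violates a domain invariant."""


class NoduleType(Enum):
    """Conventional nodule morphology on CT.

    ``GROUND_GLASS`` is the pure ground-glass ("non-solid") type.
    Perifissural nodules are not a fourth type: they are solid nodules
    attached to a fissure and carry a separate :attr:`NoduleRecord.is_pfn`
    flag, because a PFN still has a conventional morphology.
    """

    SOLID = "solid"
    PART_SOLID = "part_solid"
    GROUND_GLASS = "ground_glass"


class Calcification(Enum):
    """Calcification pattern.

    ``BENIGN_PATTERN`` covers the classically benign patterns: complete,
    central, popcorn or concentric rings.  Any other calcification is
    ``OTHER`` and does not trigger benign shortcuts in any scoring system.
    """

    NONE = "none"
    BENIGN_PATTERN = "benign_pattern"
    OTHER = "other"


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"


#: Relative tolerance for agreement between a stored volumetric mean
#: diameter and one derived from a stored volume.
VOLUME_DIAMETER_RTOL = 0.01


def _mean3d_from_volume(volume: float) -> float:
    # local copy to avoid a circular import; the public entry point is
    # nodulerisk.sizes.mean3d_from_volume
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class NoduleRecord:
    """One nodule: morphology, size measurements and outcome label.

    Size fields
    -----------
    d_longest_axial / d_perp_axial
        Longest and perpendicular diameters on axial sections (mm).
    volume, d_mean3d
        Segmented volume (mm^3) and/or the volumetric mean diameter
        (mm); at least one must be given.  When only the volume is
        present the diameter is derived as the volume-equivalent-sphere
        diameter; when both are present they must agree to 1% relative.
    *_solid
        Solid-component counterparts, required iff ``type`` is
        ``PART_SOLID`` and forbidden otherwise.
    """

    nodule_id: str
    participant_id: str
    type: NoduleType
    is_pfn: bool
    calcification: Calcification
    spiculated: bool
    upper_lobe: bool
    d_longest_axial: float
    d_perp_axial: float
    malignant: bool
    volume: Optional[float] = None
    d_mean3d: Optional[float] = None
    d_longest_axial_solid: Optional[float] = None
    d_perp_axial_solid: Optional[float] = None
    d_mean3d_solid: Optional[float] = None

    def __post_init__(self) -> None:
        nid = self.nodule_id

        def err(msg: str) -> ValidationError:
            return ValidationError(f"nodule {nid!r}: {msg}")

        if self.d_longest_axial <= 0 or self.d_perp_axial <= 0:
            raise err("axial diameters must be positive")
        if self.d_perp_axial > self.d_longest_axial:
            raise err(
                f"d_perp_axial ({self.d_perp_axial}) exceeds "
                f"d_longest_axial ({self.d_longest_axial})"
            )

        if self.volume is None and self.d_mean3d is None:
            raise err("one of volume or d_mean3d is required")
        if self.volume is not None:
            if self.volume <= 0:
                raise err("volume must be positive")
            derived = _mean3d_from_volume(self.volume)
            if self.d_mean3d is None:
                object.__setattr__(self, "d_mean3d", derived)
            elif abs(self.d_mean3d - derived) > VOLUME_DIAMETER_RTOL * derived:
                raise err(
                    f"d_mean3d ({self.d_mean3d}) inconsistent with volume "
                    f"({self.volume} -> {derived:.3f} mm)"
                )
        if self.d_mean3d is not None and self.d_mean3d <= 0:
            raise err("d_mean3d must be positive")

        solid = {
            "d_longest_axial_solid": self.d_longest_axial_solid,
            "d_perp_axial_solid": self.d_perp_axial_solid,
            "d_mean3d_solid": self.d_mean3d_solid,
        }
        if self.type is NoduleType.PART_SOLID:
            missing = [k for k, v in solid.items() if v is None]
            if missing:
                raise err(f"part-solid nodule missing {', '.join(missing)}")
            for name, value in solid.items():
                if value <= 0:
                    raise err(f"{name} must be positive")
            whole = {
                "d_longest_axial_solid": self.d_longest_axial,
                "d_perp_axial_solid": self.d_perp_axial,
                "d_mean3d_solid": self.d_mean3d,
            }
            for name, value in solid.items():
                if value > whole[name]:
                    raise err(
                        f"{name} ({value}) exceeds whole-nodule counterpart "
                        f"({whole[name]})"
                    )
            if self.d_perp_axial_solid > self.d_longest_axial_solid:
                raise err("solid-component perpendicular exceeds longest")
        else:
            present = [k for k, v in solid.items() if v is not None]
            if present:
                raise err(
                    f"solid-component measurements ({', '.join(present)}) "
                    f"given for a {self.type.value} nodule"
                )

        if self.is_pfn and self.type is not NoduleType.SOLID:
            raise err("perifissural nodules are solid by definition")


@dataclass(frozen=True)
class ParticipantRecord:
    """Subject-level covariates used by the PanCan model plus outcome."""

    participant_id: str
    age: float
    sex: Sex
    family_history_lung_cancer: bool
    emphysema: bool
    nodule_count_additional: int
    has_cancer: bool

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(
                f"participant {self.participant_id!r}: age must be positive"
            )
        if self.nodule_count_additional < 0:
            raise ValidationError(
                f"participant {self.participant_id!r}: "
                "nodule_count_additional must be >= 0"
            )


@dataclass(frozen=True)
class Cohort:
    """Validated collection of participants and their nodules.

    Construction enforces referential integrity (every nodule links to a
    known participant, every participant carries at least the nodules
    that reference it) and the outcome consistency rule: a participant
    ``has_cancer`` iff at least one of their nodules is malignant.
    """

    participants: tuple[ParticipantRecord, ...]
    nodules: tuple[NoduleRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))
        object.__setattr__(self, "nodules", tuple(self.nodules))
        pids = [p.participant_id for p in self.participants]
        if len(set(pids)) != len(pids):
            raise ValidationError("duplicate participant_id in cohort")
        nids = [n.nodule_id for n in self.nodules]
        if len(set(nids)) != len(nids):
            raise ValidationError("duplicate nodule_id in cohort")
        known = set(pids)
        malignant_by_pid: dict[str, bool] = {pid: False for pid in known}
        for n in self.nodules:
            if n.participant_id not in known:
                raise ValidationError(
                    f"nodule {n.nodule_id!r} references unknown participant "
                    f"{n.participant_id!r}"
                )
            if n.malignant:
                malignant_by_pid[n.participant_id] = True
        for p in self.participants:
            if p.has_cancer != malignant_by_pid[p.participant_id]:
                raise ValidationError(
                    f"participant {p.participant_id!r}: has_cancer="
                    f"{p.has_cancer} contradicts nodule labels"
                )

    def nodules_of(self, participant_id: str) -> tuple[NoduleRecord, ...]:
        return tuple(
            n for n in self.nodules if n.participant_id == participant_id
        )

    def participant(self, participant_id: str) -> ParticipantRecord:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_nodules(self) -> int:
        return len(self.nodules)


def build_cohort(
    participants: list[ParticipantRecord] | tuple[ParticipantRecord, ...],
    nodules: list[NoduleRecord] | tuple[NoduleRecord, ...],
    *,
    derive_counts: bool = False,
    derive_cancer: bool = False,
) -> Cohort:
    """Assemble a :class:`Cohort`, optionally deriving participant fields.

    With ``derive_counts`` the additional-nodule count of each participant
    is replaced by (number of linked nodules - 1); with ``derive_cancer``
    the ``has_cancer`` flag is set from the nodule labels.  Both are used
    by the readers when the corresponding input column is absent.
    """
    n_linked: dict[str, int] = {}
    any_malignant: dict[str, bool] = {}
    for n in nodules:
        n_linked[n.participant_id] = n_linked.get(n.participant_id, 0) + 1
        any_malignant[n.participant_id] = (
            any_malignant.get(n.participant_id, False) or n.malignant
        )
    fixed = []
    for p in participants:
        if derive_counts:
            p = replace(
                p,
                nodule_count_additional=max(
                    n_linked.get(p.participant_id, 0) - 1, 0
                ),
            )
        if derive_cancer:
            p = replace(
                p, has_cancer=any_malignant.get(p.participant_id, False)
            )
        fixed.append(p)
    return Cohort(tuple(fixed), tuple(nodules))
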