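"""Nodule size definitions and conversions.

Three interchangeable diameter definitions are used throughout:

``LONGEST_C``
    Longest diameter on axial sections from semi-automated
    segmentation.  ``LONGEST_M`` is the same quantity measured
    manually; it differs only in provenance and dispatches to the
    same stored field.
``MEAN_3D``
    Volumetric mean diameter: the diameter of the sphere matching the
    nodule's three-dimensional extent, computed from the segmented
    volume as d = (6V/pi)^(1/3).
``MEAN_AXIAL``
    Arithmetic mean of the longest and perpendicular diameters on
    axial sections.

Diameters are kept at full precision here; any rounding is a property
of the individual scoring system (Lung-RADS rounds to whole mm, the
others do not).
"""

from __future__ import annotations

import math
from enum import Enum

from .records import NoduleRecord, NoduleType


class SizeDefinition(Enum):
    LONGEST_C = "longest_c"
    LONGEST_M = "longest_m"
    MEAN_3D = "mean_3d"
    MEAN_AXIAL = "mean_axial"


class Component(Enum):
    """Whole nodule or, for part-solid nodules, the solid component."""

    WHOLE = "whole"
    SOLID = "solid"


def mean3d_from_volume(volume: float) -> float:
    """Volume-equivalent-sphere diameter in mm for a volume in mm^3.

    Strictly increasing in volume; inverse of v = pi d^3 / 6.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def mean_axial(d_longest: float, d_perp: float) -> float:
    """Mean of the longest and perpendicular axial diameters (mm)."""
    if d_perp <= 0 or d_longest <= 0:
        raise ValueError("diameters must be positive")
    if d_perp > d_longest:
        raise ValueError(
            f"perpendicular diameter ({d_perp}) exceeds longest ({d_longest})"
        )
    return 0.5 * (d_longest + d_perp)


def nodule_size(
    nodule: NoduleRecord,
    defn: SizeDefinition,
    component: Component = Component.WHOLE,
) -> float:
    """Diameter of ``nodule`` under a size definition, in mm.

    ``component=SOLID`` is only meaningful for part-solid nodules and
    raises for any other type.
    """
    if component is Component.SOLID:
        if nodule.type is not NoduleType.PART_SOLID:
            raise ValueError(
                f"nodule {nodule.nodule_id!r}: solid-component size "
                f"requested for a {nodule.type.value} nodule"
            )
        if defn in (SizeDefinition.LONGEST_C, SizeDefinition.LONGEST_M):
            return nodule.d_longest_axial_solid
        if defn is SizeDefinition.MEAN_3D:
            return nodule.d_mean3d_solid
        return mean_axial(
            nodule.d_longest_axial_solid, nodule.d_perp_axial_solid
        )
    if defn in (SizeDefinition.LONGEST_C, SizeDefinition.LONGEST_M):
        return nodule.d_longest_axial
    if defn is SizeDefinition.MEAN_3D:
        # guaranteed by record validation: d_mean3d present or derived
        return nodule.d_mean3d
    return mean_axial(nodule.d_longest_axial, nodule.d_perp_axial)
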