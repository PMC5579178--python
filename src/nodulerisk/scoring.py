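"""The three nodule risk-stratification systems.

* PanCan (Brock) model: a logistic malignancy-risk model for baseline
  screen-detected nodules producing a continuous risk in percent, here
  the full variant that includes spiculation ("model 2b").  Published
  cutpoints map the risk onto four categories.  Completely calcified
  (benign-pattern) and perifissural nodules were excluded from the
  model's derivation and are assigned a risk of exactly 0%.
* Lung-RADS v1.0: the ACR's five baseline categories (1, 2, 3, 4A, 4B)
  from nodule type and size, with sizes rounded to the nearest whole
  millimetre.  Growth-based upgrades and the subjective 4X category are
  out of scope: only baseline (first-screen) branches are implemented.
* NCCN v1.2016: six categories from nodule type and size, no rounding.
  Multiple-GGN rules are not applied.

Every scorer is parameterized by a :class:`~nodulerisk.sizes.SizeDefinition`
so the sensitivity of each system to the diameter definition can be
studied.  The published defaults are LONGEST_C for PanCan, MEAN_3D for
Lung-RADS and MEAN_AXIAL for NCCN.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .records import Calcification, Cohort, NoduleRecord, NoduleType, ParticipantRecord, Sex
from .sizes import Component, SizeDefinition, nodule_size


class System(Enum):
    PANCAN = "pancan"
    LUNG_RADS = "lung_rads"
    NCCN = "nccn"


#: Diameter definition each system uses in its original publication.
PUBLISHED_DEFN: dict[System, SizeDefinition] = {
    System.PANCAN: SizeDefinition.LONGEST_C,
    System.LUNG_RADS: SizeDefinition.MEAN_3D,
    System.NCCN: SizeDefinition.MEAN_AXIAL,
}

_LUNG_RADS_RANK = {"1": 1, "2": 2, "3": 3, "4A": 4, "4B": 5}


@dataclass(frozen=True)
class SizeTransform:
    """Named transform applied to the diameter before the size beta.

    ``identity`` uses the raw diameter in mm.  ``power_centered``
    computes (d / scale_mm) ** power - center; the published PanCan
    model uses power -0.5, scale 10 mm and center 1.58113883
    (the transform evaluated at 4 mm, so the term vanishes there).
    """

    name: str = "identity"
    power: float = 1.0
    center: float = 0.0
    scale_mm: float = 1.0

    def __call__(self, d_mm: float) -> float:
        if self.name == "identity":
            return d_mm
        if self.name == "power_centered":
            return (d_mm / self.scale_mm) ** self.power - self.center
        raise ValueError(f"unknown size transform {self.name!r}")


@dataclass(frozen=True)
class PanCanCoefficients:
    """Parameter set of the PanCan logistic model (log-odds scale).

    Loaded from a JSON/YAML config; :meth:`default` returns the bundled
    published parameter set (full model with spiculation).  ``age`` and
    ``count`` are centred before multiplication by their betas; the
    count fed to the model is the number of additional nodules on the
    scan.
    """

    intercept: float
    beta_age: float
    beta_sex_female: float
    beta_family_history: float
    beta_emphysema: float
    beta_size: float
    size_transform: SizeTransform
    beta_nonsolid: float
    beta_partsolid: float
    beta_upper_lobe: float
    beta_count: float
    beta_spiculation: float
    age_center: float = 0.0
    count_center: float = 0.0
    provenance: str = ""

    @classmethod
    def from_dict(cls, d: dict) -> "PanCanCoefficients":
        d = dict(d)
        st = d.pop("size_transform", None)
        if st is None:
            transform = SizeTransform()
        elif isinstance(st, SizeTransform):
            transform = st
        else:
            transform = SizeTransform(**st)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(
                f"unknown coefficient field(s): {', '.join(sorted(extra))}"
            )
        return cls(size_transform=transform, **d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PanCanCoefficients":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    @classmethod
    def default(cls) -> "PanCanCoefficients":
        ref = resources.files("nodulerisk.data") / "pancan_model2b.json"
        return cls.from_dict(json.loads(ref.read_text()))


@dataclass(frozen=True)
class SystemScore:
    """Per-nodule output of one scoring system.

    ``rank`` increases strictly with management intensity within a
    system, so argmax over ranks picks the risk-dominant nodule:
    PanCan rank is the continuous risk percent, Lung-RADS maps
    1,2,3,4A,4B to 1..5 and NCCN uses its numeric category.
    """

    system: System
    category_label: str
    rank: float
    risk_percent: Optional[float] = None


def pancan_risk(
    nodule: NoduleRecord,
    participant: ParticipantRecord,
    coeffs: Optional[PanCanCoefficients] = None,
    defn: SizeDefinition = SizeDefinition.LONGEST_C,
) -> float:
    """Continuous malignancy risk in percent under the PanCan model.

    Benign-pattern calcification or a perifissural nodule short-circuits
    to exactly 0.0; otherwise 100 * logistic(intercept + sum(beta * x))
    with the configured size transform applied to the whole-nodule
    diameter under ``defn``.
    """
    if coeffs is None:
        coeffs = PanCanCoefficients.default()
    if nodule.calcification is Calcification.BENIGN_PATTERN or nodule.is_pfn:
        return 0.0
    d = nodule_size(nodule, defn, Component.WHOLE)
    x = coeffs.intercept
    x += coeffs.beta_age * (participant.age - coeffs.age_center)
    if participant.sex is Sex.FEMALE:
        x += coeffs.beta_sex_female
    if participant.family_history_lung_cancer:
        x += coeffs.beta_family_history
    if participant.emphysema:
        x += coeffs.beta_emphysema
    x += coeffs.beta_size * coeffs.size_transform(d)
    if nodule.type is NoduleType.GROUND_GLASS:
        x += coeffs.beta_nonsolid
    elif nodule.type is NoduleType.PART_SOLID:
        x += coeffs.beta_partsolid
    if nodule.upper_lobe:
        x += coeffs.beta_upper_lobe
    x += coeffs.beta_count * (
        participant.nodule_count_additional - coeffs.count_center
    )
    if nodule.spiculated:
        x += coeffs.beta_spiculation
    return 100.0 / (1.0 + math.exp(-x))


def pancan_category(risk_percent: float) -> str:
    """Map a PanCan risk (percent) onto the published four categories.

    Bands are left-closed: <1.5 -> "1", [1.5, 6) -> "2",
    [6, 30) -> "3", >=30 -> "4".
    """
    if not 0.0 <= risk_percent <= 100.0:
        raise ValueError(f"risk_percent out of [0, 100]: {risk_percent}")
    if risk_percent < 1.5:
        return "1"
    if risk_percent < 6.0:
        return "2"
    if risk_percent < 30.0:
        return "3"
    return "4"


def _round_half_up_mm(d: float) -> int:
    # Lung-RADS rounds sizes to the nearest whole millimetre; ties (x.5)
    # round up, consistently with all worked category assignments.
    return int(math.floor(d + 0.5))


def lung_rads_category(
    nodule: NoduleRecord, defn: SizeDefinition = SizeDefinition.MEAN_3D
) -> str:
    """Baseline Lung-RADS v1.0 category ("1", "2", "3", "4A", "4B").

    Sizes are rounded half-up to whole mm before the threshold tests.
    Benign-pattern calcification gives category 1.  Perifissural
    nodules are scored by the solid-nodule size bands (the system has
    no PFN rule).  Growth branches and 4X are not modelled.
    """
    if nodule.calcification is Calcification.BENIGN_PATTERN:
        return "1"
    total = _round_half_up_mm(nodule_size(nodule, defn, Component.WHOLE))
    if nodule.type is NoduleType.GROUND_GLASS:
        return "2" if total < 20 else "3"
    if nodule.type is NoduleType.PART_SOLID:
        solid = _round_half_up_mm(nodule_size(nodule, defn, Component.SOLID))
        if solid >= 8:
            return "4B"
        if total < 6:
            return "2"
        if solid < 6:
            return "3"
        return "4A"
    # solid (including PFN)
    if total < 6:
        return "2"
    if total < 8:
        return "3"
    if total < 15:
        return "4A"
    return "4B"


def nccn_category(
    nodule: NoduleRecord, defn: SizeDefinition = SizeDefinition.MEAN_AXIAL
) -> str:
    """NCCN v1.2016 category ("1" .. "6"); no rounding.

    Solid and part-solid nodules are classified by the TOTAL nodule
    diameter: <6 -> 1, [6, 8] -> 5, >8 -> 6.  Pure ground-glass:
    <=5 -> 2, (5, 10] -> 3, >10 -> 4.  Benign-pattern calcification
    maps to category 1 (the guideline states no calcification rule;
    this parallels Lung-RADS 1 and the PanCan 0% rule).  PFNs are
    scored as solid nodules.  Multiple-GGN provisions are not applied.
    """
    if nodule.calcification is Calcification.BENIGN_PATTERN:
        return "1"
    total = nodule_size(nodule, defn, Component.WHOLE)
    if nodule.type is NoduleType.GROUND_GLASS:
        if total <= 5.0:
            return "2"
        if total <= 10.0:
            return "3"
        return "4"
    if total < 6.0:
        return "1"
    if total <= 8.0:
        return "5"
    return "6"


def score_nodule(
    nodule: NoduleRecord,
    system: System,
    defn: Optional[SizeDefinition] = None,
    participant: Optional[ParticipantRecord] = None,
    coeffs: Optional[PanCanCoefficients] = None,
) -> SystemScore:
    """Score a single nodule under one system.

    ``defn`` defaults to the system's published diameter definition.
    PanCan additionally needs the participant record.
    """
    if defn is None:
        defn = PUBLISHED_DEFN[system]
    if system is System.PANCAN:
        if participant is None:
            raise ValueError("PanCan scoring requires the participant record")
        risk = pancan_risk(nodule, participant, coeffs, defn)
        return SystemScore(
            system=system,
            category_label=pancan_category(risk),
            rank=risk,
            risk_percent=risk,
        )
    if system is System.LUNG_RADS:
        label = lung_rads_category(nodule, defn)
        return SystemScore(system, label, float(_LUNG_RADS_RANK[label]))
    label = nccn_category(nodule, defn)
    return SystemScore(system, label, float(label))


def score_all(
    cohort: Cohort,
    system: System,
    defn: Optional[SizeDefinition] = None,
    coeffs: Optional[PanCanCoefficients] = None,
) -> pd.DataFrame:
    """Score every nodule in a cohort under one system.

    Returns a DataFrame with one row per nodule and columns
    ``nodule_id, participant_id, system, defn, risk_percent,
    category_label, rank``; deterministic and independent of row order.
    """
    if defn is None:
        defn = PUBLISHED_DEFN[system]
    if system is System.PANCAN and coeffs is None:
        coeffs = PanCanCoefficients.default()
    participants = {p.participant_id: p for p in cohort.participants}
    rows = []
    for nodule in cohort.nodules:
        try:
            score = score_nodule(
                nodule,
                system,
                defn,
                participant=participants[nodule.participant_id],
                coeffs=coeffs,
            )
        except (ValueError, KeyError) as exc:
            raise type(exc)(
                f"scoring nodule {nodule.nodule_id!r} under "
                f"{system.value}/{defn.value}: {exc}"
            ) from exc
        rows.append(
            {
                "nodule_id": nodule.nodule_id,
                "participant_id": nodule.participant_id,
                "system": system.value,
                "defn": defn.value,
                "risk_percent": score.risk_percent,
                "category_label": score.category_label,
                "rank": score.rank,
            }
        )
    columns = [
        "nodule_id",
        "participant_id",
        "system",
        "defn",
        "risk_percent",
        "category_label",
        "rank",
    ]
    return pd.DataFrame(rows, columns=columns)
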