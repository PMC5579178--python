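"""Synthetic baseline-screening cohorts with a case-control structure.

The generator emulates the marginal structure of a baseline
lung-screening risk-dominant-nodule cohort: about one participant in
ten carries a cancer, benign nodules are small and right-skewed
(log-normal, median ~6 mm), malignant nodules larger (median ~14 mm),
spiculation is almost exclusive to cancers, while benign-pattern
calcification and perifissural morphology occur only in benign
nodules.  Participant covariates (age, sex, family history of lung
cancer, emphysema) differ modestly between the groups.

Geometry: a nodule's perpendicular axial diameter is a Beta-distributed
fraction of the longest diameter, and the volumetric mean diameter is a
"compactness" fraction of the mean axial diameter, capped at the
longest diameter — so perpendicular <= mean3d, meanAxial <= longest by
construction.  Covariates are drawn independently of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import (
    Calcification,
    Cohort,
    NoduleRecord,
    NoduleType,
    ParticipantRecord,
    Sex,
    build_cohort,
)


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class GroupParams:
    """Per-outcome-group (malignant / benign) nodule and subject marginals."""

    size_median_mm: float
    size_log_sigma: float
    #: probabilities of solid / part-solid / pure ground-glass
    type_probs: tuple[float, float, float]
    #: marginal probability of spiculation (realized on non-GGN nodules)
    spiculation_p: float
    #: marginal probability of benign-pattern calcification (solid only)
    calcified_p: float
    #: marginal probability of a perifissural nodule (solid, non-calcified)
    pfn_p: float
    upper_lobe_p: float
    age_mean: float
    age_sd: float
    sex_female_p: float
    family_history_p: float
    emphysema_p: float


#: Malignant-group defaults: median longest diameter 13.9 mm with a
#: log-sigma putting the mean near 16.5 mm; type mix 66/23/11%;
#: spiculation 28%; no calcified or perifissural cancers.
MALIGNANT_DEFAULTS = GroupParams(
    size_median_mm=13.9,
    size_log_sigma=0.586,
    type_probs=(0.66, 0.23, 0.11),
    spiculation_p=0.28,
    calcified_p=0.0,
    pfn_p=0.0,
    upper_lobe_p=0.58,
    age_mean=61.0,
    age_sd=5.5,
    sex_female_p=0.45,
    family_history_p=0.27,
    emphysema_p=0.73,
)

#: Benign-group defaults: median 6.1 mm (mean near 7.6 mm); 87/3/10%
#: type mix; spiculation 1%; 14% benign-pattern calcified; 8% PFN.
BENIGN_DEFAULTS = GroupParams(
    size_median_mm=6.1,
    size_log_sigma=0.663,
    type_probs=(0.87, 0.03, 0.10),
    spiculation_p=0.01,
    calcified_p=0.14,
    pfn_p=0.08,
    upper_lobe_p=0.48,
    age_mean=58.0,
    age_sd=5.5,
    sex_female_p=0.47,
    family_history_p=0.16,
    emphysema_p=0.67,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the simulated cohort.

    Defaults reproduce the marginal characteristics of a 613-participant
    baseline screening case-control set with cancer prevalence 64/613.
    Each participant carries one primary nodule plus a Poisson number of
    additional nodules; cancer participants' primary nodule is the
    malignant one, all other nodules are benign.
    """

    n_participants: int = 613
    cancer_prevalence: float = 64.0 / 613.0
    seed: int = 0
    malignant: GroupParams = MALIGNANT_DEFAULTS
    benign: GroupParams = BENIGN_DEFAULTS
    extra_nodules_lambda_cancer: float = 0.3
    extra_nodules_lambda_benign: float = 0.5
    max_extra_nodules: int = 5
    min_diameter_mm: float = 1.2
    #: perpendicular/longest axial ratio: lo + (hi-lo) * Beta(a, b)
    axial_ratio_range: tuple[float, float] = (0.6, 1.0)
    axial_ratio_beta: tuple[float, float] = (6.0, 2.0)
    #: mean3d / meanAxial compactness: lo + (hi-lo) * Beta(a, b),
    #: then capped so mean3d never exceeds the longest diameter
    compactness_range: tuple[float, float] = (0.70, 1.05)
    compactness_beta: tuple[float, float] = (2.0, 2.0)
    #: solid-component fraction of part-solid nodules, uniform range
    solid_fraction_range: tuple[float, float] = (0.3, 0.9)
    age_clip: tuple[float, float] = (45.0, 80.0)

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if not 0.0 <= self.cancer_prevalence <= 1.0:
            raise ConfigError("cancer_prevalence must be in [0, 1]")
        for name, group in (("malignant", self.malignant), ("benign", self.benign)):
            probs = group.type_probs
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ConfigError(f"{name}.type_probs must be 3 nonnegative values")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(
                    f"{name}.type_probs must sum to 1, got {sum(probs)}"
                )
            p_solid, _, p_ggn = probs
            for pname in (
                "spiculation_p",
                "calcified_p",
                "pfn_p",
                "upper_lobe_p",
                "sex_female_p",
                "family_history_p",
                "emphysema_p",
            ):
                p = getattr(group, pname)
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}.{pname} must be in [0, 1]")
            if group.spiculation_p > 0 and (1.0 - p_ggn) <= 0:
                raise ConfigError(f"{name}: spiculation with no non-GGN nodules")
            if group.spiculation_p > (1.0 - p_ggn) + 1e-12:
                raise ConfigError(
                    f"{name}.spiculation_p exceeds the non-GGN fraction"
                )
            if group.calcified_p > 0 and p_solid <= 0:
                raise ConfigError(f"{name}: calcification with no solid nodules")
            if p_solid > 0 and group.calcified_p / p_solid > 1 + 1e-12:
                raise ConfigError(f"{name}.calcified_p exceeds the solid fraction")
            solid_uncalc = p_solid - group.calcified_p
            if group.pfn_p > 0 and solid_uncalc <= 0:
                raise ConfigError(f"{name}: PFN with no uncalcified solid nodules")
            if solid_uncalc > 0 and group.pfn_p / solid_uncalc > 1 + 1e-12:
                raise ConfigError(
                    f"{name}.pfn_p exceeds the uncalcified solid fraction"
                )


_TYPES = (NoduleType.SOLID, NoduleType.PART_SOLID, NoduleType.GROUND_GLASS)


def _draw_nodule(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    group: GroupParams,
    nodule_id: str,
    participant_id: str,
    malignant: bool,
) -> NoduleRecord:
    d_longest = float(
        np.exp(rng.normal(math.log(group.size_median_mm), group.size_log_sigma))
    )
    d_longest = max(d_longest, cfg.min_diameter_mm)
    lo, hi = cfg.axial_ratio_range
    a, b = cfg.axial_ratio_beta
    ratio = lo + (hi - lo) * float(rng.beta(a, b))
    d_perp = ratio * d_longest
    d_mean_axial = 0.5 * (d_longest + d_perp)
    lo, hi = cfg.compactness_range
    a, b = cfg.compactness_beta
    compact = lo + (hi - lo) * float(rng.beta(a, b))
    d_mean3d = min(compact * d_mean_axial, d_longest)

    ntype = _TYPES[rng.choice(3, p=np.asarray(group.type_probs))]
    p_solid, _, p_ggn = group.type_probs

    calcified = False
    pfn = False
    spiculated = False
    if ntype is NoduleType.SOLID:
        p_calc = group.calcified_p / p_solid if p_solid > 0 else 0.0
        calcified = bool(rng.random() < p_calc)
        if not calcified:
            solid_uncalc = p_solid - group.calcified_p
            p_pfn = group.pfn_p / solid_uncalc if solid_uncalc > 0 else 0.0
            pfn = bool(rng.random() < p_pfn)
    if ntype is not NoduleType.GROUND_GLASS:
        p_spic = group.spiculation_p / (1.0 - p_ggn) if p_ggn < 1 else 0.0
        spiculated = bool(rng.random() < p_spic)

    solid_sizes = {}
    if ntype is NoduleType.PART_SOLID:
        lo, hi = cfg.solid_fraction_range
        frac = float(rng.uniform(lo, hi))
        solid_sizes = {
            "d_longest_axial_solid": frac * d_longest,
            "d_perp_axial_solid": frac * d_perp,
            "d_mean3d_solid": frac * d_mean3d,
        }

    return NoduleRecord(
        nodule_id=nodule_id,
        participant_id=participant_id,
        type=ntype,
        is_pfn=pfn,
        calcification=Calcification.BENIGN_PATTERN if calcified else Calcification.NONE,
        spiculated=spiculated,
        upper_lobe=bool(rng.random() < group.upper_lobe_p),
        d_longest_axial=d_longest,
        d_perp_axial=d_perp,
        volume=math.pi / 6.0 * d_mean3d**3,
        d_mean3d=d_mean3d,
        malignant=malignant,
        **solid_sizes,
    )


def generate(config: Optional[GeneratorConfig] = None) -> Cohort:
    """Draw one seed-deterministic synthetic cohort.

    Cancer status is assigned per participant first; each cancer
    participant's primary nodule is drawn from the malignant
    distributions and every other nodule from the benign ones, so the
    malignant label structure matches a screening case-control design.
    """
    cfg = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    participants = []
    nodules = []
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:05d}"
        has_cancer = bool(rng.random() < cfg.cancer_prevalence)
        group = cfg.malignant if has_cancer else cfg.benign
        lam = (
            cfg.extra_nodules_lambda_cancer
            if has_cancer
            else cfg.extra_nodules_lambda_benign
        )
        n_extra = int(min(rng.poisson(lam), cfg.max_extra_nodules))
        age = float(
            np.clip(rng.normal(group.age_mean, group.age_sd), *cfg.age_clip)
        )
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                age=age,
                sex=Sex.FEMALE if rng.random() < group.sex_female_p else Sex.MALE,
                family_history_lung_cancer=bool(
                    rng.random() < group.family_history_p
                ),
                emphysema=bool(rng.random() < group.emphysema_p),
                nodule_count_additional=n_extra,
                has_cancer=has_cancer,
            )
        )
        nodules.append(
            _draw_nodule(
                rng, cfg, group, f"{pid}-N1", pid, malignant=has_cancer
            )
        )
        for k in range(n_extra):
            nodules.append(
                _draw_nodule(
                    rng,
                    cfg,
                    cfg.benign,
                    f"{pid}-N{k + 2}",
                    pid,
                    malignant=False,
                )
            )
    return build_cohort(participants, nodules)
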