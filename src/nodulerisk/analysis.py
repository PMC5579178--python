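"""Participant-level comparison of the scoring systems.

Pipeline: per participant and system, pick the *risk-dominant* nodule
(the one with the highest risk index or category for that system, ties
broken at random from a seeded generator); label each participant by
cancer status; build ROC curves over the dominant-nodule scores; and
compare AUCs pairwise with the DeLong test for correlated ROC curves,
Bonferroni-corrected across the three system pairs.

The participant label is always ``has_cancer`` — a cancer participant
whose dominant pick happens to be a benign nodule still counts as a
positive, carrying that benign nodule's score.  This mirrors a clinical
per-person reading of a scan rather than a per-nodule evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Cohort, NoduleType, Calcification, Sex
from .scoring import (
    PUBLISHED_DEFN,
    PanCanCoefficients,
    System,
    score_all,
)
from .sizes import Component, SizeDefinition, nodule_size


@dataclass(frozen=True)
class DominantSelection:
    """Risk-dominant nodule per participant for one system/definition."""

    system: System
    defn: SizeDefinition
    selection: dict  # participant_id -> nodule_id
    rng_seed: int


@dataclass(frozen=True)
class RocResult:
    """ROC curve and area for one system under one size definition.

    ``auc`` is the midrank (Mann-Whitney) estimate with ties counted
    one half, identical to the trapezoidal area under ``curve_points``.
    ``operating_points`` are the (FPR, TPR) pairs reached by thresholding
    at each category boundary of a categorical system, or at the
    published risk cutpoints for the PanCan model.
    """

    system: System
    defn_label: str
    auc: float
    n_pos: int
    n_neg: int
    curve_points: tuple  # ((fpr, tpr), ...)
    operating_points: tuple = ()


@dataclass(frozen=True)
class PairwiseTest:
    """One paired DeLong comparison."""

    stratum: str  # the table row (size definition) or system it belongs to
    label_a: str
    label_b: str
    auc_a: float
    auc_b: float
    z: float
    p_two_sided: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    """AUC matrix plus pairwise DeLong tests.

    ``rocs`` maps (row_label, system) to a :class:`RocResult`; rows are
    "as_published" plus one per uniformly applied size definition.
    ``pairwise_systems`` holds the between-system tests within each row
    and ``pairwise_definitions`` the between-definition tests within
    each system.  ``significance_threshold`` is the Bonferroni-corrected
    alpha used for the ``significant`` flags.
    """

    rocs: dict
    pairwise_systems: tuple
    pairwise_definitions: tuple
    alpha_family: float
    n_comparisons: int

    @property
    def significance_threshold(self) -> float:
        return self.alpha_family / self.n_comparisons


def select_dominant(
    cohort: Cohort,
    scores: pd.DataFrame,
    system: System,
    defn: SizeDefinition,
    seed: int,
) -> DominantSelection:
    """Pick each participant's risk-dominant nodule for one system.

    ``scores`` is a :func:`~nodulerisk.scoring.score_all` table covering
    every nodule of the cohort.  Among a participant's nodules the one
    with the maximal rank wins; exact ties are broken by a uniform draw
    from ``numpy.random.default_rng(seed)``, so the selection is
    reproducible.  Participants without nodules are excluded.
    """
    rank_by_nodule = dict(zip(scores["nodule_id"], scores["rank"]))
    missing = [
        n.nodule_id for n in cohort.nodules
        if n.nodule_id not in rank_by_nodule
    ]
    if missing:
        raise ValueError(
            "scores table does not cover nodule(s): " + ", ".join(missing)
        )
    by_participant: dict[str, list] = {}
    for n in cohort.nodules:
        by_participant.setdefault(n.participant_id, []).append(n.nodule_id)
    rng = np.random.default_rng(seed)
    selection: dict[str, str] = {}
    # iterate participants in cohort order for deterministic rng consumption
    for p in cohort.participants:
        nodule_ids = by_participant.get(p.participant_id)
        if not nodule_ids:
            continue
        ranks = np.array([rank_by_nodule[nid] for nid in nodule_ids])
        best = np.flatnonzero(ranks == ranks.max())
        pick = best[rng.integers(len(best))] if len(best) > 1 else best[0]
        selection[p.participant_id] = nodule_ids[pick]
    return DominantSelection(system, defn, selection, seed)


def _midrank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    m = int(labels.sum())
    n = len(labels) - m
    return (ranks[labels].sum() - m * (m + 1) / 2.0) / (m * n)


def roc(
    labels: Sequence[bool],
    scores: Sequence[float],
    system: Optional[System] = None,
    defn_label: str = "",
    category_cutoffs: Optional[Sequence[float]] = None,
) -> RocResult:
    """ROC curve and midrank AUC for participant labels and scores.

    The curve runs over every distinct score threshold from (0, 0) to
    (1, 1); tied scores produce diagonal segments whose trapezoidal
    area equals the half-credit the Mann-Whitney statistic gives ties.
    ``category_cutoffs`` (score thresholds, "positive if score >= c")
    yield the reported operating points.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D")
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise ValueError(
            "ROC needs at least one positive and one negative participant"
        )
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    tpr = np.concatenate([[0.0], tp[distinct] / m])
    fpr = np.concatenate([[0.0], fp[distinct] / n])
    curve = tuple(zip(fpr.tolist(), tpr.tolist()))
    auc = _midrank_auc(y, s)
    operating = ()
    if category_cutoffs is not None:
        ops = []
        for c in category_cutoffs:
            pos = s >= c
            ops.append(
                (
                    float((pos & ~y).sum()) / n,
                    float((pos & y).sum()) / m,
                )
            )
        operating = tuple(ops)
    return RocResult(
        system=system,
        defn_label=defn_label,
        auc=float(auc),
        n_pos=m,
        n_neg=n,
        curve_points=curve,
        operating_points=operating,
    )


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    x = scores[labels]
    y = scores[~labels]
    m, n = len(x), len(y)
    tz = stats.rankdata(np.concatenate([x, y]))
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return auc, v10, v01


def delong_test(
    labels: Sequence[bool],
    scores_a: Sequence[float],
    scores_b: Sequence[float],
) -> tuple[float, float, float, float]:
    """Paired DeLong test for two correlated ROC curves.

    Both score vectors must refer to the same participants in the same
    order.  Returns ``(auc_a, auc_b, z, p_two_sided)`` where z is the
    AUC difference over the DeLong standard error (midranks for ties)
    and p the two-sided normal tail probability.  If the variance of
    the difference is zero the AUCs must be equal and p is 1.
    """
    y = np.asarray(labels, dtype=bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("labels, scores_a, scores_b must be equal-length")
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise ValueError("need at least one positive and one negative")
    auc_a, v10_a, v01_a = _delong_components(y, a)
    auc_b, v10_b, v01_b = _delong_components(y, b)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >=2 positives and negatives")
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) > 1e-12:
            raise FloatingPointError(
                "zero DeLong variance with unequal AUCs "
                f"({auc_a:.6f} vs {auc_b:.6f})"
            )
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def _pancan_cutoffs() -> list[float]:
    # published risk-category boundaries, percent
    return [1.5, 6.0, 30.0]


def _category_cutoffs(system: System) -> list[float]:
    if system is System.PANCAN:
        return _pancan_cutoffs()
    if system is System.LUNG_RADS:
        return [2.0, 3.0, 4.0, 5.0]
    return [2.0, 3.0, 4.0, 5.0, 6.0]


def participant_scores(
    cohort: Cohort,
    scores: pd.DataFrame,
    selection: DominantSelection,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Labels and dominant-nodule ranks aligned over participants.

    Participants are ordered by id so vectors from different systems
    are paired; returns (labels, ranks, participant_ids).
    """
    rank_by_nodule = dict(zip(scores["nodule_id"], scores["rank"]))
    pids = sorted(selection.selection)
    labels = np.array(
        [cohort.participant(pid).has_cancer for pid in pids], dtype=bool
    )
    values = np.array(
        [rank_by_nodule[selection.selection[pid]] for pid in pids]
    )
    return labels, values, pids


def compare_systems(
    cohort: Cohort,
    coeffs: Optional[PanCanCoefficients] = None,
    defns: Sequence[SizeDefinition] = (
        SizeDefinition.LONGEST_C,
        SizeDefinition.MEAN_3D,
        SizeDefinition.MEAN_AXIAL,
    ),
    alpha_family: float = 0.05,
    n_comparisons: int = 3,
    seed: int = 0,
) -> ComparisonResult:
    """Full between-system and between-definition AUC comparison.

    Builds an "as_published" row (PanCan with LONGEST_C, Lung-RADS with
    MEAN_3D, NCCN with MEAN_AXIAL) plus one row per uniformly applied
    size definition; within every row the three system pairs are tested
    with the paired DeLong method, and within every system the size
    definitions are compared likewise.  ``significant`` flags use the
    Bonferroni threshold alpha_family / n_comparisons.
    """
    if coeffs is None:
        coeffs = PanCanCoefficients.default()
    systems = [System.PANCAN, System.LUNG_RADS, System.NCCN]
    rows: list[tuple[str, dict]] = [
        ("as_published", {sys_: PUBLISHED_DEFN[sys_] for sys_ in systems})
    ]
    for d in defns:
        rows.append((d.value, {sys_: d for sys_ in systems}))

    seed_seq = np.random.SeedSequence(seed)
    child_seeds = iter(
        int(s.generate_state(1)[0] % (2**31))
        for s in seed_seq.spawn(len(rows) * len(systems))
    )

    score_cache: dict[tuple, pd.DataFrame] = {}

    def scores_for(sys_: System, d: SizeDefinition) -> pd.DataFrame:
        key = (sys_, d)
        if key not in score_cache:
            score_cache[key] = score_all(cohort, sys_, d, coeffs)
        return score_cache[key]

    threshold = alpha_family / n_comparisons
    rocs: dict = {}
    vectors: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for row_label, defn_map in rows:
        for sys_ in systems:
            d = defn_map[sys_]
            table = scores_for(sys_, d)
            sel = select_dominant(cohort, table, sys_, d, next(child_seeds))
            labels, values, _ = participant_scores(cohort, table, sel)
            vectors[(row_label, sys_)] = (labels, values)
            rocs[(row_label, sys_)] = roc(
                labels,
                values,
                system=sys_,
                defn_label=row_label,
                category_cutoffs=_category_cutoffs(sys_),
            )

    pairwise_systems = []
    pairs = [
        (System.PANCAN, System.LUNG_RADS),
        (System.PANCAN, System.NCCN),
        (System.LUNG_RADS, System.NCCN),
    ]
    for row_label, _ in rows:
        for sa, sb in pairs:
            la, va = vectors[(row_label, sa)]
            lb, vb = vectors[(row_label, sb)]
            assert np.array_equal(la, lb)
            auc_a, auc_b, z, p = delong_test(la, va, vb)
            pairwise_systems.append(
                PairwiseTest(
                    stratum=row_label,
                    label_a=sa.value,
                    label_b=sb.value,
                    auc_a=auc_a,
                    auc_b=auc_b,
                    z=z,
                    p_two_sided=p,
                    significant=p < threshold,
                )
            )

    pairwise_definitions = []
    defn_pairs = [
        (defns[i], defns[j])
        for i in range(len(defns))
        for j in range(i + 1, len(defns))
    ]
    for sys_ in systems:
        for da, db in defn_pairs:
            la, va = vectors[(da.value, sys_)]
            lb, vb = vectors[(db.value, sys_)]
            assert np.array_equal(la, lb)
            auc_a, auc_b, z, p = delong_test(la, va, vb)
            pairwise_definitions.append(
                PairwiseTest(
                    stratum=sys_.value,
                    label_a=da.value,
                    label_b=db.value,
                    auc_a=auc_a,
                    auc_b=auc_b,
                    z=z,
                    p_two_sided=p,
                    significant=p < threshold,
                )
            )

    return ComparisonResult(
        rocs=rocs,
        pairwise_systems=tuple(pairwise_systems),
        pairwise_definitions=tuple(pairwise_definitions),
        alpha_family=alpha_family,
        n_comparisons=n_comparisons,
    )


def _chi2_p(table: np.ndarray) -> float:
    # Pearson chi-square without Yates continuity correction
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _summ_cont(x: np.ndarray) -> str:
    return (
        f"median {np.median(x):.1f}, mean {np.mean(x):.1f} "
        f"({np.min(x):.1f}-{np.max(x):.1f})"
    )


def _summ_count(k: int, total: int) -> str:
    pct = 100.0 * k / total if total else 0.0
    return f"{k} ({pct:.0f}%)"


def demographics_table(cohort: Cohort, selections: Sequence[DominantSelection]) -> pd.DataFrame:
    """Cancer-vs-benign characteristics of the risk-dominant nodules.

    The table is built on the union of the risk-dominant nodules over
    all given selections (a participant can contribute up to one nodule
    per system).  Continuous rows are compared with Welch's unequal-
    variance t-test, categorical rows with Pearson's chi-square without
    continuity correction.
    """
    union_ids: set[str] = set()
    for sel in selections:
        union_ids.update(sel.selection.values())
    if not union_ids:
        raise ValueError("no dominant selections given")
    nodules = [n for n in cohort.nodules if n.nodule_id in union_ids]
    participants = {p.participant_id: p for p in cohort.participants}
    mal = [n for n in nodules if n.malignant]
    ben = [n for n in nodules if not n.malignant]
    if not mal or not ben:
        raise ValueError("both a malignant and a benign group are required")

    rows = []

    def add_cont(name, extract):
        a = np.array([extract(n) for n in mal], dtype=float)
        b = np.array([extract(n) for n in ben], dtype=float)
        rows.append(
            {
                "parameter": name,
                "cancers": _summ_cont(a),
                "benign": _summ_cont(b),
                "total": _summ_cont(np.concatenate([a, b])),
                "p_value": _welch_p(a, b),
            }
        )

    def add_binary(name, pred):
        ka = sum(pred(n) for n in mal)
        kb = sum(pred(n) for n in ben)
        table = np.array(
            [[ka, len(mal) - ka], [kb, len(ben) - kb]], dtype=float
        )
        p = _chi2_p(table) if table.sum(axis=0).all() else 1.0
        rows.append(
            {
                "parameter": name,
                "cancers": _summ_count(ka, len(mal)),
                "benign": _summ_count(kb, len(ben)),
                "total": _summ_count(ka + kb, len(nodules)),
                "p_value": p,
            }
        )

    rows.append(
        {
            "parameter": "number of nodules",
            "cancers": str(len(mal)),
            "benign": str(len(ben)),
            "total": str(len(nodules)),
            "p_value": np.nan,
        }
    )

    part_of = lambda n: participants[n.participant_id]
    add_cont("age (years)", lambda n: part_of(n).age)
    add_binary("sex: female", lambda n: part_of(n).sex is Sex.FEMALE)
    add_binary(
        "family history of lung cancer",
        lambda n: part_of(n).family_history_lung_cancer,
    )
    add_binary("emphysema", lambda n: part_of(n).emphysema)
    add_cont(
        "size: longest axial (mm)",
        lambda n: nodule_size(n, SizeDefinition.LONGEST_C),
    )
    add_cont(
        "size: volumetric mean (mm)",
        lambda n: nodule_size(n, SizeDefinition.MEAN_3D),
    )
    add_cont(
        "size: mean axial (mm)",
        lambda n: nodule_size(n, SizeDefinition.MEAN_AXIAL),
    )

    # nodule type: 3 x 2 contingency
    type_counts = {
        g: [
            sum(n.type is t for n in grp)
            for t in (
                NoduleType.SOLID,
                NoduleType.PART_SOLID,
                NoduleType.GROUND_GLASS,
            )
        ]
        for g, grp in (("mal", mal), ("ben", ben))
    }
    table = np.array([type_counts["mal"], type_counts["ben"]], dtype=float)
    nonzero = table.sum(axis=0) > 0
    p_type = _chi2_p(table[:, nonzero]) if nonzero.sum() > 1 else 1.0
    fmt_counts = lambda c, tot: "/".join(
        _summ_count(k, tot) for k in c
    )
    rows.append(
        {
            "parameter": "type solid/part-solid/non-solid",
            "cancers": fmt_counts(type_counts["mal"], len(mal)),
            "benign": fmt_counts(type_counts["ben"], len(ben)),
            "total": fmt_counts(
                [a + b for a, b in zip(*type_counts.values())], len(nodules)
            ),
            "p_value": p_type,
        }
    )

    add_binary("perifissural", lambda n: n.is_pfn)
    add_binary(
        "calcified (benign pattern)",
        lambda n: n.calcification is Calcification.BENIGN_PATTERN,
    )
    add_cont(
        "additional nodule count",
        lambda n: part_of(n).nodule_count_additional,
    )
    add_binary("upper lobe", lambda n: n.upper_lobe)
    add_binary("spiculation", lambda n: n.spiculated)

    return pd.DataFrame(
        rows, columns=["parameter", "cancers", "benign", "total", "p_value"]
    )
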