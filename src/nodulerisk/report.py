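"""Rendering of comparison results: CSV/Markdown tables and ROC plots."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .analysis import ComparisonResult
from .scoring import System

_SYSTEM_NAMES = {
    System.PANCAN: "PanCan",
    System.LUNG_RADS: "Lung-RADS",
    System.NCCN: "NCCN",
}


def auc_table(result: ComparisonResult) -> pd.DataFrame:
    """AUC per row (size definition) and system, plus pairwise p-values."""
    rows = []
    row_labels = sorted({k[0] for k in result.rocs}, key=_row_order)
    by_pair = {
        (t.stratum, t.label_a, t.label_b): t for t in result.pairwise_systems
    }
    for row_label in row_labels:
        entry = {"size_definition": row_label}
        for sys_ in (System.PANCAN, System.LUNG_RADS, System.NCCN):
            entry[f"auc_{sys_.value}"] = result.rocs[(row_label, sys_)].auc
        for sa, sb, col in (
            (System.PANCAN, System.LUNG_RADS, "p_pancan_vs_lung_rads"),
            (System.PANCAN, System.NCCN, "p_pancan_vs_nccn"),
            (System.LUNG_RADS, System.NCCN, "p_lung_rads_vs_nccn"),
        ):
            t = by_pair[(row_label, sa.value, sb.value)]
            entry[col] = t.p_two_sided
        rows.append(entry)
    return pd.DataFrame(rows)


def defn_table(result: ComparisonResult) -> pd.DataFrame:
    """Per-system comparison between size definitions."""
    rows = [
        {
            "system": t.stratum,
            "defn_a": t.label_a,
            "defn_b": t.label_b,
            "auc_a": t.auc_a,
            "auc_b": t.auc_b,
            "z": t.z,
            "p_two_sided": t.p_two_sided,
            "significant": t.significant,
        }
        for t in result.pairwise_definitions
    ]
    return pd.DataFrame(rows)


def _row_order(label: str) -> tuple:
    order = ["as_published", "longest_c", "mean_3d", "mean_axial"]
    return (order.index(label) if label in order else len(order), label)


def _md_table(df: pd.DataFrame) -> str:
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.3f}"
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = [
        "| " + " | ".join(fmt(v) for v in row) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body])


def render_markdown(result: ComparisonResult) -> str:
    """Markdown report with the AUC matrix and both pairwise tables."""
    lines = ["# Scoring-system comparison", ""]
    lines.append(
        f"Bonferroni-corrected significance threshold: "
        f"{result.alpha_family} / {result.n_comparisons} = "
        f"{result.significance_threshold:.4f}"
    )
    lines.append("")
    lines.append("## AUC per system and size definition")
    lines.append("")
    lines.append(_md_table(auc_table(result)))
    lines.append("")
    lines.append("## Size-definition comparisons within each system")
    lines.append("")
    lines.append(_md_table(defn_table(result)))
    lines.append("")
    return "\n".join(lines)


def plot_roc(
    result: ComparisonResult,
    path: Union[str, Path],
    row_label: str = "as_published",
) -> None:
    """ROC curves with category operating points for one table row.

    The PanCan model is drawn as a continuous curve with its published
    risk-cutpoint operating points; the categorical systems appear as
    their category operating points joined by line segments.
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    for sys_, color in (
        (System.PANCAN, "tab:blue"),
        (System.LUNG_RADS, "tab:orange"),
        (System.NCCN, "tab:green"),
    ):
        rr = result.rocs[(row_label, sys_)]
        fpr = [p[0] for p in rr.curve_points]
        tpr = [p[1] for p in rr.curve_points]
        ax.plot(
            fpr, tpr, color=color,
            label=f"{_SYSTEM_NAMES[sys_]} (AUC {rr.auc:.3f})",
        )
        if rr.operating_points:
            ax.plot(
                [p[0] for p in rr.operating_points],
                [p[1] for p in rr.operating_points],
                "o", color=color, markersize=5,
            )
    ax.plot([0, 1], [0, 1], "k:", linewidth=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title(f"Participant-level ROC ({row_label})")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
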