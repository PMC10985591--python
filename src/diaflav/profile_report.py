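"""Summary analytics and figures: flavone:flavonol ratio, backbone
distributions, sample-correlation heatmap and database-overlap Venn counts.

The flavone:flavonol ratio is a simple chemophenetic index — the count of
flavone-backbone hits divided by flavonol-backbone hits — used to compare
species' flavonoid profiles.  Figures are optional; every operation returns
the underlying numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .featdet import AlignedTable

__all__ = [
    "flavone_flavonol_ratio",
    "correlation_matrix",
    "correlation_heatmap",
    "venn_counts",
    "venn_figure",
    "backbone_stack",
    "ProfileSummary",
]

FIG_DPI = 500


def flavone_flavonol_ratio(flavone_hits: int, flavonol_hits: int) -> float:
    """Flavone-to-flavonol hit ratio, reported to 2 decimals."""
    if flavone_hits < 0 or flavonol_hits < 0:
        raise ValueError("hit counts must be non-negative")
    if flavonol_hits == 0:
        raise ValueError("flavone:flavonol ratio undefined: zero flavonol hits")
    return round(flavone_hits / flavonol_hits, 2)


def correlation_matrix(
    table: AlignedTable, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise sample correlation of log10(1 + intensity) feature profiles.

    Samples with constant profiles (undefined correlation) are excluded.
    """
    mat = table.intensity_matrix()
    if mat.shape[1] < 2:
        raise ValueError("correlation needs at least 2 samples")
    constant = [c for c in mat.columns if mat[c].nunique() <= 1]
    logged = np.log10(1.0 + mat).drop(columns=constant)
    if logged.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant samples")
    corr = logged.corr(method=method)
    if constant:
        corr.attrs["excluded_constant_samples"] = constant
    return corr


def correlation_heatmap(
    table: AlignedTable,
    path=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation matrix plus an optional rendered heatmap PNG."""
    corr = correlation_matrix(table, method=method)
    if path is not None:
        import seaborn as sns

        fig, ax = plt.subplots(figsize=(5, 4))
        sns.heatmap(corr, annot=True, fmt=".2f", vmin=-1, vmax=1,
                    cmap="vlag", ax=ax)
        ax.set_title("Feature-profile correlation")
        fig.tight_layout()
        fig.savefig(path, dpi=FIG_DPI)
        plt.close(fig)
    return corr


def venn_counts(
    hits_a: Iterable[float], hits_b: Iterable[float], decimals: int = 4
) -> Tuple[int, int, int]:
    """Unique/shared partition of two m/z hit sets: (only A, only B, shared).

    Membership is by consensus m/z rounded to ``decimals``.
    """
    a = {round(float(x), decimals) for x in hits_a}
    b = {round(float(x), decimals) for x in hits_b}
    shared = a & b
    return len(a - b), len(b - a), len(shared)


def venn_figure(
    hits_a: Iterable[float],
    hits_b: Iterable[float],
    labels: Tuple[str, str] = ("A", "B"),
    path=None,
) -> Tuple[int, int, int]:
    """Two-set Venn diagram drawn with plain matplotlib circles."""
    only_a, only_b, shared = venn_counts(hits_a, hits_b)
    if path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cx, color in ((-0.5, "tab:blue"), (0.5, "tab:orange")):
            ax.add_patch(plt.Circle((cx, 0), 1.0, alpha=0.4, color=color))
        ax.text(-1.0, 0, str(only_a), ha="center", fontsize=14)
        ax.text(1.0, 0, str(only_b), ha="center", fontsize=14)
        ax.text(0, 0, str(shared), ha="center", fontsize=14)
        ax.text(-1.0, 1.15, labels[0], ha="center")
        ax.text(1.0, 1.15, labels[1], ha="center")
        ax.set_xlim(-2, 2)
        ax.set_ylim(-1.5, 1.6)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.savefig(path, dpi=FIG_DPI)
        plt.close(fig)
    return only_a, only_b, shared


@dataclass
class ProfileSummary:
    """Aggregated profiling results for a cohort."""

    class_counts: pd.DataFrame  # samples x (aglycone, class)
    ratio_per_sample: Dict[str, Optional[float]]
    ratio_overall: Optional[float]

    @classmethod
    def from_class_counts(cls, counts: pd.DataFrame) -> "ProfileSummary":
        per_sample: Dict[str, Optional[float]] = {}
        tot_fl, tot_ol = 0, 0
        for sid, row in counts.iterrows():
            classes = row.index.get_level_values("class")
            flavone = int(row[classes == "flavone"].sum())
            flavonol = int(row[classes == "flavonol"].sum())
            tot_fl += flavone
            tot_ol += flavonol
            per_sample[sid] = (
                flavone_flavonol_ratio(flavone, flavonol) if flavonol else None
            )
        overall = flavone_flavonol_ratio(tot_fl, tot_ol) if tot_ol else None
        return cls(counts, per_sample, overall)


def backbone_stack(
    class_counts: pd.DataFrame,
    path=None,
) -> pd.DataFrame:
    """Per-sample stacked counts by flavonoid class (plus aglycone detail).

    Returns the tidy frame backing the stacked-bar figure; writes the figure
    when ``path`` is given.  Bars sum to the per-sample totals.
    """
    if class_counts.empty:
        return pd.DataFrame(columns=["sample", "class", "aglycone", "count"])
    tidy = (
        class_counts.stack(["aglycone", "class"], future_stack=True)
        .rename("count")
        .reset_index()
        .rename(columns={"level_0": "sample"})
    )
    tidy = tidy[tidy["count"] > 0].reset_index(drop=True)
    if path is not None:
        by_class = class_counts.T.groupby(level="class").sum().T
        ax = by_class.plot(kind="bar", stacked=True, figsize=(6, 4))
        ax.set_ylabel("aglycone hits")
        ax.set_title("Flavonoid backbone distribution")
        fig = ax.get_figure()
        fig.tight_layout()
        fig.savefig(path, dpi=FIG_DPI)
        plt.close(fig)
    return tidy
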