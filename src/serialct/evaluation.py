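"""Landmark-based registration accuracy and its summary statistics.

Accuracy protocol: landmarks are placed on proximal and distal vessel
bifurcations at the first time point (the study layout is 20 per right
lung, 18 per left, four of them in the left S1+2 segment), transferred
through each candidate transformation, and the 3D Euclidean distance to
the true time-2 position is the registration error. Distances are pooled
within stratum (proximal / distal / average) and compared across
registration methods with one-way ANOVA followed by post hoc pairwise
comparisons (Tukey HSD by default, Bonferroni-corrected t-tests as an
option) at the 0.05 significance level.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .volume import LandmarkSet

__all__ = [
    "RIGHT_LUNG_LANDMARKS",
    "LEFT_LUNG_LANDMARKS",
    "LEFT_S12_LANDMARKS",
    "landmark_displacement",
    "summarize",
    "format_summary",
    "AnovaResult",
    "anova_posthoc",
]

# study landmark layout, recorded as defaults for protocol builders
RIGHT_LUNG_LANDMARKS = 20
LEFT_LUNG_LANDMARKS = 18
LEFT_S12_LANDMARKS = 4


def landmark_displacement(reference: LandmarkSet, transferred: LandmarkSet) -> pd.DataFrame:
    """Per-landmark 3D Euclidean distance (mm), paired strictly by label.

    Returns a DataFrame with columns label, side, depth, distance_mm.
    Raises on any label mismatch, listing the unmatched labels.
    """
    ref = {p.label: p for p in reference}
    tra = {p.label: p for p in transferred}
    only_ref = sorted(set(ref) - set(tra))
    only_tra = sorted(set(tra) - set(ref))
    if only_ref or only_tra:
        raise ValueError(
            f"landmark label mismatch: only in reference {only_ref}, "
            f"only in transferred {only_tra}"
        )
    rows = []
    for label in reference.labels:
        a, b = ref[label], tra[label]
        d = float(np.linalg.norm(np.asarray(a.xyz) - np.asarray(b.xyz)))
        rows.append({"label": label, "side": a.side, "depth": a.depth, "distance_mm": d})
    return pd.DataFrame(rows)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty group")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def summarize(groups: Mapping[str, "pd.DataFrame | Sequence[float]"]) -> pd.DataFrame:
    """Mean ± sample SD (n−1 denominator) per method per stratum.

    Each group is either a DataFrame from :func:`landmark_displacement`
    (strata proximal/distal taken from the metadata, plus the pooled
    ``average`` row) or a plain sequence of numbers (``average`` row only).
    Output: rows = strata, MultiIndex columns = (method, mean/sd/n).
    """
    if not groups:
        raise ValueError("no groups to summarize")
    blocks: dict[str, pd.Series] = {}
    strata_order: list[str] = []
    for method, data in groups.items():
        cells: dict[tuple[str, str], float] = {}
        if isinstance(data, pd.DataFrame):
            for depth, sub in data.groupby("depth", sort=False):
                m, s = _mean_sd(sub["distance_mm"].to_numpy())
                cells[(depth, "mean")], cells[(depth, "sd")] = m, s
                cells[(depth, "n")] = float(len(sub))
                if depth not in strata_order:
                    strata_order.append(depth)
            values = data["distance_mm"].to_numpy()
        else:
            values = np.asarray(list(data), dtype=float)
        m, s = _mean_sd(values)
        cells[("average", "mean")], cells[("average", "sd")] = m, s
        cells[("average", "n")] = float(values.size)
        blocks[method] = pd.Series(cells)
    if "average" not in strata_order:
        strata_order.append("average")
    # canonical stratum order: proximal, distal, then average
    order = [s for s in ("proximal", "distal") if s in strata_order] + ["average"]
    table = pd.DataFrame(blocks)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["stratum", "stat"])
    table = table.T  # methods as rows of (stratum, stat) columns
    cols = [(s, stat) for s in order for stat in ("mean", "sd", "n")
            if (s, stat) in table.columns]
    return table[cols]


def format_summary(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Render a summarize() table as 'mean±sd' strings (printed precision)."""
    strata = sorted({s for s, _ in table.columns}, key=lambda s: s == "average")
    out = {}
    for s in strata:
        out[s] = [
            f"{m:.{decimals}f}±{sd:.{decimals}f}"
            for m, sd in zip(table[(s, "mean")], table[(s, "sd")])
        ]
    return pd.DataFrame(out, index=table.index)


@dataclasses.dataclass
class AnovaResult:
    """One-way ANOVA with post hoc pairwise comparisons."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_adj, significant
    method: str
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F = {self.f_statistic:.4g}, p = {self.p_value:.4g}",
            f"Post hoc ({self.method}, alpha = {self.alpha}):",
        ]
        for r in self.pairwise.itertuples():
            star = "*" if r.significant else " "
            lines.append(f"  {r.group1} vs {r.group2}: p = {r.p_adj:.4g} {star}")
        return "\n".join(lines)


def anova_posthoc(groups: Mapping[str, Sequence[float]], posthoc: str = "tukey",
                  alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA over ≥2 groups followed by post hoc pairwise tests.

    Degenerate input (every value identical across all groups) returns
    F = 0, p = 1 rather than raising.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(list(groups[n]), dtype=float) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    allvals = np.concatenate(arrays)
    if np.ptp(allvals) == 0.0:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        pairwise = pd.DataFrame(
            [{"group1": a, "group2": b, "p_adj": 1.0, "significant": False}
             for a, b in pairs]
        )
        return AnovaResult(0.0, 1.0, pairwise, posthoc, alpha)
    f, p = stats.f_oneway(*arrays)
    if posthoc == "tukey":
        labels = np.concatenate([[n] * a.size for n, a in zip(names, arrays)])
        res = pairwise_tukeyhsd(allvals, labels, alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        pairwise = pd.DataFrame({
            "group1": frame["group1"],
            "group2": frame["group2"],
            "p_adj": frame["p-adj"].astype(float),
            "significant": frame["reject"].astype(bool),
        })
    elif posthoc == "bonferroni":
        rows = []
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        for a, b in pairs:
            _, pr = stats.ttest_ind(np.asarray(list(groups[a]), dtype=float),
                                    np.asarray(list(groups[b]), dtype=float))
            padj = min(float(pr) * len(pairs), 1.0)
            rows.append({"group1": a, "group2": b, "p_adj": padj,
                         "significant": padj < alpha})
        pairwise = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}; use 'tukey' or 'bonferroni'")
    return AnovaResult(float(f), float(p), pairwise, posthoc, alpha)
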