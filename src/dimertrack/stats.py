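"""Per-cell aggregation, nonparametric group comparison and reporting.

The statistical unit is the cell: each cell contributes one relative
dimerization level (and one diffusion constant, immobile fraction, oligomer
fraction), and conditions are compared with two-sample Kolmogorov–Smirnov
tests on the per-cell values — never by pooling molecules across cells.
Box summaries are the five-number summary (min, Q1, median, Q3, max).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import combinations

import numpy as np
from scipy import special

from .errors import AnalysisError

__all__ = [
    "CellResult",
    "KsResult",
    "ks_two_sample",
    "five_number_summary",
    "significance_tier",
    "compile_report",
]

SCHEMA_VERSION = 1

#: star-convention significance thresholds
TIER_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class CellResult:
    """Per-cell summary produced by the analysis pipeline."""

    cell_id: str
    condition: str
    n_tracks_a: int                       # qualifying (mobile, lifetime > 10)
    n_tracks_b: int
    n_dimers: int
    relative_dimerization: float | None   # None = missing (no qualifying tracks)
    d_a_um2_s: float | None               # pooled-MSD D per channel
    d_b_um2_s: float | None
    immobile_fraction: float | None
    oligomer_fraction: float | None
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class KsResult:
    """Two-sample Kolmogorov–Smirnov comparison."""

    statistic: float   # exact sup |ECDF1 - ECDF2|
    p_value: float
    n1: int
    n2: int


def ks_two_sample(sample1, sample2) -> KsResult:
    """Two-sample KS test.

    The statistic is the exact supremum distance between the two empirical
    CDFs.  The p-value uses the asymptotic Kolmogorov distribution with the
    standard finite-sample effective-n correction
    λ = (√en + 0.12 + 0.11/√en)·D, en = n1·n2/(n1+n2).
    """
    x = np.sort(np.asarray(sample1, dtype=float))
    y = np.sort(np.asarray(sample2, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise AnalysisError("KS test requires two non-empty samples")
    grid = np.concatenate([x, y])
    cdf1 = np.searchsorted(x, grid, side="right") / n1
    cdf2 = np.searchsorted(y, grid, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    en = n1 * n2 / (n1 + n2)
    lam = (np.sqrt(en) + 0.12 + 0.11 / np.sqrt(en)) * d
    p = float(np.clip(special.kolmogorov(lam), 0.0, 1.0))
    return KsResult(statistic=d, p_value=p, n1=n1, n2=n2)


def five_number_summary(values) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with linear-interpolation quartiles.

    Quartiles use the linear interpolation convention (numpy default):
    Q_p sits at fractional rank p·(n−1).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise AnalysisError("five-number summary of an empty sample")
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return tuple(float(x) for x in q)  # type: ignore[return-value]


def significance_tier(p_value: float) -> str:
    """Star label for a p-value (NS / * / ** / *** / ****)."""
    for threshold, stars in TIER_THRESHOLDS:
        if p_value < threshold:
            return stars
    return "NS"


_METRICS = (
    "relative_dimerization",
    "d_a_um2_s",
    "d_b_um2_s",
    "immobile_fraction",
    "oligomer_fraction",
)


def _metric_values(cells: list[CellResult], metric: str) -> list[float]:
    return [
        float(getattr(c, metric)) for c in cells if getattr(c, metric) is not None
    ]


def compile_report(cells: list[CellResult], seed: int | None = None) -> dict:
    """Build the per-condition results document.

    Contains, per condition, the per-cell table and five-number summaries of
    every metric with at least one non-missing value, plus pairwise KS tests
    (with significance tiers) between all condition pairs for every metric
    both sides report.  Condition order follows first appearance in the
    input; output ordering is deterministic.
    """
    if not cells:
        raise AnalysisError("compile_report needs at least one cell")
    conditions: list[str] = []
    for c in cells:
        if c.condition not in conditions:
            conditions.append(c.condition)
    by_cond = {
        cond: [c for c in cells if c.condition == cond] for cond in conditions
    }
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "conditions": {},
        "comparisons": [],
    }
    for cond in conditions:
        group = by_cond[cond]
        summaries = {}
        for metric in _METRICS:
            vals = _metric_values(group, metric)
            if vals:
                mn, q1, med, q3, mx = five_number_summary(vals)
                summaries[metric] = {
                    "n": len(vals), "min": mn, "q1": q1,
                    "median": med, "q3": q3, "max": mx,
                }
        doc["conditions"][cond] = {
            "n_cells": len(group),
            "summaries": summaries,
            "cells": [c.to_dict() for c in group],
        }
    if len(conditions) > 1:
        for c1, c2 in combinations(conditions, 2):
            for metric in _METRICS:
                v1 = _metric_values(by_cond[c1], metric)
                v2 = _metric_values(by_cond[c2], metric)
                if not v1 or not v2:
                    continue
                ks = ks_two_sample(v1, v2)
                doc["comparisons"].append(
                    {
                        "metric": metric,
                        "condition_1": c1,
                        "condition_2": c2,
                        "ks_d": ks.statistic,
                        "p_value": ks.p_value,
                        "tier": significance_tier(ks.p_value),
                        "n_1": ks.n1,
                        "n_2": ks.n2,
                    }
                )
    return doc


def plot_boxes(doc: dict, metric: str, path) -> None:
    """Optional five-number box plot of one metric across conditions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conds, stats = [], []
    for cond, entry in doc["conditions"].items():
        s = entry["summaries"].get(metric)
        if s is None:
            continue
        conds.append(cond)
        stats.append(
            {
                "label": cond, "whislo": s["min"], "q1": s["q1"],
                "med": s["median"], "q3": s["q3"], "whishi": s["max"],
                "fliers": [],
            }
        )
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(conds), 3.2))
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
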