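"""Assay-level statistics: MN%, relative viability, t-tests, R², tables.

The micronucleus assay summarizes each dose group by the percentage of
micronucleated cells among all scored cells (MN%) and by relative
viability — the mean number of cells per photographed field expressed as a
percentage of the untreated control's mean, a cytotoxicity proxy.  Method
comparisons between automated and manual counts use a pooled-variance
one-sided Student t-test on per-image counts and the coefficient of
determination (squared Pearson correlation) on per-image pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DoseGroupSummary",
    "TTestResult",
    "mn_percentage",
    "relative_viability",
    "one_sided_t_test",
    "star_label",
    "r_squared",
    "build_table",
]

#: Significance-star mapping used in assay tables.
STAR_THRESHOLDS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mn_percentage(mn_cells: int, total_cells: int) -> float:
    """Percentage of micronucleus-containing cells, rounded to 2 decimals."""
    if total_cells < 1:
        raise ValidationError("total_cells must be >= 1")
    if not 0 <= mn_cells <= total_cells:
        raise ValidationError("mn_cells must be in [0, total_cells]")
    return round(100.0 * mn_cells / total_cells, 2)


def relative_viability(
    group_total: int,
    group_images: int,
    control_total: int,
    control_images: int,
) -> int:
    """Mean cells-per-image of a group relative to control, as integer %.

    ``round(100 * (group_total/group_images) / (control_total/control_images))``
    with half-up rounding.
    """
    for name, v in (
        ("group_total", group_total),
        ("group_images", group_images),
        ("control_total", control_total),
        ("control_images", control_images),
    ):
        if v < 1:
            raise ValidationError(f"{name} must be >= 1, got {v}")
    ratio = (group_total / group_images) / (control_total / control_images)
    return _round_half_up(100.0 * ratio)


def star_label(p: float) -> str:
    """Map a p-value onto the assay-table stars (0.05/0.01/0.005)."""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    stars: str
    n_a: int
    n_b: int


def one_sided_t_test(
    counts_a,
    counts_b,
    alternative: str = "greater",
) -> TTestResult:
    """Pooled-variance (classic Student) one-sided two-sample t-test.

    ``alternative='greater'`` tests mean(a) > mean(b) — the default
    direction asks whether the automated counts over-call relative to the
    manual ones; ``'less'`` tests the reverse.  With zero pooled variance
    and equal means the test is uninformative and returns t = 0, p = 0.5.
    """
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample must have at least 2 values")
    na, nb = a.size, b.size
    mean_a, mean_b = a.mean(), b.mean()
    pooled_var = (
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled_var == 0.0:
        if mean_a == mean_b:
            t = 0.0
            p = 0.5
        else:
            t = math.inf if mean_a > mean_b else -math.inf
            p = 0.0 if (t > 0) == (alternative == "greater") else 1.0
    else:
        se = math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
        t = (mean_a - mean_b) / se
        from scipy.stats import t as t_dist

        df = na + nb - 2
        if alternative == "greater":
            p = float(t_dist.sf(t, df))
        else:
            p = float(t_dist.cdf(t, df))
    return TTestResult(t=float(t), p=float(p), stars=star_label(p),
                       n_a=na, n_b=nb)


def r_squared(x, y) -> float:
    """Coefficient of determination: squared Pearson correlation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValidationError("series must share length")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("R^2 is undefined for a constant series")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


@dataclass(frozen=True)
class DoseGroupSummary:
    label: str
    dose: str
    n_images: int
    total_cells: int
    mn_cells: int
    mn_percent: float
    relative_viability_percent: int


def build_table(
    groups: dict[str, list[tuple[str, int, int]]],
    control_label: str,
    comparison: dict[str, list[int]] | None = None,
) -> pd.DataFrame:
    """Summarize per-image counts into a dose-group assay table.

    ``groups`` maps a group label to per-image ``(image, total, mn)``
    triples; the control group anchors the viability column at 100.  When
    ``comparison`` provides a second method's per-image MN counts for a
    group, the table gains that group's one-sided t statistic, p-value and
    significance stars (direction: this table's counts > comparison).
    """
    if control_label not in groups:
        raise ValidationError(
            f"control group {control_label!r} missing from input"
        )
    control = groups[control_label]
    if not control:
        raise ValidationError("control group has no images")
    control_total = sum(t for _, t, _ in control)
    control_images = len(control)

    rows = []
    for label, counts in groups.items():
        if not counts:
            raise ValidationError(f"group {label!r} has no images")
        total = sum(t for _, t, _ in counts)
        mn = sum(m for _, _, m in counts)
        if mn > total:
            raise ValidationError(f"group {label!r} has mn_cells > total_cells")
        row = {
            "group": label,
            "n_images": len(counts),
            "total_cells": total,
            "mn_cells": mn,
            "mn_percent": mn_percentage(mn, total),
            "viability_percent": relative_viability(
                total, len(counts), control_total, control_images
            ),
        }
        if comparison is not None and label in comparison:
            res = one_sided_t_test([m for _, _, m in counts],
                                   comparison[label])
            row["t"] = res.t
            row["p"] = res.p
            row["stars"] = res.stars
        rows.append(row)
    return pd.DataFrame(rows)
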