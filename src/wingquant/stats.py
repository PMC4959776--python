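"""Two-group comparisons of proliferation indices.

Groups are compared with an unpaired two-sided t test — pooled-variance
("Student's") by default, Welch as an option for unequal variances — and
annotated with the conventional significance stars (*p < .05, **p < .01,
***p < .001, strict inequalities). No multiple-testing correction is
applied: each comparison is reported at its nominal level, so with many
genotypes the family-wise error rate exceeds the per-test level.
Comparisons run against named reference (control) conditions rather than
all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateGroupsError, ValidationError
from .quantify import FailureRecord, QuantRecord

__all__ = [
    "GroupComparison",
    "t_test",
    "star_annotation",
    "compare_all",
    "comparisons_frame",
    "plot_group_bars",
]

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float
    stars: str
    variant: Literal["student_pooled", "welch"]


def star_annotation(p_value: float) -> str:
    """Map a p value to the printed star convention (strict boundaries)."""
    if not 0 <= p_value <= 1:
        raise ValidationError(f"p value must be in [0, 1], got {p_value}")
    for level, stars in STAR_LEVELS:
        if p_value < level:
            return stars
    return ""


def t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: Literal["student_pooled", "welch"] = "student_pooled",
    *,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Unpaired two-sided t test between two groups of indices.

    The pooled variant uses t = (m_a - m_b) / (s_p * sqrt(1/n_a + 1/n_b))
    with df = n_a + n_b - 2; Welch uses per-group variances with
    Satterthwaite degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if variant not in ("student_pooled", "welch"):
        raise ValidationError(f"unknown t-test variant: {variant!r}")
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            f"each group needs >= 2 values (got {a.size} and {b.size})"
        )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # Degenerate: no within-group spread at all.
        if a.mean() == b.mean():
            t_stat, df, p = 0.0, _df(a, b, variant), 1.0
        else:
            raise DegenerateGroupsError(
                "zero variance in both groups with unequal means"
            )
    else:
        res = sps.ttest_ind(a, b, equal_var=(variant == "student_pooled"))
        t_stat, df, p = float(res.statistic), float(res.df), float(res.pvalue)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=t_stat,
        df=df,
        p_value=p,
        stars=star_annotation(p),
        variant=variant,
    )


def _df(a: np.ndarray, b: np.ndarray, variant: str) -> float:
    if variant == "student_pooled":
        return float(a.size + b.size - 2)
    return float(a.size + b.size - 2)  # degenerate Welch case: same convention


def _group_values(
    records: Iterable[QuantRecord | FailureRecord],
) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {}
    for rec in records:
        if isinstance(rec, QuantRecord):
            groups.setdefault(rec.genotype, []).append(rec.proliferation_index)
    return groups


def compare_all(
    records: Iterable[QuantRecord | FailureRecord],
    reference_groups: Sequence[str],
    variant: Literal["student_pooled", "welch"] = "student_pooled",
) -> list[GroupComparison]:
    """Compare every genotype against each named reference condition.

    For each reference in order, every other genotype (including the other
    references) is tested against it; references are never compared to
    themselves. The reference is group_b so a positive t means the test
    genotype exceeds its control.
    """
    groups = _group_values(records)
    missing = [r for r in reference_groups if r not in groups]
    if missing:
        raise ValidationError(
            f"reference group(s) absent from records: {missing}; "
            f"present: {sorted(groups)}"
        )
    comparisons = []
    for ref in reference_groups:
        for genotype in groups:
            if genotype == ref:
                continue
            comparisons.append(
                t_test(
                    groups[genotype],
                    groups[ref],
                    variant,
                    label_a=genotype,
                    label_b=ref,
                )
            )
    return comparisons


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = [
        {
            "group": c.group_a,
            "reference": c.group_b,
            "n": c.n_a,
            "n_ref": c.n_b,
            "mean": c.mean_a,
            "mean_ref": c.mean_b,
            "t": c.t_stat,
            "df": c.df,
            "p_value": c.p_value,
            "stars": c.stars,  # empty string = not significant
            "variant": c.variant,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)


def plot_group_bars(
    records: Iterable[QuantRecord | FailureRecord],
    comparisons: Sequence[GroupComparison],
    path: str | Path,
    *,
    order: Sequence[str] | None = None,
) -> None:
    """Bar plot of mean index +/- s.e.m. per genotype with star marks.

    Non-significant comparisons are drawn as "ns"; stars refer to the first
    reference each group was compared against.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = _group_values(records)
    names = list(order) if order is not None else sorted(groups)
    means = [np.mean(groups[g]) for g in names]
    sems = [np.std(groups[g], ddof=1) / np.sqrt(len(groups[g])) for g in names]
    first_stars = {}
    for c in comparisons:
        first_stars.setdefault(c.group_a, c.stars if c.stars else "ns")

    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 1.5, 4))
    x = np.arange(len(names))
    ax.bar(x, means, yerr=sems, capsize=4, color="#88c999", edgecolor="black")
    for xi, g, m, s in zip(x, names, means, sems):
        if g in first_stars:
            ax.text(xi, m + s + 0.01, first_stars[g], ha="center", fontsize=11)
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=30, ha="right")
    ax.set_ylabel("proliferation index (GFP area / disc area, AU)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
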