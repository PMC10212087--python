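"""Group comparisons and report assembly.

The stiffness and morphometry arms each end in a two-group comparison
(day 5 vs day 20 moduli; inner vs outer regions).  The test is Welch's
unequal-variance t-test:

    t  = (m_a - m_b) / sqrt(s_a²/n_a + s_b²/n_b)
    df = (s_a²/n_a + s_b²/n_b)² / [ (s_a²/n_a)²/(n_a-1) + (s_b²/n_b)²/(n_b-1) ]

with a two-sided p from the t distribution.  Welch is the safe default
when group variances differ (as they visibly do here); a pooled-variance
Student's t is available behind a flag for sensitivity analysis.  The
summary-statistics entry point lets printed mean ± SD (n) values be
tested without raw data.  No multiple-testing correction is applied
(three comparisons per table, reported as-is).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import ValidationError
from .morphometry import MorphometrySummary

#: Significance marks: smallest threshold the p-value clears.
SIGNIFICANCE_MARKS = ((0.001, "**"), (0.005, "*"))


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("p must be in (0, 1]")
        if self.df <= 0:
            raise ValidationError("df must be positive")

    @property
    def significance_mark(self) -> str:
        for threshold, mark in SIGNIFICANCE_MARKS:
            if self.p_value < threshold:
                return mark
        return ""


def welch_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int,
                       label_a: str = "a", label_b: str = "b",
                       pooled: bool = False) -> GroupComparison:
    """Welch's t-test from summary statistics (mean, SD, N per group).

    ``pooled=True`` switches to Student's equal-variance test (pooled SD,
    df = n_a + n_b - 2) for sensitivity checks.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("SDs must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs N >= 2")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        if mean_a == mean_b:
            t_stat, df, p = 0.0, float(n_a + n_b - 2), 1.0
        else:
            t_stat = np.inf if mean_a > mean_b else -np.inf
            df, p = float(n_a + n_b - 2), float(np.finfo(float).tiny)
    elif pooled:
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        t_stat = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = float(n_a + n_b - 2)
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    else:
        t_stat = (mean_a - mean_b) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    return GroupComparison(label_a, label_b, mean_a, mean_b, sd_a, sd_b,
                           n_a, n_b, float(t_stat), float(df),
                           max(p, float(np.finfo(float).tiny)))


def welch_t_test(sample_a, sample_b, label_a: str = "a", label_b: str = "b",
                 pooled: bool = False) -> GroupComparison:
    """Welch's t-test on raw samples (delegates to the summary form)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs N >= 2")
    return welch_from_summary(a.mean(), a.std(ddof=1), len(a),
                              b.mean(), b.std(ddof=1), len(b),
                              label_a, label_b, pooled=pooled)


@dataclass(frozen=True)
class Report:
    """Assembled analysis report: a morphometry table and a stiffness block."""

    table: pd.DataFrame  # Table-1-shaped morphometry rows
    stiffness: pd.DataFrame  # per-group modulus summaries
    comparisons: list[GroupComparison]
    force_ratio: float | None
    complete: bool  # False if any expected group was missing

    def to_markdown(self) -> str:
        lines = ["# Spheroid analysis report", "", "## Morphometry", ""]
        lines.append(self.table.to_markdown(index=False))
        lines += ["", "## Stiffness", "", self.stiffness.to_markdown(index=False), ""]
        if self.force_ratio is not None:
            lines.append(f"Model force ratio (stiff/soft at equal compression): "
                         f"{self.force_ratio:.3f}")
        lines.append("")
        lines.append("## Comparisons")
        lines.append("")
        for c in self.comparisons:
            lines.append(f"- {c.label_a} vs {c.label_b}: t = {c.t_statistic:.3f}, "
                         f"df = {c.df:.2f}, p = {c.p_value:.3g} {c.significance_mark}")
        if not self.complete:
            lines.append("")
            lines.append("WARNING: one or more expected groups were missing (—).")
        return "\n".join(lines)


def build_report(morphometry: MorphometrySummary,
                 comparisons: list[GroupComparison],
                 moduli: dict[str, tuple[float, float, int]] | None = None,
                 expected_groups=("day5", "day20"),
                 expected_regions=("inner", "outer")) -> Report:
    """Assemble the Table-1-shaped table plus the stiffness block.

    ``moduli`` maps group name to (mean Pa, SD Pa, n).  Missing groups
    render with an explicit "—" gap marker and set ``complete=False``
    (strict CLI mode turns that into a nonzero exit).
    """
    marks = {}
    for c in comparisons:
        marks[(c.label_a, c.label_b)] = c.significance_mark
        marks[(c.label_b, c.label_a)] = c.significance_mark

    rows, complete = [], True
    areas = morphometry.areas.set_index(["group", "region"]) if len(
        morphometry.areas) else pd.DataFrame()
    dens = morphometry.densities.set_index(["group", "region"]) if len(
        morphometry.densities) else pd.DataFrame()
    for group in expected_groups:
        for region in expected_regions:
            key = (group, region)
            mark = marks.get((f"{group}:inner", f"{group}:outer"), "")
            if len(areas) and key in areas.index:
                a = areas.loc[key]
                cell = f"{a['cell_mean']:.0f}±{a['cell_sd']:.0f} (N = {int(a['n_cells'])}){mark}"
                nuc = f"{a['nucleus_mean']:.0f}±{a['nucleus_sd']:.0f} (N = {int(a['n_cells'])}){mark}"
            else:
                cell = nuc = "—"
                complete = False
            if len(dens) and key in dens.index:
                d = dens.loc[key]
                sd = d["density_sd"]
                density = (f"{d['density_mean']:.1f}±{sd:.1f}" if np.isfinite(sd)
                           else f"{d['density_mean']:.1f}±NA")
            else:
                density = "—"
                complete = False
            rows.append({"group": group, "region": region, "cell_um2": cell,
                         "nucleus_um2": nuc, "space_density_pct": density})
    table = pd.DataFrame(rows)

    srows = []
    ratio = None
    if moduli:
        for group in expected_groups:
            if group in moduli:
                m, sd, n = moduli[group]
                srows.append({"group": group, "modulus_pa": f"{m:.0f}±{sd:.0f}",
                              "n": n})
            else:
                srows.append({"group": group, "modulus_pa": "—", "n": 0})
                complete = False
        present = [moduli[g][0] for g in expected_groups if g in moduli]
        if len(present) == 2 and min(present) > 0:
            ratio = max(present) / min(present)
    stiffness = pd.DataFrame(srows, columns=["group", "modulus_pa", "n"])
    return Report(table=table, stiffness=stiffness, comparisons=comparisons,
                  force_ratio=ratio, complete=complete)
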