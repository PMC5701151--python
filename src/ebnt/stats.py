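"""Two-group statistics: normality screen, t-tests, Bonferroni families.

Every network measure is compared between groups with an independent
two-sample t-test (pooled variance by default; Welch available).  A
Shapiro-Wilk screen is run per group x measure x band as an advisory
check of the t-test's normality assumption.

Multiple-comparison families follow the structure of the analysis:
within each band and graph method, the two topology measures form one
Bonferroni family (they are correlated, so the correction is
conservative); the binary density sweep additionally corrects for its
15 densities, applied multiplicatively on top of the two-measure
factor.  Corrected p-values are classified at alpha = 0.01, with an
explicit "marginal" tier for 0.01 <= p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import shapiro, ttest_ind

__all__ = [
    "GroupComparison",
    "normality_screen",
    "group_ttest",
    "bonferroni",
    "run_full_comparison",
    "comparisons_to_frame",
]

#: measure label -> graph-method family used for Bonferroni correction
MEASURE_FAMILIES: dict[str, tuple[str, int]] = {
    # (method, per-band family size excluding the density factor)
    "mean_pli": ("connectivity", 1),
    "cc_norm": ("weighted", 2),
    "pl_norm": ("weighted", 2),
    "binary_cc": ("binary", 2),
    "binary_pl": ("binary", 2),
    "leaf_fraction": ("mst", 2),
    "tree_hierarchy": ("mst", 2),
}


@dataclass
class GroupComparison:
    """Result of one measure x band (x density) two-group test."""

    measure: str
    band: str
    t_stat: float
    p_raw: float
    p_corrected: float
    n_comparisons: int
    density: float | None = None

    @property
    def tier(self) -> str:
        if np.isnan(self.p_corrected):
            return "degenerate"
        if self.p_corrected < 0.01:
            return "significant"
        if self.p_corrected < 0.05:
            return "marginal"
        return "ns"


def normality_screen(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p for one group's measure vector.

    Advisory only: the pipeline proceeds with t-tests regardless.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least three observations")
    if values.std() == 0:
        raise ValueError("constant vector: normality test undefined")
    stat, p = shapiro(values)
    return float(stat), float(p)


def group_ttest(group1: np.ndarray, group2: np.ndarray,
                welch: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance unless
    ``welch``)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need at least two observations per group")
    if np.std(np.concatenate([g1, g2])) == 0:
        raise ValueError("zero variance in both groups: t undefined")
    t, p = ttest_ind(g1, g2, equal_var=not welch)
    return float(t), float(p)


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    """Multiply each p by the family size and clip at 1."""
    p = np.asarray(p_values, dtype=float)
    if n_comparisons is None:
        n_comparisons = p.size
    if n_comparisons < p.size:
        raise ValueError("family size cannot be smaller than the number of "
                         "p-values in the family")
    return np.minimum(1.0, p * n_comparisons)


def _family_size(measure: str, n_densities: int) -> int:
    method, base = MEASURE_FAMILIES.get(measure, ("other", 1))
    if method == "binary":
        return base * n_densities
    return base


def run_full_comparison(metrics: pd.DataFrame,
                        welch: bool = False) -> list[GroupComparison]:
    """All group comparisons from a tidy per-subject metrics table.

    ``metrics`` needs columns ``subject, group, band, measure, value``
    and optionally ``density`` (NaN outside the binary sweep).  One
    :class:`GroupComparison` is produced per measure x band (x density),
    Bonferroni-corrected within its method family.  Measures missing for
    some subjects raise with an explicit listing.
    """
    required = {"subject", "group", "band", "measure", "value"}
    missing_cols = required - set(metrics.columns)
    if missing_cols:
        raise ValueError(f"metrics table lacks columns {sorted(missing_cols)}")
    df = metrics.copy()
    if "density" not in df.columns:
        df["density"] = np.nan

    n_subjects = df.groupby("group")["subject"].nunique()
    out: list[GroupComparison] = []
    for (band, measure, density), cell in df.groupby(
            ["band", "measure", "density"], dropna=False, sort=True):
        per_group = {g: sub for g, sub in cell.groupby("group")}
        if set(per_group) != {1, 2}:
            raise ValueError(f"{measure}/{band}: need both groups")
        for g, sub in per_group.items():
            absent = n_subjects[g] - sub["subject"].nunique()
            if absent:
                have = set(sub["subject"])
                all_subj = set(df[df["group"] == g]["subject"])
                raise ValueError(
                    f"{measure}/{band}: group {g} missing subjects "
                    f"{sorted(all_subj - have)}")
        if cell["density"].notna().any():
            n_densities = int(df[(df["band"] == band) &
                                 (df["measure"] == measure)]
                              ["density"].nunique())
        else:
            n_densities = 1
        v1 = per_group[1]["value"].to_numpy()
        v2 = per_group[2]["value"].to_numpy()
        if np.std(np.concatenate([v1, v2])) == 0:
            # identical values in every subject (e.g. binary path length
            # at high densities, fixed by the equal edge count): flag as
            # degenerate instead of failing
            t, p = float("nan"), float("nan")
        else:
            t, p = group_ttest(v1, v2, welch=welch)
        n_comp = _family_size(measure, int(n_densities))
        out.append(GroupComparison(
            measure=measure,
            band=band,
            t_stat=t,
            p_raw=p,
            p_corrected=float(bonferroni([p], n_comp)[0]),
            n_comparisons=n_comp,
            density=None if pd.isna(density) else float(density),
        ))
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tidy DataFrame of comparison results (one row per test)."""
    return pd.DataFrame([{
        "measure": c.measure,
        "band": c.band,
        "density": c.density,
        "t": c.t_stat,
        "p_raw": c.p_raw,
        "p_corrected": c.p_corrected,
        "n_comparisons": c.n_comparisons,
        "tier": c.tier,
    } for c in comparisons])
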