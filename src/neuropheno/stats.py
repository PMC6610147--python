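"""Replicate aggregation and group contrasts for plate-based assays.

Statistical tests run on biological-replicate means (one well/differentiation
of one donor line, gated at ≥100 cells), mirroring how such assays report n.
Cell-level testing is possible by passing cell values directly but is not the
default unit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MW_MAX_N = 12


@dataclass
class GroupComparison:
    """Outcome of one statistical contrast."""

    test: str
    statistic: float
    p_value: float
    group_means: tuple[float, ...] = ()
    effect_percent: float = float("nan")
    flagged: bool = False
    note: str = ""

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def aggregate(
    cells: pd.DataFrame,
    group_cols: list[str],
    value_col: str,
    min_cells: int = 100,
) -> pd.DataFrame:
    """One summary row per replicate group, gated on minimum cell count.

    Replicates below ``min_cells`` are kept in the table but flagged
    (``passed_gate`` False) and should be excluded from tests.
    """
    missing = [c for c in group_cols + [value_col] if c not in cells.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    g = cells.groupby(group_cols, sort=True)[value_col]
    out = g.agg(n_cells="count", mean="mean", sd="std").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["passed_gate"] = out["n_cells"] >= min_cells
    return out


def percent_change(reference_mean: float, case_mean: float) -> float:
    """Signed percent change of the case relative to the reference."""
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (case_mean - reference_mean) / reference_mean


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with the midrank tie convention."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U on two independent samples.

    Exact p (full enumeration of group assignments, valid under ties) for
    combined n ≤ 12; tie-corrected normal approximation with continuity
    correction otherwise. All-identical pooled values leave the p-value
    undefined; the result is flagged with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    means = (float(x.mean()), float(y.mean()))
    eff = percent_change(means[0], means[1]) if means[0] != 0 else float("nan")

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            "mann-whitney-u", u, 1.0, means, eff, flagged=True,
            note="degenerate: all pooled values identical",
        )

    if n1 + n2 <= EXACT_MW_MAX_N:
        center = n1 * n2 / 2.0
        dev = abs(u - center)
        count = 0
        total = 0
        idx_all = range(n1 + n2)
        for comb in itertools.combinations(idx_all, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - center) >= dev - 1e-12:
                count += 1
        p = count / total
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return GroupComparison("mann-whitney-u", u, min(p, 1.0), means, eff)


def t_test_unpaired(x, y, equal_var: bool = True) -> GroupComparison:
    """Two-sided unpaired t-test (pooled variance by default; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    means = (float(x.mean()), float(y.mean()))
    eff = percent_change(means[0], means[1]) if means[0] != 0 else float("nan")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and means[0] == means[1]:
        return GroupComparison(
            "t-unpaired", 0.0, 1.0, means, eff, flagged=True,
            note="degenerate: zero pooled variance with equal means",
        )
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return GroupComparison("t-unpaired", float(t), float(p), means, eff)


def two_way_anova(
    summaries: pd.DataFrame,
    value_col: str = "mean",
    factor_a: str = "genotype",
    factor_b: str = "treatment",
) -> list[GroupComparison]:
    """Type-II two-way ANOVA on a replicate-level table.

    Returns comparisons for factor A, factor B and the A×B interaction.
    Raises on empty design cells, naming the offending cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (value_col, factor_a, factor_b):
        if col not in summaries.columns:
            raise KeyError(f"missing column {col!r}")
    levels_a = summaries[factor_a].unique()
    levels_b = summaries[factor_b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need at least 2 levels")
    counts = summaries.groupby([factor_a, factor_b], observed=True).size()
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in counts.index:
                raise ValueError(f"empty design cell: {factor_a}={a!r}, {factor_b}={b!r}")

    vals = summaries[value_col].to_numpy(dtype=float)
    scale = max(np.mean(np.abs(vals)), 1.0)
    if np.var(vals) <= (1e-12 * scale) ** 2:
        # constant response: every F is 0/0; report flagged nulls rather
        # than the machine-epsilon garbage an OLS fit would produce
        return [
            GroupComparison(f"anova2:{name}", 0.0, 1.0, flagged=True,
                            note="degenerate: no variance")
            for name in (factor_a, factor_b, f"{factor_a}x{factor_b}")
        ]

    df = summaries.rename(columns={value_col: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    for term, name in (("C(_a)", factor_a), ("C(_b)", factor_b), ("C(_a):C(_b)", f"{factor_a}x{factor_b}")):
        F = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        flagged = False
        note = ""
        if math.isnan(F):  # zero residual + zero effect variance
            F, p, flagged, note = 0.0, 1.0, True, "degenerate: no variance"
        out.append(GroupComparison(f"anova2:{name}", F, p, flagged=flagged, note=note))
    return out


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "group_means": list(c.group_means),
                "effect_percent": c.effect_percent,
                "stars": c.stars,
                "flagged": c.flagged,
                "note": c.note,
            }
            for c in comparisons
        ]
    )


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
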