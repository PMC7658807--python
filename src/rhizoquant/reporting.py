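"""Relative qPCR expression and the group-statistics harness.

Expression of a target gene is reported relative to a reference gene by
2^-dCp, where dCp = Cp_target - Cp_reference is the crossing-point
difference.  Group comparisons are presented exactly as figure legends
name them: two-tailed Student's t for two groups, one- or two-way ANOVA
with a post hoc Tukey HSD test for factorial designs.  Upstream modules
produce one value per cell / trace / image; this module aggregates per
biological replicate and tests on those, so legend n's refer to
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "relative_expression_2dcp",
    "relative_expression_table",
    "significance_stars",
    "GroupStatsResult",
    "compare_groups",
]


def relative_expression_2dcp(cp_target, cp_reference):
    """Relative expression 2^-(Cp_target - Cp_reference).

    Accepts scalars or arrays; equal crossing points give 1.0 and each
    additional target cycle halves the value.  Non-finite input is an
    error (a missing Cp cannot silently become an expression level).
    """
    ct = np.asarray(cp_target, dtype=np.float64)
    cr = np.asarray(cp_reference, dtype=np.float64)
    if not (np.isfinite(ct).all() and np.isfinite(cr).all()):
        raise ValueError("Cp values must be finite")
    out = np.power(2.0, -(ct - cr))
    return float(out) if out.ndim == 0 else out


def relative_expression_table(
    cp: pd.DataFrame, reference_gene: str
) -> pd.DataFrame:
    """Per-sample relative expression of every gene versus a reference.

    ``cp`` needs columns sample, gene, cp.  Every sample must carry a Cp
    for the reference gene.  The reference gene itself is omitted from
    the output (its relative expression is identically 1).
    """
    required = {"sample", "gene", "cp"}
    if not required.issubset(cp.columns):
        raise ValueError(f"Cp table needs columns {sorted(required)}")
    ref = cp[cp["gene"] == reference_gene].set_index("sample")["cp"]
    missing = set(cp["sample"]) - set(ref.index)
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for samples {sorted(missing)}"
        )
    tgt = cp[cp["gene"] != reference_gene].copy()
    tgt["relative_expression"] = relative_expression_2dcp(
        tgt["cp"].to_numpy(), ref.loc[tgt["sample"]].to_numpy()
    )
    return tgt[["sample", "gene", "relative_expression"]].reset_index(drop=True)


def significance_stars(p: float, thresholds=(0.05, 0.01, 0.001)) -> str:
    """Figure-legend stars: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if not np.isfinite(p):
        return "na"
    stars = sum(p < t for t in thresholds)
    return "*" * stars if stars else "ns"


@dataclass
class GroupStatsResult:
    """Outcome of one group comparison: the test identity, per-comparison
    rows (statistic, p, stars), and ANOVA effect table when applicable."""

    method: str
    comparisons: pd.DataFrame
    effects: pd.DataFrame | None = None
    alpha: float = 0.05


def _check_groups(groups: dict[str, np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has < 2 replicates")


def compare_groups(
    data: pd.DataFrame,
    value: str,
    factors: list[str] | str,
    method: str = "t",
    alpha: float = 0.05,
) -> GroupStatsResult:
    """Compare replicate measurements across groups.

    method 't': two-tailed Student's t test between exactly two groups of
    ``factors[0]``.  'anova1-tukey': one-way ANOVA over the levels of one
    factor, post hoc Tukey HSD.  'anova2-tukey': two-way ANOVA with
    interaction over two crossed factors (balanced designs only — an
    unbalanced two-way layout is an explicit error, never a silent
    fallback), Tukey HSD on the factor-combination cells.
    """
    if isinstance(factors, str):
        factors = [factors]
    for col in [value, *factors]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    df = data.dropna(subset=[value]).copy()

    if method == "t":
        if len(factors) != 1:
            raise ValueError("t test takes exactly one grouping factor")
        levels = sorted(df[factors[0]].unique())
        if len(levels) != 2:
            raise ValueError(f"t test needs exactly 2 groups, got {len(levels)}")
        groups = {lv: df.loc[df[factors[0]] == lv, value].to_numpy()
                  for lv in levels}
        _check_groups(groups)
        t, p = stats.ttest_ind(groups[levels[0]], groups[levels[1]])
        comp = pd.DataFrame([{
            "group1": levels[0], "group2": levels[1],
            "statistic": float(t), "p_value": float(p),
            "stars": significance_stars(float(p)),
        }])
        return GroupStatsResult("two-tailed Student's t test", comp, alpha=alpha)

    if method == "anova1-tukey":
        if len(factors) != 1:
            raise ValueError("one-way ANOVA takes exactly one factor")
        fac = factors[0]
        groups = {lv: df.loc[df[fac] == lv, value].to_numpy()
                  for lv in df[fac].unique()}
        _check_groups(groups)
        model = ols(f"Q('{value}') ~ C(Q('{fac}'))", data=df).fit()
        effects = anova_lm(model, typ=2)
        tuk = pairwise_tukeyhsd(df[value], df[fac], alpha=alpha)
        comp = _tukey_frame(tuk)
        return GroupStatsResult(
            "one-way ANOVA with post hoc Tukey HSD", comp, effects, alpha)

    if method == "anova2-tukey":
        if len(factors) != 2:
            raise ValueError("two-way ANOVA takes exactly two factors")
        a, b = factors
        cells = df.groupby([a, b], observed=True)[value].count()
        full = df[a].nunique() * df[b].nunique()
        if len(cells) != full or cells.nunique() != 1:
            raise ValueError(
                "two-way ANOVA with interaction requires a balanced, fully "
                f"crossed design; got cell sizes {dict(cells)}"
            )
        if cells.iloc[0] < 2:
            raise ValueError("need >= 2 replicates per cell")
        model = ols(
            f"Q('{value}') ~ C(Q('{a}')) * C(Q('{b}'))", data=df
        ).fit()
        effects = anova_lm(model, typ=2)
        combo = df[a].astype(str) + ":" + df[b].astype(str)
        tuk = pairwise_tukeyhsd(df[value], combo, alpha=alpha)
        comp = _tukey_frame(tuk)
        return GroupStatsResult(
            "two-way ANOVA with post hoc Tukey HSD", comp, effects, alpha)

    raise ValueError(f"unknown method {method!r}")


def _tukey_frame(tuk) -> pd.DataFrame:
    tbl = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    out = pd.DataFrame({
        "group1": tbl["group1"],
        "group2": tbl["group2"],
        "statistic": tbl["meandiff"].astype(float),
        "p_value": tbl["p-adj"].astype(float),
    })
    out["stars"] = out["p_value"].map(significance_stars)
    return out
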