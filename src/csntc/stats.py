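"""Fixed-effects two-way ANOVA computed directly from sums of squares.

Used for the lesion study: per-simulation NRMSE with factors TEST
(SAME vs DIFF condition) and LESION (lesion group vs baseline). The
implementation is the classical balanced-design decomposition, so it can
be checked against hand computation; a guard rejects unbalanced tables,
where the classical formulas are not the least-squares decomposition.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

__all__ = ["anova_two_way"]


def anova_two_way(
    records: pd.DataFrame,
    response: str = "nrmse",
    factor_a: str = "condition",
    factor_b: str = "lesion",
) -> dict:
    """Two-way fixed-effects ANOVA with interaction on a balanced table.

    Returns a dict with F statistics, p-values (from the F distribution)
    and degrees of freedom for the two main effects and their interaction.
    Every factor-level cell needs at least 2 observations, and all cells
    must have equal counts (balanced design).
    """
    df = records[[factor_a, factor_b, response]].dropna()
    y = df[response].to_numpy(dtype=float)
    a_lv = df[factor_a].unique()
    b_lv = df[factor_b].unique()
    a, b = len(a_lv), len(b_lv)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least two levels")

    counts = df.groupby([factor_a, factor_b]).size()
    if len(counts) != a * b or counts.min() < 2:
        raise ValueError("every cell needs >= 2 observations")
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced table: classical sums of squares require equal "
            f"cell counts, got {sorted(counts.unique())}"
        )
    n = int(counts.iloc[0])
    N = len(y)

    grand = y.mean()
    mean_a = df.groupby(factor_a)[response].mean()
    mean_b = df.groupby(factor_b)[response].mean()
    mean_ab = df.groupby([factor_a, factor_b])[response].mean()

    ss_a = b * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a * n * float(((mean_b - grand) ** 2).sum())
    ss_cells = n * float(((mean_ab - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    cell_of = mean_ab.loc[list(zip(df[factor_a], df[factor_b]))].to_numpy()
    ss_err = float(((y - cell_of) ** 2).sum())

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = N - a * b
    ms_err = ss_err / df_err

    def f_p(ss, dof):
        F = (ss / dof) / ms_err
        return F, float(sps.f.sf(F, dof, df_err))

    F_a, p_a = f_p(ss_a, df_a)
    F_b, p_b = f_p(ss_b, df_b)
    F_ab, p_ab = f_p(ss_ab, df_ab)
    return {
        "F_A": F_a, "p_A": p_a,
        "F_B": F_b, "p_B": p_b,
        "F_AB": F_ab, "p_AB": p_ab,
        "df": {"A": df_a, "B": df_b, "AB": df_ab, "error": df_err},
        "ss": {"A": ss_a, "B": ss_b, "AB": ss_ab, "error": ss_err},
        "factors": {"A": factor_a, "B": factor_b},
    }
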