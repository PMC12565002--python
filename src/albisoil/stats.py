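"""Treatment-effect statistics for balanced inoculation trials.

Percent change versus control, one-way ANOVA with Duncan's multiple range
test letters, balanced 2x2 factorial two-way ANOVA, and a Pearson
correlation matrix with t-transform p-values. Only balanced designs are
supported, which keeps the factorial sums of squares orthogonal and free of
Type-I/II/III ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .soil_tables import IndicatorTable

__all__ = [
    "AnovaResult",
    "percent_change",
    "one_way_anova",
    "duncan_letters",
    "two_way_anova",
    "pearson_matrix",
]


@dataclass
class AnovaResult:
    """ANOVA source table plus group means and (one-way) Duncan letters."""

    table: pd.DataFrame  # index: sources; columns: df, SS, MS, F, p
    group_means: pd.Series
    letters: dict[str, str] | None = None
    status: str = "ok"  # "ok" | "undefined" (all observations identical)


def percent_change(treated_mean: float, control_mean: float) -> float:
    """100 * (treated - control) / control."""
    if control_mean == 0:
        raise DegenerateDataError("control mean is zero; percent change undefined")
    return 100.0 * (treated_mean - control_mean) / control_mean


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have the same length")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        out[str(g)] = values[groups == g]
    return out


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical between/within decomposition with the F test.

    Degenerate cases: all observations identical -> status ``"undefined"``
    (F and p NaN); zero within-group variance with unequal means -> F
    reported as +inf with p = 0.
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValidationError("one-way ANOVA needs >= 2 groups")
    small = [g for g, v in by_group.items() if len(v) < 2]
    if small:
        raise ValidationError(f"group(s) with < 2 observations: {small}")

    y = np.asarray(values, dtype=float)
    n = len(y)
    grand = y.mean()
    means = {g: v.mean() for g, v in by_group.items()}
    ss_between = sum(len(v) * (m - grand) ** 2 for (g, v), m in zip(by_group.items(), means.values()))
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_b, df_w = len(by_group) - 1, n - len(by_group)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w

    status = "ok"
    if ss_within <= 0 and ss_between <= 0:
        f_stat, p = float("nan"), float("nan")
        status = "undefined"
    elif ss_within <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(sps.f.sf(f_stat, df_b, df_w))

    table = pd.DataFrame(
        {
            "df": [df_b, df_w, n - 1],
            "SS": [ss_between, ss_within, ss_between + ss_within],
            "MS": [ms_b, ms_w, np.nan],
            "F": [f_stat, np.nan, np.nan],
            "p": [p, np.nan, np.nan],
        },
        index=["between", "within", "total"],
    )
    return AnovaResult(table=table, group_means=pd.Series(means), status=status)


def _cld_insert_absorb(names: list[str], significant) -> dict[str, str]:
    """Compact letter display (insert-and-absorb) for groups sorted by mean.

    ``significant(i, j)`` answers whether groups i and j (indices into
    ``names``) differ; letters are assigned alphabetically in the given
    (descending-mean) order.
    """
    columns: list[set[int]] = [set(range(len(names)))]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if not significant(i, j):
                continue
            for col in list(columns):
                if i in col and j in col:
                    columns.remove(col)
                    a, b = col - {j}, col - {i}
                    # absorb: drop a new column contained in an existing one
                    if not any(a <= other for other in columns):
                        columns.append(a)
                    if not any(b <= other for other in columns):
                        columns.append(b)
    # order columns by the first (highest-mean) member for stable lettering
    columns.sort(key=lambda col: sorted(col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for letter, col in zip(alphabet, columns):
        for i in sorted(col):
            letters[names[i]] += letter
    return letters


def duncan_letters(
    means: Mapping[str, float],
    mse: float,
    df: int,
    n_per_group: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan's multiple range test as a compact letter display.

    For a pair spanning p ordered means the critical point is the
    studentized range quantile at the protection level
    ``alpha_p = 1 - (1 - alpha)^(p - 1)`` with the residual df; a range
    whose enclosing span already tested non-significant is declared
    non-significant without testing (the standard step-down protection).
    Balanced groups only.
    """
    if mse < 0 or df < 1 or n_per_group < 2:
        raise ValidationError("need mse >= 0, df >= 1, n_per_group >= 2")
    names = sorted(means, key=lambda g: (-means[g], g))
    m = np.array([means[g] for g in names])
    k = len(names)
    se = np.sqrt(mse / n_per_group)

    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)
    for span in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        crit = sps.studentized_range.ppf(1.0 - alpha_p, span, df) * se
        for i in range(0, k - span + 1):
            j = i + span - 1
            enclosed = any(
                nonsig[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (a, b) != (i, j) and b - a > j - i
            )
            if enclosed or (m[i] - m[j]) <= crit:
                nonsig[i:j + 1, i:j + 1] = True

    letters = _cld_insert_absorb(names, lambda i, j: not nonsig[i, j])
    return letters


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[bool],
    factor_b: Sequence[bool],
) -> AnovaResult:
    """Balanced 2x2 factorial ANOVA: main effects A, B, interaction, residual."""
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a, dtype=bool)
    b = np.asarray(factor_b, dtype=bool)
    if not (len(y) == len(a) == len(b)):
        raise ValidationError("values and factors must have the same length")
    cells = {(la, lb): y[(a == la) & (b == lb)] for la in (False, True) for lb in (False, True)}
    sizes = {c: len(v) for c, v in cells.items()}
    if len(set(sizes.values())) != 1 or min(sizes.values()) < 2:
        raise ValidationError(f"design must be balanced with >= 2 per cell, got {sizes}")

    grand = y.mean()
    mean_a = {la: y[a == la].mean() for la in (False, True)}
    mean_b = {lb: y[b == lb].mean() for lb in (False, True)}
    cell_mean = {c: v.mean() for c, v in cells.items()}

    ss_a = sum((a == la).sum() * (mean_a[la] - grand) ** 2 for la in (False, True))
    ss_b = sum((b == lb).sum() * (mean_b[lb] - grand) ** 2 for lb in (False, True))
    ss_ab = sum(
        sizes[c] * (cell_mean[c] - mean_a[c[0]] - mean_b[c[1]] + grand) ** 2 for c in cells
    )
    ss_res = sum(((v - cell_mean[c]) ** 2).sum() for c, v in cells.items())
    n = len(y)
    df_res = n - 4
    ms_res = ss_res / df_res

    rows = {}
    for src, ss in (("A", ss_a), ("B", ss_b), ("A:B", ss_ab)):
        if ms_res > 0:
            f_stat = ss / 1 / ms_res
            p = float(sps.f.sf(f_stat, 1, df_res))
        else:
            f_stat = float("inf") if ss > 0 else float("nan")
            p = 0.0 if ss > 0 else float("nan")
        rows[src] = [1, ss, ss, f_stat, p]
    rows["residual"] = [df_res, ss_res, ms_res, np.nan, np.nan]
    rows["total"] = [n - 1, ss_a + ss_b + ss_ab + ss_res, np.nan, np.nan, np.nan]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "SS", "MS", "F", "p"]
    )
    means = pd.Series({f"A={c[0]},B={c[1]}": m for c, m in cell_mean.items()})
    return AnovaResult(table=table, group_means=means)


def pearson_matrix(table: IndicatorTable | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r matrix and two-sided p matrix (t-transform, n-2 df)."""
    frame = table.data if isinstance(table, IndicatorTable) else table
    x = frame.to_numpy(dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValidationError("pearson_matrix needs >= 3 samples")
    flat = [str(c) for c, s in zip(frame.columns, x.std(axis=0)) if s == 0]
    if flat:
        raise DegenerateDataError(f"constant column(s): {flat}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / (1.0 - r**2))
    pmat = 2.0 * sps.t.sf(t, n - 2)
    pmat[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(pmat, 0.0)
    cols = frame.columns
    return pd.DataFrame(r, index=cols, columns=cols), pd.DataFrame(pmat, index=cols, columns=cols)
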