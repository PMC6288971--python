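"""Statistical layer: balanced ANOVA, Duncan's multiple range test, fold changes.

The expression analysis tests homeolog/genotype and treatment effects with a
classical fixed-effects two-way ANOVA (balanced designs only), follows a
significant omnibus test with Duncan's multiple range post-hoc procedure
(shared-letter displays), and reports fold changes on two conventions:
RPKPM ratios (with a pseudocount guarding zero baselines) and differences of
background-subtracted log2 microarray intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Residual variance is zero; F statistics are undefined."""


class UnbalancedDesignError(ValueError):
    """The implemented sums of squares require a balanced design."""


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float
    F: float
    p: float


@dataclass
class AnovaResult:
    rows: list[AnovaRow]
    error_df: int
    mse: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": r.source, "df": r.df, "ss": r.ss, "ms": r.ms,
              "F": r.F, "p": r.p} for r in self.rows]
        )

    def p_value(self, source: str) -> float:
        for r in self.rows:
            if r.source == source:
                return r.p
        raise KeyError(source)


def _check_balanced(table: pd.DataFrame, factors: list[str]) -> int:
    sizes = table.groupby(factors, observed=True).size()
    expected = 1
    for f in factors:
        expected *= table[f].nunique()
    if len(sizes) != expected or sizes.nunique() != 1:
        raise UnbalancedDesignError(
            "unbalanced design: every factor-level combination needs the same "
            "number of replicates"
        )
    n = int(sizes.iloc[0])
    if n < 2:
        raise UnbalancedDesignError("at least 2 replicates per cell are required")
    return n


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "treatment",
) -> AnovaResult:
    """Classical fixed-effects two-way ANOVA on a balanced design.

    Partitions the total sum of squares into main effects, interaction and
    residual; p-values from the F distribution.  Rejects unbalanced designs
    and zero residual variance explicitly.
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    n = _check_balanced(table, [factor_a, factor_b])
    a_levels = sorted(table[factor_a].unique())
    b_levels = sorted(table[factor_b].unique())
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least two levels")

    y = np.empty((a, b, n), dtype=float)
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            cell = table.loc[(table[factor_a] == al) & (table[factor_b] == bl), value]
            y[i, j, :] = cell.to_numpy(dtype=float)

    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_cell = y.mean(axis=2)

    ss_a = b * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a * n * float(((mean_b - grand) ** 2).sum())
    ss_ab = n * float(
        ((mean_cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_e = float(((y - mean_cell[:, :, None]) ** 2).sum())

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)
    if ss_e <= 0:
        raise DegenerateDataError("zero residual variance")
    mse = ss_e / df_e

    rows = []
    for source, ss, df in ((factor_a, ss_a, df_a), (factor_b, ss_b, df_b),
                           ("interaction", ss_ab, df_ab)):
        ms = ss / df
        F = ms / mse
        p = float(sps.f.sf(F, df, df_e))
        rows.append(AnovaRow(source, df, ss, ms, F, p))
    rows.append(AnovaRow("residual", df_e, ss_e, mse, np.nan, np.nan))
    return AnovaResult(rows=rows, error_df=df_e, mse=mse)


def one_way_anova(groups: Mapping[str, Sequence[float]] | pd.DataFrame,
                  value: str = "value", factor: str = "group") -> AnovaResult:
    """One-way fixed-effects ANOVA (balanced; explicit on degenerate data)."""
    if isinstance(groups, pd.DataFrame):
        groups = {lvl: sub[value].to_numpy(dtype=float)
                  for lvl, sub in groups.groupby(factor, observed=True)}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = {len(v) for v in arrays.values()}
    if len(sizes) != 1:
        raise UnbalancedDesignError("groups must be of equal size")
    n = sizes.pop()
    if n < 2:
        raise UnbalancedDesignError("at least 2 replicates per group are required")
    k = len(arrays)
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = n * sum((v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b, df_e = k - 1, k * (n - 1)
    if ss_within <= 0:
        raise DegenerateDataError("zero residual variance")
    mse = ss_within / df_e
    F = (ss_between / df_b) / mse
    p = float(sps.f.sf(F, df_b, df_e))
    rows = [AnovaRow(factor, df_b, float(ss_between), float(ss_between) / df_b, float(F), p),
            AnovaRow("residual", df_e, float(ss_within), mse, np.nan, np.nan)]
    return AnovaResult(rows=rows, error_df=df_e, mse=mse)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass
class MrtResult:
    """Duncan letter display over ordered group means."""

    means: pd.Series            # sorted descending
    letters: dict[str, str]     # group label -> letter string
    critical_ranges: dict[int, float]  # span p -> R_p
    alpha: float
    error_df: int
    mse: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.means,
            "letters": pd.Series(self.letters).reindex(self.means.index),
        })


def duncan_critical_range(p: int, error_df: int, mse: float, n_per_group: int,
                          alpha: float = 0.05) -> float:
    """Critical range R_p for a span of p ordered means.

    Uses Duncan's protection level 1-(1-alpha)^(p-1): the studentized-range
    quantile q at that level times sqrt(MSE/n).
    """
    level = (1.0 - alpha) ** (p - 1)
    q = float(sps.studentized_range.ppf(level, p, error_df))
    return q * float(np.sqrt(mse / n_per_group))


def duncan_mrt(
    means: Mapping[str, float] | pd.Series,
    n_per_group: int,
    mse: float,
    error_df: int,
    alpha: float = 0.05,
) -> MrtResult:
    """Duncan's multiple range test with a shared-letter display.

    Means are sorted descending; for each span p the range of p consecutive
    ordered means is declared non-significant when it does not exceed the
    critical range R_p, and (per the standard protection rule) whenever it is
    contained in a longer non-significant range.  Letters are assigned to the
    maximal non-significant stretches; groups sharing a letter are not
    significantly different.

    The caller is expected to run this only after a significant omnibus
    ANOVA (protected test); ``mse``/``error_df`` come from that ANOVA.
    """
    s = pd.Series(dict(means), dtype=float).sort_values(ascending=False, kind="stable")
    k = len(s)
    if k < 2:
        raise ValueError("need at least two group means")
    if n_per_group < 1:
        raise ValueError("n_per_group must be positive")
    vals = s.to_numpy()

    ranges = {p: duncan_critical_range(p, error_df, mse, n_per_group, alpha)
              for p in range(2, k + 1)}

    # nonsig[i][j]: ordered means i..j (inclusive) are homogeneous.
    # Sweep spans longest-first so containment in a non-significant range
    # propagates to all sub-ranges.
    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            contained = False
            if span < k:
                if i > 0 and nonsig[i - 1, j]:
                    contained = True
                if j < k - 1 and nonsig[i, j + 1]:
                    contained = True
            if contained or (vals[i] - vals[j]) <= ranges[span]:
                nonsig[i, j] = True

    # maximal homogeneous stretches -> letters
    stretches = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        stretches.append((i, j))
    maximal = [st for st in stretches
               if not any(o != st and o[0] <= st[0] and st[1] <= o[1] for o in stretches)]
    maximal.sort()

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {label: "" for label in s.index}
    for li, (i, j) in enumerate(maximal):
        ch = alphabet[li % len(alphabet)]
        for idx in range(i, j + 1):
            letters[s.index[idx]] += ch

    return MrtResult(means=s, letters=letters, critical_ranges=ranges,
                     alpha=alpha, error_df=error_df, mse=mse)


def anova_duncan(
    values: pd.DataFrame,
    value: str = "value",
    factor: str = "group",
    alpha: float = 0.05,
) -> tuple[AnovaResult, MrtResult | None]:
    """Protected Duncan test: letters only when the one-way ANOVA rejects.

    When the omnibus test is not significant at ``alpha`` all groups share
    the letter 'a'.
    """
    anova = one_way_anova(values, value=value, factor=factor)
    means = values.groupby(factor, observed=True)[value].mean()
    n = int(values.groupby(factor, observed=True).size().iloc[0])
    if anova.rows[0].p >= alpha:
        letters = {label: "a" for label in means.index}
        mrt = MrtResult(means=means.sort_values(ascending=False), letters=letters,
                        critical_ranges={}, alpha=alpha,
                        error_df=anova.error_df, mse=anova.mse)
        return anova, mrt
    mrt = duncan_mrt(means, n_per_group=n, mse=anova.mse,
                     error_df=anova.error_df, alpha=alpha)
    return anova, mrt


# ---------------------------------------------------------------------------
# fold-change conventions
# ---------------------------------------------------------------------------

def fold_change_rpkpm(treated: float, control: float, pseudocount: float = 0.1) -> float:
    """RPKPM ratio with a pseudocount guarding zero baselines."""
    if treated < 0 or control < 0:
        raise ValueError("RPKPM values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and control == 0:
        raise ZeroDivisionError("control is zero; use a positive pseudocount")
    return (treated + pseudocount) / (control + pseudocount)


def fold_change_log2(treated_log2: float, control_log2: float,
                     background: float = 3.4) -> float:
    """Fold change from background-subtracted log2 intensities.

    Values are floored at the background before differencing, so a 1-unit
    difference is a two-fold change and sub-background signals count as zero.
    """
    t = max(treated_log2 - background, 0.0)
    c = max(control_log2 - background, 0.0)
    return float(2.0 ** (t - c))
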