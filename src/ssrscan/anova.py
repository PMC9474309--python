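"""Analysis of variance and Tukey all-pairs comparison of SSR abundance.

The inference layer compares per-window SSR occurrence counts between genomes
and between motifs.  The observation unit is a non-overlapping genomic window
(default 100 kb): each (genome, motif) cell contributes one count per window,
giving the replicate structure a fixed-effects ANOVA needs.

One-way ANOVA decomposes total variation into a between-group and a
within-group sum of squares::

    SS_between = sum_i n_i (xbar_i - xbar_G)^2      df_between = k - 1
    SS_within  = sum_ij (x_ij - xbar_i)^2           df_within  = N - k
    F = MS_between / MS_within

with the p-value the upper tail of the F distribution at
(df_between, df_within).  The two-way layout (genome x motif, windows as
replicates) uses the exact balanced-design decomposition; with a single
replicate per cell the additive model is fitted and the interaction is not
estimable.  Tukey's HSD controls the family-wise error of all pairwise mean
comparisons through the studentized range distribution.

Decision rules
--------------
``standard`` rejects the null when ``p < alpha`` (equivalently
``F > F_critical``).  ``paper`` is a compatibility mode that *inverts* the
inequality (reject when ``F < F_critical``); it exists only for traceability
against prior published output that used the inverted rule and should not be
used for new analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, UnbalancedDesignError
from .search import MotifPattern, find_occurrences

__all__ = [
    "GroupedObservations",
    "AnovaResult",
    "AnovaEffect",
    "TwoWayAnovaResult",
    "TukeyComparison",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "f_tail_probability",
    "f_critical_value",
    "windowed_counts",
    "panel_window_counts",
]

DECISION_RULES = ("standard", "paper")


@dataclass(frozen=True)
class GroupedObservations:
    """k >= 2 labelled groups of real-valued observations."""

    labels: tuple[str, ...]
    groups: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        groups = tuple(np.asarray(g, dtype=float).ravel() for g in self.groups)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.labels) != len(groups):
            raise ValueError("labels and groups must have equal length")
        if len(groups) < 2:
            raise ValueError("at least two groups are required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("group labels must be unique")
        if any(g.size == 0 for g in groups):
            raise ValueError("every group needs at least one observation")

    @classmethod
    def from_dict(cls, data: Mapping[str, Sequence[float]]) -> "GroupedObservations":
        return cls(tuple(data.keys()), tuple(np.asarray(v, float) for v in data.values()))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str, value_col: str) -> "GroupedObservations":
        """Build groups from a tidy DataFrame, preserving first-seen order."""
        labels = list(dict.fromkeys(df[group_col]))
        groups = tuple(df.loc[df[group_col] == l, value_col].to_numpy(float) for l in labels)
        return cls(tuple(str(l) for l in labels), groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([g.size for g in self.groups])

    @property
    def n_total(self) -> int:
        return int(self.sizes.sum())

    @property
    def group_means(self) -> np.ndarray:
        return np.array([g.mean() for g in self.groups])

    @property
    def grand_mean(self) -> float:
        return float(np.concatenate(self.groups).mean())


@dataclass(frozen=True)
class AnovaResult:
    """One-way F-test decomposition."""

    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    f_statistic: float
    p_value: float
    reject_null: bool
    alpha: float
    decision_rule: str = "standard"

    def as_dict(self) -> dict:
        return {
            "ss_between": self.ss_between, "df_between": self.df_between,
            "ms_between": self.ms_between, "ss_within": self.ss_within,
            "df_within": self.df_within, "ms_within": self.ms_within,
            "f_statistic": self.f_statistic, "p_value": self.p_value,
            "reject": self.reject_null,
        }


@dataclass(frozen=True)
class AnovaEffect:
    """One tested effect row of a factorial decomposition."""

    name: str
    ss: float
    df: int
    ms: float
    f_statistic: float
    p_value: float
    reject_null: bool


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Balanced two-way decomposition: main effects, optional interaction, residual."""

    effects: tuple[AnovaEffect, ...]
    residual_ss: float
    residual_df: int
    residual_ms: float
    ss_total: float
    alpha: float
    decision_rule: str = "standard"

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {"effect": e.name, "ss": e.ss, "df": e.df, "ms": e.ms,
             "f_statistic": e.f_statistic, "p_value": e.p_value,
             "reject": e.reject_null}
            for e in self.effects
        ]
        rows.append({"effect": "residual", "ss": self.residual_ss,
                     "df": self.residual_df, "ms": self.residual_ms,
                     "f_statistic": np.nan, "p_value": np.nan, "reject": None})
        return pd.DataFrame(rows).set_index("effect")


@dataclass(frozen=True)
class TukeyComparison:
    """One pairwise comparison under Tukey's HSD.

    ``reject`` is true exactly when the family-level confidence interval
    ``[lower, upper]`` excludes zero.
    """

    group_a: str
    group_b: str
    meandiff: float
    lower: float
    upper: float
    reject: bool
    family_alpha: float


@lru_cache(maxsize=4096)
def _studentized_range_quantile(alpha: float, k: int, df: int) -> float:
    # studentized_range.ppf is expensive (~0.1 s); (alpha, k, df) recur
    # constantly across Tukey families, so memoise
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def f_tail_probability(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability ``P(F_{df1,df2} >= f)``."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if f < 0:
        raise ValueError("F statistic must be non-negative")
    return float(stats.f.sf(f, df1, df2))


def f_critical_value(alpha: float, df1: int, df2: int) -> float:
    """Upper ``alpha`` quantile of the F distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.isf(alpha, df1, df2))


def _decide(f: float, p: float, alpha: float, df1: int, df2: int, rule: str) -> bool:
    if rule == "standard":
        return bool(p < alpha)
    if rule == "paper":
        # compatibility mode: inverted inequality (see module docstring)
        return bool(f < f_critical_value(alpha, df1, df2))
    raise ValueError(f"unknown decision rule {rule!r}; expected one of {DECISION_RULES}")


def one_way_anova(
    data: GroupedObservations, alpha: float = 0.05, *, decision_rule: str = "standard"
) -> AnovaResult:
    """One-way fixed-effects ANOVA across the groups of ``data``.

    Raises :class:`DegenerateDataError` when the pooled within-group sum of
    squares is zero (the F denominator is undefined), naming the constant
    groups.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = data.k
    n_i = data.sizes
    n_total = data.n_total
    df_between = k - 1
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("need at least one residual degree of freedom (N - k >= 1)")

    means = data.group_means
    grand = data.grand_mean
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - mu) ** 2) for g, mu in zip(data.groups, means)))
    if ss_within == 0.0:
        constant = [l for l, g in zip(data.labels, data.groups) if np.ptp(g) == 0]
        raise DegenerateDataError(
            "zero within-group variance (F denominator undefined); "
            f"constant groups: {constant}"
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = f_tail_probability(f, df_between, df_within)
    return AnovaResult(
        ss_between=ss_between, df_between=df_between, ms_between=ms_between,
        ss_within=ss_within, df_within=df_within, ms_within=ms_within,
        f_statistic=f, p_value=p,
        reject_null=_decide(f, p, alpha, df_between, df_within, decision_rule),
        alpha=alpha, decision_rule=decision_rule,
    )


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    alpha: float = 0.05,
    *,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
    decision_rule: str = "standard",
) -> TwoWayAnovaResult:
    """Balanced two-way fixed-effects ANOVA.

    Requires a balanced layout (equal replicates ``r`` in every cell of the
    ``a x b`` design); raises :class:`UnbalancedDesignError` otherwise.  With
    ``r == 1`` the additive model is fitted: the interaction is not estimable
    and the cell-residual term (df ``(a-1)(b-1)``) serves as the error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = np.asarray(values, dtype=float).ravel()
    fa = np.asarray(factor_a).ravel()
    fb = np.asarray(factor_b).ravel()
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factor labels must have equal length")

    a_levels = list(dict.fromkeys(fa))
    b_levels = list(dict.fromkeys(fb))
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least two levels")

    cell_counts = {}
    for la, lb in zip(fa, fb):
        cell_counts[(la, lb)] = cell_counts.get((la, lb), 0) + 1
    counts = set(cell_counts.values())
    if len(cell_counts) != a * b or len(counts) != 1:
        raise UnbalancedDesignError(
            "two-way layout must be balanced (equal replicates in every cell)"
        )
    r = counts.pop()

    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    mean_a = {l: y[fa == l].mean() for l in a_levels}
    mean_b = {l: y[fb == l].mean() for l in b_levels}
    cell_mean = {
        (la, lb): y[(fa == la) & (fb == lb)].mean()
        for la in a_levels for lb in b_levels
    }
    ss_a = float(r * b * sum((mean_a[l] - grand) ** 2 for l in a_levels))
    ss_b = float(r * a * sum((mean_b[l] - grand) ** 2 for l in b_levels))
    ss_cells = float(r * sum((cell_mean[c] - grand) ** 2 for c in cell_mean))
    ss_inter = ss_cells - ss_a - ss_b

    if r >= 2:
        resid_ss = ss_total - ss_cells
        resid_df = a * b * (r - 1)
        tested = [
            (factor_names[0], ss_a, a - 1),
            (factor_names[1], ss_b, b - 1),
            ("interaction", ss_inter, (a - 1) * (b - 1)),
        ]
    else:
        # single replicate: additive model, interaction term is the error
        resid_ss = ss_total - ss_a - ss_b
        resid_df = (a - 1) * (b - 1)
        tested = [
            (factor_names[0], ss_a, a - 1),
            (factor_names[1], ss_b, b - 1),
        ]
    if resid_df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    resid_ss = max(resid_ss, 0.0)
    if resid_ss == 0.0:
        raise DegenerateDataError(
            "zero residual variance in two-way layout (F denominator undefined)"
        )
    resid_ms = resid_ss / resid_df

    effects = []
    for name, ss, df in tested:
        ms = ss / df
        f = ms / resid_ms
        p = f_tail_probability(f, df, resid_df)
        effects.append(AnovaEffect(
            name=name, ss=ss, df=df, ms=ms, f_statistic=f, p_value=p,
            reject_null=_decide(f, p, alpha, df, resid_df, decision_rule),
        ))
    return TwoWayAnovaResult(
        effects=tuple(effects), residual_ss=float(resid_ss), residual_df=resid_df,
        residual_ms=float(resid_ms), ss_total=ss_total, alpha=alpha,
        decision_rule=decision_rule,
    )


def tukey_hsd(
    data: GroupedObservations, family_alpha: float = 0.05
) -> list[TukeyComparison]:
    """Tukey HSD comparisons for every unordered pair of groups.

    Interval half-width for the pair (a, b) is::

        q(1 - family_alpha; k, df_within) / sqrt(2)
            * sqrt(MS_within * (1/n_a + 1/n_b))

    which reduces to the classic ``q * sqrt(MS_within / n)`` for equal group
    sizes and is the Tukey-Kramer adjustment otherwise.  ``meandiff`` is
    ``mean(b) - mean(a)`` with groups in input order.
    """
    # reuse the one-way machinery for MS_within and its df (and its
    # degenerate-variance guard)
    aov = one_way_anova(data, alpha=0.5)  # alpha irrelevant here
    q = _studentized_range_quantile(family_alpha, data.k, aov.df_within)
    means = data.group_means
    sizes = data.sizes
    out = []
    for i, j in itertools.combinations(range(data.k), 2):
        diff = float(means[j] - means[i])
        half = q / np.sqrt(2.0) * np.sqrt(aov.ms_within * (1.0 / sizes[i] + 1.0 / sizes[j]))
        lower, upper = diff - half, diff + half
        out.append(TukeyComparison(
            group_a=data.labels[i], group_b=data.labels[j],
            meandiff=diff, lower=float(lower), upper=float(upper),
            reject=bool(lower > 0 or upper < 0), family_alpha=family_alpha,
        ))
    return out


def windowed_counts(genome, motifs: Sequence, window_size: int) -> pd.DataFrame:
    """Per-motif occurrence counts in non-overlapping windows of one genome.

    Windows are ``[i*w, (i+1)*w)``; an occurrence belongs to the window
    containing its start; the trailing partial window is dropped.  Returns a
    motif x window integer DataFrame.  These window counts are the replicate
    observations the ANOVA layer consumes.
    """
    patterns = [m if isinstance(m, MotifPattern) else MotifPattern(m) for m in motifs]
    if not patterns:
        raise ValueError("at least one motif is required")
    max_m = max(p.length for p in patterns)
    if window_size < 10 * max_m:
        raise ValueError(
            f"window_size must be >= 10x the longest motif ({10 * max_m})"
        )
    length = len(genome.residues) if hasattr(genome, "residues") else len(genome)
    n_windows = length // window_size
    if n_windows < 1:
        raise ValueError("window_size exceeds the sequence length")
    table = np.zeros((len(patterns), n_windows), dtype=int)
    for row, pat in enumerate(patterns):
        starts = np.asarray(find_occurrences(genome, pat).starts, dtype=np.int64)
        if starts.size:
            idx = starts // window_size
            idx = idx[idx < n_windows]  # starts in the dropped partial window
            np.add.at(table[row], idx, 1)
    return pd.DataFrame(
        table, index=[p.motif for p in patterns], columns=range(n_windows)
    )


def panel_window_counts(
    genomes: Iterable, motifs: Sequence, window_size: int
) -> pd.DataFrame:
    """Tidy window counts for a panel: columns genome, motif, window, count."""
    rows = []
    for g in genomes:
        wc = windowed_counts(g, motifs, window_size)
        for motif in wc.index:
            for window in wc.columns:
                rows.append({
                    "genome": g.id, "motif": motif,
                    "window": int(window), "count": int(wc.loc[motif, window]),
                })
    return pd.DataFrame(rows)
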