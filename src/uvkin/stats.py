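"""Categorical statistics battery for isolate phenotype and treatment data.

Implements, from first principles, the four tests routinely applied to
plate-count and isolate-phenotype tables:

* Pearson chi-square for r×c count tables, with the Yates continuity
  correction on 2×2 tables;
* Fisher's exact test for 2×2 tables, two-sided by probability-mass
  ordering (the R ``fisher.test`` convention): the p-value is the sum of
  hypergeometric probabilities of all tables with the observed margins
  that are no more likely than the observed one;
* the Kruskal–Wallis rank test with mid-ranks and the standard tie
  correction;
* two-way ANOVA with interaction for balanced designs (for balanced
  data the Type I/II/III sums-of-squares distinction vanishes).

Test statistics are computed directly from their defining formulas;
only the reference distributions (chi-square, F) come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import UsageError, ValidationError

__all__ = [
    "ContingencyTable",
    "TestResult",
    "TreatmentGrid",
    "chisq_test",
    "fisher_exact",
    "kruskal_wallis",
    "two_way_anova",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r×c table of nonnegative integer counts with axis labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __init__(self, counts, row_labels=None, col_labels=None) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValidationError("contingency table must be 2-dimensional")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("contingency cells must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("contingency cells must be nonnegative")
        r, c = counts.shape
        if r < 2 or c < 2:
            raise ValidationError("need at least 2 rows and 2 columns")
        if counts.sum() == 0:
            raise ValidationError("grand total must be positive")
        row_labels = tuple(map(str, row_labels)) if row_labels is not None else tuple(
            f"r{i}" for i in range(r)
        )
        col_labels = tuple(map(str, col_labels)) if col_labels is not None else tuple(
            f"c{j}" for j in range(c)
        )
        if len(row_labels) != r or len(col_labels) != c:
            raise ValidationError("label lengths must match table shape")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", row_labels)
        object.__setattr__(self, "col_labels", col_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is the (numerator) degrees of freedom and is None for exact
    tests; ``df_denom`` is set only for F tests. ``flags`` carries
    degenerate-case annotations such as ``zero_variance``.
    """

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    df_denom: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {"statistic": self.statistic, "p_value": self.p_value, "method": self.method}
        if self.df is not None:
            d["df"] = self.df
        if self.df_denom is not None:
            d["df_denom"] = self.df_denom
        if self.flags:
            d["flags"] = list(self.flags)
        return d


def chisq_test(table: ContingencyTable, continuity_correction: bool = True) -> TestResult:
    """Pearson's chi-square test of independence on an r×c count table.

    Expected counts are the usual margin products E_ij = R_i C_j / N.
    With ``continuity_correction`` the Yates term max(|O-E|-0.5, 0)
    replaces |O-E| — on 2×2 tables only, the standard scope of the
    correction.  The p-value is the upper tail of the chi-square
    distribution with (r-1)(c-1) degrees of freedom.
    """
    obs = table.counts.astype(float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValidationError("degenerate table: a row or column margin is zero")
    n = obs.sum()
    expected = np.outer(rows, cols) / n
    dev = np.abs(obs - expected)
    if continuity_correction and obs.shape == (2, 2):
        dev = np.maximum(dev - 0.5, 0.0)
        method = "pearson-chisq-yates"
    else:
        method = "pearson-chisq"
    stat = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_sps.chi2.sf(stat, df))
    return TestResult(statistic=stat, p_value=p, method=method, df=df)


def _hypergeom_pmf_exact(a: int, r1: int, r2: int, c1: int) -> float:
    """P(top-left cell = a) for fixed margins, from exact binomials."""
    num = math.comb(r1, a) * math.comb(r2, c1 - a)
    den = math.comb(r1 + r2, c1)
    return num / den


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Fisher's exact test on a 2×2 table, two-sided.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of tables no more likely than the
    observed one (within a 1e-7 relative slack).  Probabilities share
    the denominator C(N, c1), so the comparison and the sum are done on
    exact integer numerators — the returned p of a full-mass sum is
    exactly 1.
    """
    if table.shape != (2, 2):
        raise UsageError("fisher_exact is defined for 2x2 tables only")
    (a, b), (c, d) = (int(x) for x in table.counts[0]), (
        int(x) for x in table.counts[1]
    )
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    den = math.comb(r1 + r2, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    cutoff = num_obs + num_obs // 10**7  # integer form of the 1e-7 slack
    total = sum(
        n
        for x in range(lo, hi + 1)
        if (n := math.comb(r1, x) * math.comb(r2, c1 - x)) <= cutoff
    )
    return TestResult(statistic=num_obs / den, p_value=min(total / den, 1.0),
                      method="fisher-exact-2x2")


def kruskal_wallis(groups: list[list[float]]) -> TestResult:
    """Kruskal–Wallis rank test across two or more groups.

    Pooled observations receive mid-ranks; the statistic

        H = 12/(N(N+1)) * sum_i n_i (rbar_i - (N+1)/2)^2

    is divided by the tie correction 1 - sum(t^3 - t)/(N^3 - N).  When
    every observation is identical the statistic is 0 and p = 1 (there
    is no rank information, not an error).  p comes from the chi-square
    approximation with (groups - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise UsageError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise UsageError("every group must be nonempty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    if n < 3:
        raise UsageError("need at least 3 observations in total")
    df = len(groups) - 1
    ranks = _sps.rankdata(pooled)
    mean_rank = (n + 1) / 2.0
    h = 0.0
    start = 0
    for s in sizes:
        rbar = ranks[start : start + s].mean()
        h += s * (rbar - mean_rank) ** 2
        start += s
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # all observations identical
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal-wallis",
                          df=df, flags=("no_rank_information",))
    h /= denom
    p = float(_sps.chi2.sf(h, df))
    return TestResult(statistic=float(h), p_value=p, method="kruskal-wallis", df=df)


@dataclass(frozen=True)
class TreatmentGrid:
    """Balanced replicate CFU counts indexed by treatment × exposure time.

    ``values`` has shape (levels_a, levels_b, replicates); ``levels_a``
    are treatment labels (e.g. extract concentrations in mg/ml plus
    controls) and ``levels_b`` exposure times in minutes.
    """

    values: np.ndarray
    levels_a: tuple[str, ...]
    levels_b: tuple[str, ...]

    def __init__(self, values, levels_a=None, levels_b=None) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValidationError("grid must be (levels_a, levels_b, replicates)")
        a, b, r = values.shape
        if a < 2 or b < 2:
            raise ValidationError("need at least 2 levels per factor")
        if r < 1:
            raise ValidationError("need at least 1 replicate per cell")
        if not np.isfinite(values).all():
            raise ValidationError("grid values must be finite")
        levels_a = tuple(map(str, levels_a)) if levels_a is not None else tuple(
            f"a{i}" for i in range(a)
        )
        levels_b = tuple(map(str, levels_b)) if levels_b is not None else tuple(
            f"b{j}" for j in range(b)
        )
        if len(levels_a) != a or len(levels_b) != b:
            raise ValidationError("level labels must match grid shape")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "levels_a", levels_a)
        object.__setattr__(self, "levels_b", levels_b)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TreatmentGrid":
        """Build a grid from long-format columns treatment/time_min/cfu.

        The design must be balanced: every (treatment, time) cell must
        hold the same number of replicates.
        """
        required = {"treatment", "time_min", "cfu"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        sizes = df.groupby(["treatment", "time_min"]).size()
        levels_a = sorted(df["treatment"].unique(), key=str)
        levels_b = sorted(df["time_min"].unique())
        if len(sizes) != len(levels_a) * len(levels_b) or sizes.nunique() != 1:
            raise ValidationError(
                "unbalanced design: every treatment x time cell needs the same "
                "replicate count; balance the data or subsample before testing"
            )
        r = int(sizes.iloc[0])
        values = np.empty((len(levels_a), len(levels_b), r))
        for i, ta in enumerate(levels_a):
            for j, tb in enumerate(levels_b):
                cell = df[(df["treatment"] == ta) & (df["time_min"] == tb)]["cfu"]
                values[i, j, :] = cell.to_numpy()
        return cls(values, levels_a=[str(x) for x in levels_a],
                   levels_b=[str(x) for x in levels_b])

    def to_long(self) -> pd.DataFrame:
        a, b, r = self.values.shape
        rows = []
        for i in range(a):
            for j in range(b):
                for rep in range(r):
                    rows.append(
                        {
                            "treatment": self.levels_a[i],
                            "time_min": self.levels_b[j],
                            "replicate": rep + 1,
                            "cfu": self.values[i, j, rep],
                        }
                    )
        return pd.DataFrame(rows)


def two_way_anova(grid: TreatmentGrid) -> dict[str, TestResult]:
    """Two-way ANOVA with interaction on a balanced treatment grid.

    Uses the standard balanced decomposition

        SS_total = SS_A + SS_B + SS_AB + SS_error

    with F ratios against MS_error and p-values from the F distribution.
    The interaction term requires >= 2 replicates per cell.  When
    MS_error is zero, a term with positive SS reports F = +inf (flagged
    ``zero_error_variance``); an all-constant grid reports every F as 0
    with a ``zero_variance`` flag.

    Returns a dict with keys ``"treatment"``, ``"time"`` and
    ``"interaction"``.
    """
    y = grid.values
    a, b, r = y.shape
    if r < 2:
        raise ValidationError("interaction testing needs >= 2 replicates per cell")
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)
    ss_a = b * r * float(((mean_a - grand) ** 2).sum())
    ss_b = a * r * float(((mean_b - grand) ** 2).sum())
    ss_ab = r * float(
        ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_err = float(((y - mean_ab[:, :, None]) ** 2).sum())
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (r - 1)
    ms_err = ss_err / df_err
    all_zero = ss_a == 0 and ss_b == 0 and ss_ab == 0 and ss_err == 0

    def term(name: str, ss: float, df: int) -> TestResult:
        flags: tuple[str, ...] = ()
        if all_zero:
            return TestResult(0.0, 1.0, "two-way-anova", df=df, df_denom=df_err,
                              flags=("zero_variance",))
        ms = ss / df
        if ms_err == 0:
            if ss > 0:
                return TestResult(math.inf, 0.0, "two-way-anova", df=df,
                                  df_denom=df_err, flags=("zero_error_variance",))
            return TestResult(0.0, 1.0, "two-way-anova", df=df, df_denom=df_err,
                              flags=("zero_error_variance",))
        f = ms / ms_err
        p = float(_sps.f.sf(f, df, df_err))
        return TestResult(float(f), p, "two-way-anova", df=df, df_denom=df_err,
                          flags=flags)

    return {
        "treatment": term("treatment", ss_a, df_a),
        "time": term("time", ss_b, df_b),
        "interaction": term("interaction", ss_ab, df_ab),
    }
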