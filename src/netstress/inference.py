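"""Statistical battery for the 2 (group) x 2 (pre/post) strength design.

The primary model is a repeated-measures GLM with diagnostic group (PTSD vs
MDD) as the between-subject factor and scan (pre vs post stressor) as the
within-subject factor, with network strength as the outcome.  With a 2x2
design the three F tests reduce exactly to t-tests:

* group main effect      — independent t on per-subject scan means, F = t^2
* group x scan interaction — independent t on post-minus-pre differences,
  F = t^2
* scan (stress) main effect — one-sample t on the unweighted average of the
  two group mean differences, using the pooled difference variance

all on df = (1, N - 2).  This algebraic reduction is the implementation and
doubles as its own oracle.  The module also provides the follow-up battery:
within-group paired contrasts (simple effects), between-group contrasts with
percent differences, the covariate-adjusted interaction test, delta-strength
correlations against symptom severity, 2x2 chi-square and Mann-Whitney
comparisons for cohort tables, and Benjamini-Hochberg FDR adjustment for the
nodal exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "CohortTable",
    "AnovaResult",
    "EffectContrast",
    "CorrelationResult",
    "ContingencyResult",
    "mixed_anova_2x2",
    "simple_effect",
    "group_contrast",
    "percent_difference",
    "ancova_interaction",
    "correlation_test",
    "correlation_p",
    "chi_square_2x2",
    "mann_whitney",
    "fdr_adjust",
    "duration_analysis",
]

GROUPS = ("PTSD", "MDD")


@dataclass(frozen=True)
class AnovaResult:
    """One effect's F test from the repeated-measures GLM."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be nonnegative")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        # invariant: p is the upper tail of F(df1, df2)
        expected = float(stats.f.sf(self.F, self.df1, self.df2))
        if abs(expected - self.p) > 1e-10:
            raise ValueError("p inconsistent with F and its degrees of freedom")


@dataclass(frozen=True)
class EffectContrast:
    """A mean-difference contrast (paired or independent).

    ``mean_difference`` is the magnitude of the contrast with its direction in
    ``direction``; ``signed_difference`` keeps the raw signed value used in
    arithmetic (post minus pre for within contrasts, PTSD minus MDD for
    between contrasts).
    """

    label: str
    mean_difference: float
    sem: float
    p: float
    n: int
    df: int
    t: float
    direction: str
    signed_difference: float

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValueError("r must lie in [-1, 1]")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class ContingencyResult:
    counts: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p: float
    df: int = 1


@dataclass(frozen=True)
class CohortTable:
    """One row per subject: group, pre/post strength, covariates, scores.

    ``subjects`` must contain columns ``subject_id``, ``group`` (PTSD/MDD),
    ``strength_pre``, ``strength_post``; any further numeric columns are
    treated as covariates or symptom scores and addressed by name.
    """

    subjects: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "group", "strength_pre", "strength_post")

    def __post_init__(self) -> None:
        df = self.subjects.copy().reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids {dup[:5]}")
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group labels {bad}; allowed {list(GROUPS)}")
        for g in GROUPS:
            if (df["group"] == g).sum() == 0:
                raise ValueError(f"group {g} is empty")
        for col in ("strength_pre", "strength_post"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"missing/non-numeric values in {col}")
            df[col] = vals.astype(float)
        object.__setattr__(self, "subjects", df)

    def group_values(self, group: str, column: str) -> np.ndarray:
        return self.subjects.loc[self.subjects["group"] == group, column].to_numpy(float)

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def diffs(self) -> np.ndarray:
        """Post minus pre, aligned with the table's row order."""
        return (self.subjects["strength_post"] - self.subjects["strength_pre"]).to_numpy(float)

    @property
    def means(self) -> np.ndarray:
        return (
            (self.subjects["strength_post"] + self.subjects["strength_pre"]) / 2.0
        ).to_numpy(float)


def _direction(signed: float) -> str:
    if signed > 0:
        return "increase"
    if signed < 0:
        return "decrease"
    return "none"


def _pooled_t(
    x: np.ndarray, y: np.ndarray, zero_as_null: bool = False
) -> tuple[float, float, int]:
    """Pooled-variance independent t; returns (t, se_diff, df).

    ``zero_as_null`` maps the all-constant degenerate case (zero variance AND
    zero mean difference) to t = 0 instead of erroring.
    """
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if zero_as_null and x.mean() == y.mean():
            return 0.0, 0.0, df
        raise ValueError("zero pooled variance: contrast is degenerate")
    return (x.mean() - y.mean()) / se, se, df


def mixed_anova_2x2(cohort: CohortTable) -> dict[str, AnovaResult]:
    """Group, stress and group x stress F tests, each on df (1, N-2)."""
    g1 = cohort.subjects["group"] == "PTSD"
    g2 = cohort.subjects["group"] == "MDD"
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs >=2 subjects")
    n1, n2 = int(g1.sum()), int(g2.sum())
    N = n1 + n2
    means, diffs = cohort.means, cohort.diffs

    def f_from_t(t: float, effect: str) -> AnovaResult:
        F = float(t * t)
        return AnovaResult(effect=effect, F=F, df1=1, df2=N - 2,
                           p=float(stats.f.sf(F, 1, N - 2)))

    t_group, _, _ = _pooled_t(means[g1.to_numpy()], means[g2.to_numpy()],
                              zero_as_null=True)
    t_inter, _, _ = _pooled_t(diffs[g1.to_numpy()], diffs[g2.to_numpy()],
                              zero_as_null=True)

    d1, d2 = diffs[g1.to_numpy()], diffs[g2.to_numpy()]
    sp2 = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (N - 2)
    if sp2 == 0.0 and (d1.mean() + d2.mean()) == 0.0:
        # all differences identical and zero: F = 0 by convention
        t_stress = 0.0
    else:
        if sp2 == 0.0:
            raise ValueError("zero variance in difference scores")
        # unweighted mean of the two group mean-differences
        m = 0.5 * (d1.mean() + d2.mean())
        se = 0.5 * np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t_stress = m / se
    return {
        "group": f_from_t(t_group, "group"),
        "stress": f_from_t(t_stress, "stress"),
        "interaction": f_from_t(t_inter, "interaction"),
    }


def simple_effect(cohort: CohortTable, group: str) -> EffectContrast:
    """Within-group paired contrast of post vs pre (the simple stress effect)."""
    mask = cohort.subjects["group"] == group
    if mask.sum() < 2:
        raise ValueError(f"group {group!r} needs >=2 subjects")
    diffs = cohort.diffs[mask.to_numpy()]
    n = len(diffs)
    sd = diffs.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(diffs).max())):
        raise ValueError(
            f"all post-minus-pre differences identical in group {group!r}; "
            "sem degenerate"
        )
    sem = sd / np.sqrt(n)
    signed = float(diffs.mean())
    t = signed / sem
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return EffectContrast(
        label=f"stress simple effect ({group})",
        mean_difference=abs(signed),
        sem=float(sem),
        p=p,
        n=n,
        df=n - 1,
        t=float(t),
        direction=_direction(signed),
        signed_difference=signed,
    )


def group_contrast(cohort: CohortTable, condition: str = "post") -> EffectContrast:
    """Independent-samples pooled-t contrast of PTSD vs MDD strength.

    ``condition`` selects the outcome: "pre", "post", or the two-scan "mean".
    The signed difference is PTSD minus MDD.
    """
    if condition == "pre":
        col = cohort.subjects["strength_pre"].to_numpy(float)
    elif condition == "post":
        col = cohort.subjects["strength_post"].to_numpy(float)
    elif condition == "mean":
        col = cohort.means
    else:
        raise ValueError("condition must be 'pre', 'post' or 'mean'")
    g1 = (cohort.subjects["group"] == "PTSD").to_numpy()
    g2 = (cohort.subjects["group"] == "MDD").to_numpy()
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs >=2 subjects")
    t, se, df = _pooled_t(col[g1], col[g2])
    signed = float(col[g1].mean() - col[g2].mean())
    p = float(2.0 * stats.t.sf(abs(t), df))
    return EffectContrast(
        label=f"group contrast ({condition})",
        mean_difference=abs(signed),
        sem=float(se),
        p=p,
        n=int(g1.sum() + g2.sum()),
        df=df,
        t=float(t),
        direction=_direction(signed),
        signed_difference=signed,
    )


def percent_difference(effect: float, reference: float) -> float:
    """Effect expressed as a percentage of a reference mean.

    Convention: stress effects are referenced to the group's pre-stress mean;
    group effects to the MDD mean of the same condition.
    """
    if reference == 0.0:
        raise ValueError("reference mean is zero; percent difference undefined")
    return 100.0 * effect / reference


def ancova_interaction(
    cohort: CohortTable, covariates: Sequence[str]
) -> AnovaResult:
    """Group x stress interaction F with mean-centered between-subject
    covariates added; df2 = N - 2 - (number of retained covariates).

    Covariates that are constant (zero after centering) are dropped, so adding
    one leaves the covariate-free F unchanged.  Collinear covariate pairs are
    an error.
    """
    df = cohort.subjects
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not in cohort table: {missing}")
    C = df.loc[:, list(covariates)].apply(pd.to_numeric, errors="coerce")
    if C.isna().any().any():
        bad = C.columns[C.isna().any()].tolist()
        raise ValueError(f"missing/non-numeric covariate values in {bad}")
    Cc = C - C.mean(axis=0)
    keep = [c for c in Cc.columns if Cc[c].abs().max() > 1e-12]
    Cc = Cc.loc[:, keep]
    if len(keep) >= 2:
        corr = Cc.corr().to_numpy()
        k = len(keep)
        for i in range(k):
            for j in range(i + 1, k):
                if abs(corr[i, j]) > 1.0 - 1e-10:
                    raise ValueError(
                        f"collinear covariates: {keep[i]!r} and {keep[j]!r}"
                    )
    y = cohort.diffs
    g = (df["group"] == "PTSD").to_numpy(float)
    X = np.column_stack([np.ones(len(y)), g, Cc.to_numpy(float)])
    N, pcols = X.shape
    df2 = N - pcols
    if df2 <= 0:
        raise ValueError("not enough subjects for this many covariates")
    if np.linalg.matrix_rank(X) < pcols:
        raise ValueError("design matrix rank-deficient (collinear covariates)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df2
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    if se == 0.0:
        raise ValueError("degenerate design: zero standard error for group term")
    t = beta[1] / se
    F = float(t * t)
    return AnovaResult(
        effect="interaction (covariate-adjusted)",
        F=F,
        df1=1,
        df2=df2,
        p=float(stats.f.sf(F, 1, df2)),
    )


def correlation_test(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Pearson correlation with the two-tailed t-based p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if len(x) < 4:
        raise ValueError("need n >= 4 for the correlation test")
    r = float(np.corrcoef(x, y)[0, 1])
    return correlation_p(r, len(x))


def correlation_p(r: float, n: int) -> CorrelationResult:
    """Two-tailed p for a Pearson r at sample size n, from the exact t
    transform t = r sqrt(n-2) / sqrt(1-r^2) on n-2 df."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return CorrelationResult(r=float(r), n=int(n), p=0.0, degenerate=True)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=float(r), n=int(n), p=p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Pearson chi-square for the table [[a, b], [c, d]], without continuity
    correction (matching SPSS's default "Pearson Chi-Square" row)."""
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("all row and column margins must be positive")
    N = counts.sum()
    chi2 = N * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    return ContingencyResult(
        counts=((int(a), int(b)), (int(c), int(d))),
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, 1)),
    )


def mann_whitney(
    x: Iterable[float], y: Iterable[float], method: str = "auto"
) -> float:
    """Two-tailed Mann-Whitney U p-value.

    ``method='auto'`` uses exact enumeration when both samples have n <= 8 and
    there are no ties, and the normal approximation with tie correction (no
    continuity correction) otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "normal"
    scipy_method = {"exact": "exact", "normal": "asymptotic"}[method]
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=scipy_method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def fdr_adjust(p: Iterable[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (``method='bonferroni'``
    available)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


def duration_analysis(cohort: CohortTable) -> dict[str, AnovaResult]:
    """2x2 GLM with the within factor = scan half (first vs second).

    ``cohort`` carries the half-scan strengths in ``strength_pre`` (first
    half) and ``strength_post`` (second half); effects come back keyed
    ``group``, ``time``, ``interaction``.
    """
    res = mixed_anova_2x2(cohort)
    time = res.pop("stress")
    res["time"] = AnovaResult(effect="time", F=time.F, df1=time.df1,
                              df2=time.df2, p=time.p)
    inter = res["interaction"]
    res["interaction"] = AnovaResult(effect="group x time interaction",
                                     F=inter.F, df1=inter.df1,
                                     df2=inter.df2, p=inter.p)
    return res
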