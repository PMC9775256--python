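"""Inferential statistics for reconstruction-accuracy comparisons.

Two-sample t-test (Welch default, pooled available), one-way ANOVA, and
Tukey HSD (Tukey-Kramer for unbalanced groups) are implemented with
explicit formulas so every number in a study report can be audited from
the raw distance records.  Only the distribution functions (t, F,
studentized range) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import MorphorecError


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float  # mean(x) - mean(y)
    variant: str


def two_sample_t(x, y, variant: str = "welch") -> TTestResult:
    """Two-sided two-sample t-test.

    Welch (default) uses per-sample variances with Welch-Satterthwaite
    degrees of freedom; ``pooled`` assumes equal variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise MorphorecError("each sample needs n >= 2")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    mean_diff = float(x.mean() - y.mean())
    if variant == "welch":
        if vx == 0 and vy == 0:
            raise MorphorecError("both samples have zero variance")
        se2 = vx / nx + vy / ny
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    elif variant == "pooled":
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        if sp2 == 0:
            raise MorphorecError("pooled variance is zero")
        se2 = sp2 * (1 / nx + 1 / ny)
        df = nx + ny - 2
    else:
        raise ValueError(f"variant must be welch or pooled, got {variant!r}")
    t = mean_diff / np.sqrt(se2)
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(
        t=float(t), df=float(df), p=float(p), mean_diff=mean_diff, variant=variant
    )


def paired_t(x, y) -> TTestResult:
    """Paired t-test on per-target differences (supplementary variant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MorphorecError("paired samples must have equal length")
    d = x - y
    if len(d) < 2 or d.var(ddof=1) == 0:
        raise MorphorecError("degenerate paired differences")
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    df = len(d) - 1
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(
        t=float(t), df=float(df), p=float(p), mean_diff=float(d.mean()),
        variant="paired",
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyComparison:
    pair: tuple[str, str]
    diff: float  # mean(first) - mean(second)
    p: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    anova: AnovaResult
    tukey: tuple[TukeyComparison, ...]


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise MorphorecError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise MorphorecError("each group needs n >= 2")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within with
    df = (g - 1, N - g)."""
    gs = _check_groups(groups)
    N = sum(len(g) for g in gs)
    g = len(gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in gs)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in gs)
    df_b, df_w = g - 1, N - g
    ms_within = ss_within / df_w
    if ms_within == 0:
        raise MorphorecError(
            "zero within-group variance: F statistic undefined"
        )
    F = (ss_between / df_b) / ms_within
    p = sps.f.sf(F, df_b, df_w)
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=float(p))


def tukey_hsd(groups, labels=None) -> tuple[TukeyComparison, ...]:
    """All-pairs Tukey HSD (Tukey-Kramer for unequal group sizes).

    For each pair, ``q = |mean_i - mean_j| / sqrt(MS_within/2 (1/n_i + 1/n_j))``
    with the p-value from the studentized-range distribution on
    (g, N - g).
    """
    gs = _check_groups(groups)
    g = len(gs)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(g)]
    labels = list(labels)
    if len(labels) != g:
        raise MorphorecError(f"{len(labels)} labels for {g} groups")
    N = sum(len(x) for x in gs)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in gs)
    df_w = N - g
    ms_within = ss_within / df_w
    if ms_within == 0:
        raise MorphorecError("zero within-group variance: Tukey q undefined")
    out = []
    for i in range(g):
        for j in range(i + 1, g):
            diff = float(gs[i].mean() - gs[j].mean())
            se = np.sqrt(ms_within / 2 * (1 / len(gs[i]) + 1 / len(gs[j])))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, g, df_w))
            out.append(TukeyComparison(pair=(labels[i], labels[j]), diff=diff, p=p))
    return tuple(out)


def anova_with_tukey(groups, labels=None) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD post-hoc table."""
    return AnovaTukeyResult(
        anova=one_way_anova(groups), tukey=tukey_hsd(groups, labels)
    )
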