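"""Hypothesis tests computed from summary statistics (mean, SEM/SD, n).

Anticonvulsant interaction studies rarely publish per-animal data; what
circulates are tables of ED50 +/- SEM (with an effective n) and of brain
concentrations mean +/- SD.  Every test here therefore runs off the
``(mean, dispersion, n)`` triple:

* one-way ANOVA with Dunnett's many-to-one post hoc on ED50 tables,
* Welch's unequal-variance t-test (for comparing an experimental
  combination ED50 against its theoretical additive prediction), and
* the classical pooled-variance two-sample t-test (for brain
  concentration comparisons).

SEM-tagged dispersions are converted internally via ``SD = SEM * sqrt(n)``
with ``n`` the tabulated group size, which is exactly what standard
bioassay software does when it pools within-group variance from an ED50
table.  Dunnett p-values come from the equicorrelated multivariate-t
distribution (scipy's implementation), evaluated on samples
reconstructed to the exact summary moments; the t statistics themselves
are computed directly from the summary formulas.

Every summary-path result is exactly reproducible from raw data carrying
the same moments — a property the test suite checks to 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SummaryGroup",
    "AnovaResult",
    "DunnettComparison",
    "DunnettResult",
    "TTestResult",
    "exact_moment_sample",
    "anova_from_summaries",
    "dunnett_from_summaries",
    "welch_t",
    "welch_t_from_summaries",
    "pooled_t_from_summaries",
]

DispersionKind = Literal["SEM", "SD"]


@dataclass(frozen=True)
class SummaryGroup:
    """A ``(mean, dispersion, n)`` triple with an explicit dispersion tag.

    The tag is never inferred: ED50 tables report SEM, concentration
    tables report SD, and silently confusing the two changes every
    downstream statistic by a factor of sqrt(n).

    ``df`` optionally overrides the error degrees of freedom attached to
    this group's mean (default ``n - 1``); ED50 estimates use
    ``n_effective - 2`` because the dose-response line consumes two
    parameters.
    """

    label: str
    mean: float
    dispersion: float
    dispersion_kind: DispersionKind
    n: int
    df: float | None = None

    def __post_init__(self) -> None:
        if self.dispersion_kind not in ("SEM", "SD"):
            raise ValueError(f"dispersion_kind must be 'SEM' or 'SD', got {self.dispersion_kind!r}")
        if not self.dispersion > 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @property
    def sd(self) -> float:
        if self.dispersion_kind == "SD":
            return self.dispersion
        return self.dispersion * np.sqrt(self.n)

    @property
    def sem(self) -> float:
        if self.dispersion_kind == "SEM":
            return self.dispersion
        return self.dispersion / np.sqrt(self.n)

    @property
    def df_effective(self) -> float:
        return float(self.n - 1) if self.df is None else float(self.df)


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float


@dataclass(frozen=True)
class DunnettComparison:
    label: str
    t_stat: float
    p_value: float
    significant_at_005: bool
    significant_at_001: bool


@dataclass(frozen=True)
class DunnettResult:
    control_label: str
    comparisons: tuple[DunnettComparison, ...]

    def __getitem__(self, label: str) -> DunnettComparison:
        for c in self.comparisons:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class TTestResult:
    """Signed t statistic, its df (fractional for Welch) and two-sided p."""

    t_stat: float
    df: float
    p_value: float
    kind: str = ""


def exact_moment_sample(mean: float, sd: float, n: int) -> np.ndarray:
    """A sample of size ``n`` with exactly the given mean and SD (ddof=1).

    Affine transform of a fixed standardized base sample; used to route
    summary statistics through raw-data procedures without changing any
    moment-determined statistic.
    """
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= base.std(ddof=1)
    return mean + sd * base


def anova_from_summaries(groups: Sequence[SummaryGroup]) -> AnovaResult:
    """One-way fixed-effects ANOVA from group summaries.

    SS_between = sum n_i (m_i - m_bar)^2 around the weighted grand mean;
    SS_within = sum (n_i - 1) SD_i^2.  Identical to the raw-data ANOVA
    for any data with these moments.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd for g in groups], dtype=float)
    if np.all(sd == 0):
        raise ValueError("all group SDs are zero: F undefined")
    grand = float(np.sum(n * m) / np.sum(n))
    ss_between = float(np.sum(n * (m - grand) ** 2))
    ss_within = float(np.sum((n - 1) * sd**2))
    df_between = len(groups) - 1
    df_within = int(np.sum(n - 1))
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_stat=f,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ms_within=ms_within,
    )


def dunnett_from_summaries(
    groups: Sequence[SummaryGroup],
    control_label: str,
    anova: AnovaResult | None = None,
    rng: np.random.Generator | int | None = 0,
) -> DunnettResult:
    """Dunnett's many-to-one comparisons against a control group.

    Each treatment's statistic is
    ``t_i = (m_i - m_0) / sqrt(MS_within * (1/n_i + 1/n_0))`` with
    MS_within pooled over *all* groups (the ANOVA error term).
    Two-sided p-values are adjusted for the k-1 simultaneous
    comparisons via the equicorrelated multivariate t distribution;
    ``rng`` seeds its quasi-Monte-Carlo evaluation for reproducibility.
    """
    groups = list(groups)
    controls = [g for g in groups if g.label == control_label]
    if not controls:
        raise ValueError(f"control group {control_label!r} not found")
    control = controls[0]
    treatments = [g for g in groups if g.label != control_label]
    if not treatments:
        raise ValueError("no treatment groups to compare")
    if anova is None:
        anova = anova_from_summaries(groups)

    t_stats = np.array(
        [
            (g.mean - control.mean)
            / np.sqrt(anova.ms_within * (1.0 / g.n + 1.0 / control.n))
            for g in treatments
        ]
    )
    res = stats.dunnett(
        *(exact_moment_sample(g.mean, g.sd, g.n) for g in treatments),
        control=exact_moment_sample(control.mean, control.sd, control.n),
        alternative="two-sided",
        rng=np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng,
    )
    pvals = np.atleast_1d(res.pvalue)
    comparisons = tuple(
        DunnettComparison(
            label=g.label,
            t_stat=float(t),
            p_value=float(p),
            significant_at_005=bool(p < 0.05),
            significant_at_001=bool(p < 0.01),
        )
        for g, t, p in zip(treatments, t_stats, pvals)
    )
    return DunnettResult(control_label=control_label, comparisons=comparisons)


def welch_t(
    mean_a: float,
    sem_a: float,
    df_a: float,
    mean_b: float,
    sem_b: float,
    df_b: float,
) -> TTestResult:
    """Welch's t from two means with standard errors and per-estimate df.

    ``t = (m_a - m_b) / sqrt(SEM_a^2 + SEM_b^2)`` with
    Welch-Satterthwaite degrees of freedom
    ``(SEM_a^2 + SEM_b^2)^2 / (SEM_a^4/df_a + SEM_b^4/df_b)``.
    """
    if sem_a <= 0 or sem_b <= 0:
        raise ValueError("standard errors must be positive")
    if df_a <= 0 or df_b <= 0:
        raise ValueError("degrees of freedom must be positive")
    va, vb = sem_a**2, sem_b**2
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / df_a + vb**2 / df_b)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t_stat=float(t), df=float(df), p_value=p, kind="welch")


def welch_t_from_summaries(a: SummaryGroup, b: SummaryGroup) -> TTestResult:
    """Welch's unequal-variance t-test between two summary groups."""
    return welch_t(a.mean, a.sem, a.df_effective, b.mean, b.sem, b.df_effective)


def pooled_t_from_summaries(a: SummaryGroup, b: SummaryGroup) -> TTestResult:
    """Classical pooled-variance two-sample t-test, df = n_a + n_b - 2."""
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if sp2 <= 0:
        raise ValueError("pooled variance is zero: t undefined")
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    df = a.n + b.n - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t_stat=float(t), df=float(df), p_value=p, kind="pooled")
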