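"""Shared statistical kernel.

All hypothesis tests used by the pipeline live here with explicit contracts:
one-sample / paired / unpaired t tests, the D'Agostino-Pearson normality
gate, and one-way ANOVA followed by Dunnett many-to-one comparisons against
a control group.  Degenerate inputs (zero variance) raise rather than
returning NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, SpecError

__all__ = [
    "TestResult",
    "one_sample_t",
    "paired_t",
    "unpaired_t",
    "normality_gate",
    "NormalityDecision",
    "anova_dunnett",
    "significance_stars",
]

#: minimum n at which the omnibus normality test is attempted
NORMALITY_MIN_N = 8


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    estimate: float | None = None
    sd: float | None = None
    n: int | None = None
    adjusted: bool = False
    method: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    def as_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": df,
            "p": self.p,
            "estimate": self.estimate,
            "sd": self.sd,
            "n": self.n,
            "adjusted": self.adjusted,
            "method": self.method,
            "stars": self.stars,
            "flags": self.flags,
        }


def significance_stars(p: float) -> str:
    """Figure-legend star convention: p <= 0.05 *, <= 0.01 **, <= 0.001 ***."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(arr)):
        raise SpecError(f"{name} contains non-finite values")
    return arr


def one_sample_t(values, mu0: float) -> TestResult:
    """Two-sided one-sample t test of ``mean(values) == mu0``.

    t = (mean - mu0) / (sd / sqrt(n)) on n - 1 degrees of freedom.
    """
    arr = _as_1d(values, "values")
    n = arr.size
    if n < 2:
        raise SpecError(f"one-sample t needs n >= 2, got {n}")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("one-sample t undefined: zero variance")
    mean = float(arr.mean())
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult("one-sample t", t, n - 1, float(p), estimate=mean, sd=sd, n=n)


def paired_t(pairs) -> TestResult:
    """Two-sided paired t test on within-pair differences (first - second)."""
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise SpecError("pairs must be an (n, 2) array")
    diffs = arr[:, 0] - arr[:, 1]
    try:
        res = one_sample_t(diffs, 0.0)
    except DegenerateDataError:
        raise DegenerateDataError("paired t undefined: constant differences")
    res.test_name = "paired t"
    return res


def unpaired_t(group_a, group_b, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t test (equal-variance Student form by default)."""
    a = _as_1d(group_a, "group_a")
    b = _as_1d(group_b, "group_b")
    if a.size < 2 or b.size < 2:
        raise SpecError("unpaired t needs n >= 2 per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise DegenerateDataError("unpaired t undefined: zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        "unpaired t",
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        estimate=float(a.mean() - b.mean()),
        n=a.size + b.size,
        method="student" if equal_var else "welch",
    )


@dataclass
class NormalityDecision:
    status: str  # "parametric-ok" | "non-normal" | "not-assessed"
    statistic: float | None = None
    p: float | None = None
    n: int = 0


def normality_gate(values, alpha: float = 0.05) -> NormalityDecision:
    """D'Agostino-Pearson omnibus K² normality check, gated on sample size.

    Runs only for n >= 8 (the omnibus test is unreliable below that); smaller
    samples return ``"not-assessed"`` and the pipeline proceeds with
    parametric tests.
    """
    arr = _as_1d(values, "values")
    n = arr.size
    if n < NORMALITY_MIN_N:
        return NormalityDecision("not-assessed", n=n)
    k2, p = sps.normaltest(arr)
    status = "parametric-ok" if p > alpha else "non-normal"
    return NormalityDecision(status, statistic=float(k2), p=float(p), n=n)


def anova_dunnett(groups, control_index: int = 0, rng=0) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA followed by Dunnett many-to-one comparisons.

    Returns the omnibus F result and one adjusted result per non-control
    group, in input order.  ``rng`` seeds the numerical integration of the
    multivariate t distribution used for the Dunnett adjustment, making the
    adjusted p-values reproducible.
    """
    arrays = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise SpecError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise SpecError("each group needs n >= 2")
    f_stat, f_p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_tot = sum(a.size for a in arrays)
    anova = TestResult(
        "one-way ANOVA", float(f_stat), (k - 1, n_tot - k), float(f_p), n=n_tot)

    control = arrays[control_index]
    others = [(i, a) for i, a in enumerate(arrays) if i != control_index]
    dres = sps.dunnett(*(a for _, a in others), control=control, rng=rng)
    per_group: list[TestResult] = []
    for j, (i, a) in enumerate(others):
        per_group.append(
            TestResult(
                f"Dunnett group {i} vs control",
                float(dres.statistic[j]),
                n_tot - k,
                float(dres.pvalue[j]),
                estimate=float(a.mean() - control.mean()),
                n=a.size,
                adjusted=True,
                method="dunnett",
            )
        )
    return anova, per_group
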