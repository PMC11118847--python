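"""Within-group inference: normality gating, paired t-tests, power analysis.

The study design is paired throughout (same subject measured pre/post
exercise, or in both fluids), so the effect size used everywhere is
Cohen's d_z = mean(differences) / sd(differences) — the variant under
which a paired t-test with n pairs has noncentrality d_z * sqrt(n).
Power and minimum-detectable-effect computations use the noncentral t
distribution with n - 1 degrees of freedom; all tests are two-sided
unless requested otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "PairedComparison", "TTestResult", "PowerSpec",
    "shapiro_wilk", "paired_t", "bonferroni",
    "power_paired_t", "required_effect_size",
]


@dataclass(frozen=True)
class PairedComparison:
    """Two same-length measurement vectors on the same subjects, in order."""

    label: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError(f"{self.label}: paired vectors must match in length")
        if a.size < 2:
            raise InsufficientDataError(f"{self.label}: need >= 2 pairs, got {a.size}")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError(f"{self.label}: values must be finite")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float            # Cohen's d_z
    mean_diff: float
    n: int
    p_adjusted: Optional[float] = None


@dataclass(frozen=True)
class PowerSpec:
    """Parameters of a paired-design power computation."""

    n: int
    alpha: float = 0.05
    power: float = 0.80
    sides: str = "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sides not in ("two", "one"):
            raise ValueError(f"sides must be 'two' or 'one', got {self.sides!r}")


def shapiro_wilk(values: Sequence[float]) -> tuple:
    """Shapiro-Wilk W and p, used as a warn-don't-abort normality gate."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise InsufficientDataError(
            f"Shapiro-Wilk is unreliable above n = 5000, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDataError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def paired_t(comp: PairedComparison) -> TTestResult:
    """Two-sided paired-sample t-test with Cohen's d_z.

    Differences are values_b - values_a, so a positive t means b reads
    higher.  Zero-variance differences are a hard error (the test statistic
    is undefined), reported with the comparison label.
    """
    d = comp.values_b - comp.values_a
    n = d.size
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError(
            f"{comp.label}: differences have zero variance; t undefined"
        )
    mean_diff = float(np.mean(d))
    t = mean_diff / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return TTestResult(t=t, df=n - 1, p=p, d=mean_diff / sd,
                       mean_diff=mean_diff, n=n)


def bonferroni(p_values: Sequence[float], family: int) -> list:
    """Bonferroni adjustment: multiply by the family size, cap at 1."""
    if family < 1:
        raise ValueError(f"family must be >= 1, got {family}")
    ps = [float(p) for p in p_values]
    if any(not 0 <= p <= 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * family) for p in ps]


def _nct_tail(q: float, df: int, nc: float) -> float:
    """P(T' <= q) for noncentral t, with a guard for the NaN band scipy's
    implementation produces at large noncentrality (where the tail is
    numerically negligible anyway)."""
    val = float(stats.nct.cdf(q, df, nc))
    if not math.isfinite(val):
        # lower tail far below the bulk of the distribution
        return 0.0 if q < nc else 1.0
    return val


def power_paired_t(d: float, n: int, alpha: float = 0.05,
                   sides: str = "two") -> float:
    """Power of a paired t-test at standardized effect d (Cohen's d_z).

    P(|T'| > t_crit) where T' is noncentral t with df = n - 1 and
    noncentrality d * sqrt(n).
    """
    spec = PowerSpec(n=n, alpha=alpha, power=0.5, sides=sides)  # validates
    df = spec.n - 1
    nc = d * math.sqrt(spec.n)
    if sides == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return (1.0 - _nct_tail(tcrit, df, nc)) + _nct_tail(-tcrit, df, nc)
    tcrit = stats.t.ppf(1 - alpha, df)
    return 1.0 - _nct_tail(tcrit, df, nc)


def required_effect_size(spec: PowerSpec) -> float:
    """Smallest Cohen's d_z reaching the specified power.

    Inverts :func:`power_paired_t` over d in (0, 10] by bisection to an
    accuracy of 1e-6 in power.
    """
    target = spec.power

    def gap(d: float) -> float:
        return power_paired_t(d, spec.n, spec.alpha, spec.sides) - target

    lo, hi = 1e-9, 10.0
    if gap(hi) < 0:
        raise ValueError(
            f"power {target} unattainable for n = {spec.n} within d <= {hi}"
        )
    d = float(optimize.brentq(gap, lo, hi, xtol=1e-10, rtol=8.9e-16))
    assert abs(gap(d)) < 1e-6
    return d


def required_d(n: int, alpha: float = 0.05, power: float = 0.80,
               sides: str = "two") -> float:
    """Convenience wrapper around :func:`required_effect_size`."""
    return required_effect_size(PowerSpec(n=n, alpha=alpha, power=power, sides=sides))
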