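"""Method-agreement statistics for paired saliva/plasma measurements.

For each analyte x cycle-phase x timepoint stratum the package quantifies
agreement between the salivary and plasmatic measurement of the same
analyte with three complementary tools:

* Pearson correlation (linearity of the relationship);
* ordinary least squares (OLS) regression of saliva on plasma (the display
  line of the scatter plots);
* ordinary least products (OLP, also called geometric-mean or reduced
  major axis) regression, which treats both fluids as error-prone.  Its
  slope is sign(r) * sd(saliva)/sd(plasma) and its intercept
  mean(saliva) - b * mean(plasma).  A differential (constant) bias is
  declared when the 95% CI of the intercept excludes 0; a proportional
  bias when the 95% CI of the slope excludes 1;
* the Bland-Altman method of differences: mean difference, +-1.96 SD
  limits of agreement (LoA), exact-t confidence bands for the mean
  difference and each limit, and the OLS regression of differences on
  means whose slope CI excluding 0 signals proportional bias.

The OLP slope CI is the standard analytic geometric-mean-regression
interval: with B = F_{1-alpha}(1, n-2) * (1 - r^2) / (n - 2),

    b_ci = ( b * (sqrt(B + 1) - sqrt(B)),  b * (sqrt(B + 1) + sqrt(B)) )

for b > 0, and the intercept CI endpoints come from a = mean(y) - b* mean(x)
evaluated at the opposing slope-CI endpoints.  A percentile bootstrap of the
same estimator is available as an alternative (``ci_method="bootstrap"``).

Differences are oriented saliva - plasma throughout, so a positive mean
difference means saliva reads higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError

ANALYTE_ORDER = ("DC", "TC", "SB")
PHASE_ORDER = ("F", "L")
TIMEPOINT_ORDER = ("pre", "post")

#: LoA multiplier is the fixed normal-approximation 1.96, never a t quantile;
#: t quantiles are used only for confidence-interval half-widths.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedDataset:
    """Saliva/plasma pairs for one analyte in one cycle-phase x timepoint stratum."""

    analyte: str
    cycle_phase: str
    timepoint: str
    subject_ids: tuple
    plasma: np.ndarray
    saliva: np.ndarray

    def __post_init__(self) -> None:
        plasma = np.asarray(self.plasma, dtype=float)
        saliva = np.asarray(self.saliva, dtype=float)
        object.__setattr__(self, "plasma", plasma)
        object.__setattr__(self, "saliva", saliva)
        if plasma.shape != saliva.shape or plasma.ndim != 1:
            raise ValueError("plasma and saliva must be 1-D arrays of equal length")
        if len(self.subject_ids) != plasma.size:
            raise ValueError("subject_ids length must match the value arrays")
        if plasma.size < 3:
            raise InsufficientDataError(
                f"need >= 3 pairs, got {plasma.size} "
                f"({self.analyte}/{self.cycle_phase}/{self.timepoint})"
            )
        if not (np.all(np.isfinite(plasma)) and np.all(np.isfinite(saliva))):
            raise ValueError("all paired values must be finite")

    @property
    def n(self) -> int:
        return int(self.plasma.size)

    @property
    def label(self) -> str:
        return f"{self.analyte}/{self.cycle_phase}/{self.timepoint}"


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int
    p_adjusted: Optional[float] = None


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    slope_ci: tuple
    slope_se: float
    p: float
    n: int


@dataclass(frozen=True)
class OLPFit:
    """Geometric-mean regression summary: the Table-2-style surface."""

    r: float
    a: float                 # intercept, analyte units
    b: float                 # slope, dimensionless
    a_ci: tuple
    b_ci: tuple
    n: int
    differential_bias: bool  # 0 outside the intercept CI
    proportional_bias: bool  # 1 outside the slope CI


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_diff_ci: tuple
    loa_low_ci: Optional[tuple]
    loa_high_ci: Optional[tuple]
    prop_slope: float
    prop_slope_ci: tuple
    prop_p: float
    n: int
    differential_bias: bool
    proportional_bias: bool
    outside_loa_count: int
    degenerate: bool = False  # sd_diff == 0: LoA collapse, LoA CIs undefined


def _check_variance(x: np.ndarray, what: str) -> None:
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"zero variance in {what}")


def pearson_r(data: PairedDataset) -> PearsonResult:
    """Pearson product-moment correlation with its two-sided p-value."""
    _check_variance(data.plasma, f"plasma values ({data.label})")
    _check_variance(data.saliva, f"saliva values ({data.label})")
    res = stats.pearsonr(data.plasma, data.saliva)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=data.n)


def ols_fit(data: PairedDataset, alpha: float = 0.05) -> OLSFit:
    """OLS line of saliva on plasma with a t-based slope CI on n-2 df."""
    _check_variance(data.plasma, f"plasma values ({data.label})")
    res = stats.linregress(data.plasma, data.saliva)
    tq = stats.t.ppf(1 - alpha / 2, data.n - 2)
    half = tq * res.stderr
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(res.slope - half), float(res.slope + half)),
        slope_se=float(res.stderr),
        p=float(res.pvalue),
        n=data.n,
    )


def _olp_point_estimates(x: np.ndarray, y: np.ndarray) -> tuple:
    r = float(stats.pearsonr(x, y).statistic)
    b = float(np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1))
    a = float(np.mean(y) - b * np.mean(x))
    return r, a, b


def olp_slope_ci_analytic(b: float, r: float, n: int, alpha: float) -> tuple:
    """F-based CI for the geometric-mean regression slope."""
    big_b = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r * r) / (n - 2)
    lo = b * (np.sqrt(big_b + 1) - np.sqrt(big_b))
    hi = b * (np.sqrt(big_b + 1) + np.sqrt(big_b))
    return (float(min(lo, hi)), float(max(lo, hi)))


def olp_bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    n_boot: int = 20_000,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Percentile-bootstrap CIs for the OLP slope and intercept.

    Resamples pairs with replacement; degenerate resamples (zero variance
    in either member) are rejected and redrawn.  Vectorised.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    sx = xb.std(axis=1, ddof=1)
    sy = yb.std(axis=1, ddof=1)
    ok = (sx > 0) & (sy > 0)
    while not np.all(ok):  # redraw degenerate resamples
        bad = np.flatnonzero(~ok)
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        xb, yb = x[idx], y[idx]
        sx = xb.std(axis=1, ddof=1)
        sy = yb.std(axis=1, ddof=1)
        ok = (sx > 0) & (sy > 0)
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / ((n - 1) * sx * sy)
    b = np.sign(r) * sy / sx
    a = yb.mean(axis=1) - b * xb.mean(axis=1)
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    b_lo, b_hi = np.percentile(b, qs)
    a_lo, a_hi = np.percentile(a, qs)
    return (float(b_lo), float(b_hi)), (float(a_lo), float(a_hi))


def olp_fit(
    data: PairedDataset,
    alpha: float = 0.05,
    ci_method: str = "analytic",
    n_boot: int = 20_000,
    rng: Optional[np.random.Generator] = None,
) -> OLPFit:
    """Ordinary least products (geometric-mean) regression of saliva on plasma."""
    _check_variance(data.plasma, f"plasma values ({data.label})")
    _check_variance(data.saliva, f"saliva values ({data.label})")
    x, y = data.plasma, data.saliva
    r, a, b = _olp_point_estimates(x, y)
    if r == 0:
        raise DegenerateDataError(
            f"r = 0: OLP slope sign undefined ({data.label})"
        )
    if ci_method == "analytic":
        b_ci = olp_slope_ci_analytic(b, r, data.n, alpha)
        # intercept CI from a = mean(y) - b* mean(x) at opposing slope endpoints
        mx, my = float(np.mean(x)), float(np.mean(y))
        cand = (my - b_ci[1] * mx, my - b_ci[0] * mx)
        a_ci = (float(min(cand)), float(max(cand)))
    elif ci_method == "bootstrap":
        b_ci, a_ci = olp_bootstrap_ci(x, y, alpha=alpha, n_boot=n_boot, rng=rng)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return OLPFit(
        r=r, a=a, b=b, a_ci=a_ci, b_ci=b_ci, n=data.n,
        differential_bias=not (a_ci[0] <= 0.0 <= a_ci[1]),
        proportional_bias=not (b_ci[0] <= 1.0 <= b_ci[1]),
    )


def bland_altman(data: PairedDataset, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman method of differences with exact-t CI bands.

    Differences are saliva - plasma; means are (saliva + plasma) / 2.
    LoA = mean_diff +- 1.96 sd_diff (sample SD, n-1 denominator).  The CI
    half-width for each limit is t * sd * sqrt(1/n + 1.96^2 / (2(n-1))).
    With sd_diff = 0 the LoA collapse to the mean difference and the LoA
    CIs are undefined; the result is flagged degenerate rather than raised.
    """
    d = data.saliva - data.plasma
    m = (data.saliva + data.plasma) / 2.0
    n = data.n
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_low = mean_diff - LOA_MULTIPLIER * sd_diff
    loa_high = mean_diff + LOA_MULTIPLIER * sd_diff
    tq = stats.t.ppf(1 - alpha / 2, n - 1)

    degenerate = sd_diff == 0.0
    if degenerate:
        mean_diff_ci = (mean_diff, mean_diff)
        loa_low_ci = loa_high_ci = None
        outside = 0
    else:
        half_md = tq * sd_diff / np.sqrt(n)
        mean_diff_ci = (mean_diff - half_md, mean_diff + half_md)
        half_loa = tq * sd_diff * np.sqrt(1.0 / n + LOA_MULTIPLIER**2 / (2 * (n - 1)))
        loa_low_ci = (loa_low - half_loa, loa_low + half_loa)
        loa_high_ci = (loa_high - half_loa, loa_high + half_loa)
        outside = int(np.sum(np.abs(d - mean_diff) > LOA_MULTIPLIER * sd_diff))

    # proportional bias: OLS of differences on means
    if np.ptp(m) == 0:
        raise DegenerateDataError(
            f"zero variance in pair means; differences-on-means slope "
            f"undefined ({data.label})"
        )
    if np.ptp(d) == 0:
        # constant differences: the slope on means is exactly 0
        prop_slope, prop_ci, prop_p = 0.0, (0.0, 0.0), 1.0
    else:
        res = stats.linregress(m, d)
        prop_slope = float(res.slope)
        tq2 = stats.t.ppf(1 - alpha / 2, n - 2)
        if res.stderr == 0.0:
            # exact linear relation of differences on means: CI is a point
            prop_ci = (prop_slope, prop_slope)
            prop_p = 1.0 if prop_slope == 0.0 else 0.0
        else:
            prop_ci = (float(res.slope - tq2 * res.stderr),
                       float(res.slope + tq2 * res.stderr))
            prop_p = float(res.pvalue)

    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        mean_diff_ci=(float(mean_diff_ci[0]), float(mean_diff_ci[1])),
        loa_low_ci=loa_low_ci,
        loa_high_ci=loa_high_ci,
        prop_slope=prop_slope,
        prop_slope_ci=prop_ci,
        prop_p=prop_p,
        n=n,
        differential_bias=not (mean_diff_ci[0] <= 0.0 <= mean_diff_ci[1]),
        proportional_bias=not (prop_ci[0] <= 0.0 <= prop_ci[1]),
        outside_loa_count=outside,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class AgreementRow:
    """All agreement statistics for one stratum, or its failure."""

    dataset: PairedDataset
    pearson: Optional[PearsonResult] = None
    ols: Optional[OLSFit] = None
    olp: Optional[OLPFit] = None
    ba: Optional[BlandAltmanResult] = None
    error: Optional[str] = None


def _stratum_sort_key(ds: PairedDataset) -> tuple:
    def pos(seq, v):
        return seq.index(v) if v in seq else len(seq)
    return (pos(ANALYTE_ORDER, ds.analyte),
            pos(PHASE_ORDER, ds.cycle_phase),
            pos(TIMEPOINT_ORDER, ds.timepoint))


def agreement_suite(
    datasets: Sequence[PairedDataset],
    alpha: float = 0.05,
    bonferroni_family: int = 1,
    ci_method: str = "analytic",
    n_boot: int = 20_000,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Run the full agreement battery on every stratum.

    Rows are ordered analyte (DC, TC, SB) x phase (F, L) x timepoint
    (pre, post).  Correlation p-values are Bonferroni-adjusted when
    ``bonferroni_family > 1``.  Per-stratum failures are recorded in the
    row's ``error`` field without aborting the remaining strata.
    """
    if len(datasets) == 0:
        raise InsufficientDataError("agreement_suite needs at least one dataset")
    if bonferroni_family < 1:
        raise ValueError("bonferroni_family must be >= 1")
    rows = []
    for ds in sorted(datasets, key=_stratum_sort_key):
        try:
            pr = pearson_r(ds)
            if bonferroni_family > 1:
                pr = PearsonResult(r=pr.r, p=pr.p, n=pr.n,
                                   p_adjusted=min(1.0, pr.p * bonferroni_family))
            rows.append(AgreementRow(
                dataset=ds,
                pearson=pr,
                ols=ols_fit(ds, alpha=alpha),
                olp=olp_fit(ds, alpha=alpha, ci_method=ci_method,
                            n_boot=n_boot, rng=rng),
                ba=bland_altman(ds, alpha=alpha),
            ))
        except Exception as exc:  # failed rows marked, remaining rows continue
            rows.append(AgreementRow(dataset=ds, error=f"{type(exc).__name__}: {exc}"))
    return rows


def agreement_table(rows: Iterable[AgreementRow]) -> pd.DataFrame:
    """Regression/correlation summary table (one row per stratum)."""
    recs = []
    for row in rows:
        ds = row.dataset
        rec = {"analyte": ds.analyte, "phase": ds.cycle_phase,
               "timepoint": ds.timepoint, "n": ds.n}
        if row.error is not None:
            rec["error"] = row.error
        else:
            rec.update({
                "r": row.pearson.r, "p_r": row.pearson.p,
                "p_r_adjusted": row.pearson.p_adjusted,
                "a": row.olp.a, "a_lo": row.olp.a_ci[0], "a_hi": row.olp.a_ci[1],
                "b": row.olp.b, "b_lo": row.olp.b_ci[0], "b_hi": row.olp.b_ci[1],
                "ols_slope": row.ols.slope, "ols_intercept": row.ols.intercept,
                "differential_bias": row.olp.differential_bias,
                "proportional_bias": row.olp.proportional_bias,
                "error": None,
            })
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def bland_altman_table(rows: Iterable[AgreementRow]) -> pd.DataFrame:
    """Bland-Altman summary table (one row per stratum)."""
    recs = []
    for row in rows:
        ds = row.dataset
        rec = {"analyte": ds.analyte, "phase": ds.cycle_phase,
               "timepoint": ds.timepoint, "n": ds.n}
        if row.error is not None:
            rec["error"] = row.error
        else:
            ba = row.ba
            rec.update({
                "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "md_lo": ba.mean_diff_ci[0], "md_hi": ba.mean_diff_ci[1],
                "loal_lo": None if ba.loa_low_ci is None else ba.loa_low_ci[0],
                "loal_hi": None if ba.loa_low_ci is None else ba.loa_low_ci[1],
                "loah_lo": None if ba.loa_high_ci is None else ba.loa_high_ci[0],
                "loah_hi": None if ba.loa_high_ci is None else ba.loa_high_ci[1],
                "prop_slope": ba.prop_slope,
                "prop_lo": ba.prop_slope_ci[0], "prop_hi": ba.prop_slope_ci[1],
                "prop_p": ba.prop_p,
                "differential_bias": ba.differential_bias,
                "proportional_bias": ba.proportional_bias,
                "outside_loa_count": ba.outside_loa_count,
                "degenerate": ba.degenerate,
                "error": None,
            })
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def paired_datasets_from_long(conc_long: pd.DataFrame) -> list:
    """Build PairedDatasets from a long table.

    Expects columns ``subject_id, cycle_phase, timepoint, analyte, plasma,
    saliva`` (one row per subject per stratum).
    """
    needed = {"subject_id", "cycle_phase", "timepoint", "analyte", "plasma", "saliva"}
    missing = needed - set(conc_long.columns)
    if missing:
        raise ValueError(f"long concentration table missing columns: {sorted(missing)}")
    out = []
    for (analyte, phase, tp), grp in conc_long.groupby(
            ["analyte", "cycle_phase", "timepoint"], sort=False):
        grp = grp.sort_values("subject_id")
        out.append(PairedDataset(
            analyte=str(analyte), cycle_phase=str(phase), timepoint=str(tp),
            subject_ids=tuple(grp["subject_id"]),
            plasma=grp["plasma"].to_numpy(dtype=float),
            saliva=grp["saliva"].to_numpy(dtype=float),
        ))
    out.sort(key=_stratum_sort_key)
    return out


def pivot_concentrations(conc: pd.DataFrame) -> pd.DataFrame:
    """Pivot a per-specimen concentrations table to the long paired layout.

    Input is the quantification output schema (one row per specimen with
    ``fluid`` in {saliva, plasma} and dc/tc/sb columns); output has one row
    per subject x stratum x analyte with ``plasma`` and ``saliva`` columns.
    Subjects missing either fluid in a stratum are dropped.
    """
    long = conc.melt(
        id_vars=["subject_id", "fluid", "cycle_phase", "timepoint"],
        value_vars=["dc", "tc", "sb"], var_name="analyte", value_name="value",
    )
    long["analyte"] = long["analyte"].str.upper()
    wide = long.pivot_table(
        index=["subject_id", "cycle_phase", "timepoint", "analyte"],
        columns="fluid", values="value", aggfunc="mean",
    ).reset_index()
    wide.columns.name = None
    return wide.dropna(subset=["plasma", "saliva"])
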