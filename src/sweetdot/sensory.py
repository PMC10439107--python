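"""Sensory-panel statistics for time-intensity sweetness ratings.

Two-way ANOVA with sample and timepoint as fixed factors and assessor and
replicate (session) as additive random blocks, Tukey HSD post-hoc within each
timepoint, percent amplification against a reference sample, and the
stimulus-size linear response model with its 95 % confidence band.

For balanced designs the ANOVA uses exact classical sums of squares (fast
enough for Monte-Carlo calibration); unbalanced designs fall back to a
statsmodels OLS with Type-II sums of squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TIMEPOINTS",
    "RatingRecord",
    "AnovaTerm",
    "AnovaResult",
    "TukeyComparison",
    "StimulusResponseFit",
    "records_to_frame",
    "two_way_anova",
    "tukey_by_timepoint",
    "amplification",
    "fit_stimulus_response",
    "predict_deviation",
    "significance_stars",
]

TIMEPOINTS = ("start", "max", "end")

#: Star thresholds per the four-level figure-legend convention (p < threshold).
DEFAULT_STAR_THRESHOLDS = ((0.001, "****"), (0.01, "***"), (0.1, "**"), (0.5, "*"))


@dataclass(frozen=True)
class RatingRecord:
    """One panelist's sweetness intensity for one sample at one timepoint."""

    assessor: str
    sample: str
    session: int
    timepoint: str
    intensity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity <= 100.0):
            raise ValueError(f"intensity {self.intensity} outside [0, 100]")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint {self.timepoint!r} not in {TIMEPOINTS}")


@dataclass(frozen=True)
class AnovaTerm:
    df: int
    ss: float
    ms: float
    f: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaResult:
    terms: Mapping[str, AnovaTerm]
    n_obs: int
    balanced: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": {k: t.df for k, t in self.terms.items()},
                "sum_sq": {k: t.ss for k, t in self.terms.items()},
                "mean_sq": {k: t.ms for k, t in self.terms.items()},
                "F": {k: t.f for k, t in self.terms.items()},
                "p": {k: t.p for k, t in self.terms.items()},
            }
        )


@dataclass(frozen=True)
class TukeyComparison:
    timepoint: str
    sample_a: str
    sample_b: str
    mean_diff: float
    p_adj: float
    reject: bool
    stars: str


def significance_stars(
    p: float, thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS
) -> str:
    """Asterisk coding: the most stringent threshold with p < threshold."""
    for cutoff, mark in sorted(thresholds):
        if p < cutoff:
            return mark
    return ""


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "assessor": [r.assessor for r in records],
            "sample": [r.sample for r in records],
            "session": [r.session for r in records],
            "timepoint": [r.timepoint for r in records],
            "intensity": [r.intensity for r in records],
        }
    )


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["sample", "timepoint", "assessor", "session"], observed=True).size()
    full = (
        df["sample"].nunique()
        * df["timepoint"].nunique()
        * df["assessor"].nunique()
        * df["session"].nunique()
    )
    return len(counts) == full and counts.nunique() == 1


def two_way_anova(records) -> AnovaResult:
    """Mixed two-way ANOVA of intensity on sample x timepoint.

    Fixed effects: sample, timepoint, their interaction.  Random blocks:
    assessor and session, entered additively; all terms are tested against
    the residual mean square.  Requires >= 2 samples, the 3 timepoints and
    >= 2 assessors.
    """
    df = records_to_frame(records)
    if df["sample"].nunique() < 2:
        raise ValueError("need >= 2 samples")
    if df["assessor"].nunique() < 2:
        raise ValueError("need >= 2 assessors")
    if df["timepoint"].nunique() < 2:
        raise ValueError("need >= 2 timepoints")
    if _is_balanced(df):
        return _balanced_anova(df)
    warnings.warn("unbalanced design: using Type-II sums of squares", stacklevel=2)
    return _ols_anova(df)


def _balanced_anova(df: pd.DataFrame) -> AnovaResult:
    y = df["intensity"].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())

    def main_ss(col: str) -> tuple[float, int]:
        g = df.groupby(col, observed=True)["intensity"]
        m = g.mean()
        cnt = g.size()
        return float((cnt * (m - grand) ** 2).sum()), len(m) - 1

    ss_sample, df_sample = main_ss("sample")
    ss_tp, df_tp = main_ss("timepoint")
    ss_ass, df_ass = main_ss("assessor")
    ss_ses, df_ses = main_ss("session")

    cell = df.groupby(["sample", "timepoint"], observed=True)["intensity"].agg(["mean", "size"])
    m_s = df.groupby("sample", observed=True)["intensity"].mean()
    m_t = df.groupby("timepoint", observed=True)["intensity"].mean()
    dev = (
        cell["mean"]
        - m_s.reindex(cell.index.get_level_values(0)).to_numpy()
        - m_t.reindex(cell.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_int = float((cell["size"] * dev**2).sum())
    df_int = df_sample * df_tp

    explained = ss_sample + ss_tp + ss_int + ss_ass + ss_ses
    ss_res = max(sst - explained, 0.0)
    df_res = n - 1 - (df_sample + df_tp + df_int + df_ass + df_ses)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom: design saturated")
    ms_res = ss_res / df_res

    def term(ss: float, dof: int) -> AnovaTerm:
        ms = ss / dof
        f = ms / ms_res
        p = float(stats.f.sf(f, dof, df_res))
        return AnovaTerm(dof, ss, ms, f, p)

    terms = {
        "sample": term(ss_sample, df_sample),
        "timepoint": term(ss_tp, df_tp),
        "sample:timepoint": term(ss_int, df_int),
        "assessor": term(ss_ass, df_ass),
        "session": term(ss_ses, df_ses),
        "residual": AnovaTerm(df_res, ss_res, ms_res, None, None),
    }
    return AnovaResult(terms, n, balanced=True)


def _ols_anova(df: pd.DataFrame) -> AnovaResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols(
        "intensity ~ C(sample) * C(timepoint) + C(assessor) + C(session)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(sample)": "sample",
        "C(timepoint)": "timepoint",
        "C(sample):C(timepoint)": "sample:timepoint",
        "C(assessor)": "assessor",
        "C(session)": "session",
        "Residual": "residual",
    }
    terms: dict[str, AnovaTerm] = {}
    for raw, name in rename.items():
        if raw not in table.index:
            continue
        row = table.loc[raw]
        dof = int(row["df"])
        ss = float(row["sum_sq"])
        ms = ss / dof if dof else math.nan
        f = float(row["F"]) if np.isfinite(row.get("F", np.nan)) else None
        p = float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else None
        terms[name] = AnovaTerm(dof, ss, ms, f, p)
    return AnovaResult(terms, len(df), balanced=False)


def tukey_by_timepoint(
    records,
    timepoint: str,
    alpha: float = 0.05,
    star_thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS,
) -> list[TukeyComparison]:
    """All pairwise sample comparisons at one timepoint, Tukey-HSD adjusted."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = records_to_frame(records)
    sub = df[df["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"timepoint {timepoint!r} not present")
    if sub["sample"].nunique() < 2:
        return []
    res = pairwise_tukeyhsd(
        sub["intensity"].to_numpy(), sub["sample"].to_numpy(), alpha=alpha
    )
    from itertools import combinations

    groups = [str(g) for g in res.groupsunique]
    out = []
    for (ga, gb), diff, p, reject in zip(
        combinations(groups, 2), res.meandiffs, res.pvalues, res.reject
    ):
        p = float(p)
        out.append(
            TukeyComparison(
                timepoint=timepoint,
                sample_a=ga,
                sample_b=gb,
                mean_diff=float(diff),
                p_adj=p,
                reject=bool(reject),
                stars=significance_stars(p, star_thresholds),
            )
        )
    return out


def amplification(records, reference_sample: str, timepoint: str) -> dict[str, float]:
    """Percent change of each sample's mean intensity vs the reference.

    amplification% = 100 * (mean_sample - mean_reference) / mean_reference,
    so the study's "+300 %" corresponds to 4x the reference mean.
    """
    df = records_to_frame(records)
    sub = df[df["timepoint"] == timepoint]
    means = sub.groupby("sample", observed=True)["intensity"].mean()
    if reference_sample not in means.index:
        raise ValueError(f"reference sample {reference_sample!r} absent at {timepoint!r}")
    ref = means[reference_sample]
    out: dict[str, float] = {}
    for sample, m in means.items():
        if sample == reference_sample:
            continue
        if ref == 0:
            warnings.warn("reference mean is 0: amplification undefined", stacklevel=2)
            out[sample] = float("nan")
        else:
            out[sample] = 100.0 * (m - ref) / ref
    return out


@dataclass(frozen=True)
class StimulusResponseFit:
    """OLS line of mean I_max on stimulus size with a 95 % confidence band."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    x_mean: float
    sxx: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the mean response."""
        x = np.asarray(x, dtype=float)
        pred = self.predict(x)
        dof = self.n - 2
        if dof <= 0:
            return pred, pred
        tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
        se = self.residual_sd * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        return pred - tcrit * se, pred + tcrit * se


def fit_stimulus_response(points: Sequence[tuple]) -> StimulusResponseFit:
    """Fit mean maximum intensity against stimulus size by OLS.

    ``points`` holds (stimulus_size, mean_intensity[, sd]) tuples; any third
    element is accepted (the study's error bars) but the fit is unweighted.
    """
    arr = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 points for the stimulus-response fit")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all stimulus sizes identical: cannot fit a line")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = n - 2
    residual_sd = math.sqrt(ss_res / dof) if dof > 0 else 0.0
    return StimulusResponseFit(slope, intercept, r2, residual_sd, n, float(xm), sxx)


def predict_deviation(fit: StimulusResponseFit, point: tuple[float, float]) -> float:
    """Standardized residual (observed - predicted) / residual sd.

    Flags off-line samples; 0 for a residual-free fit evaluated on the line,
    +/- inf off the line in that degenerate case.
    """
    x, y = point
    resid = y - float(fit.predict(x))
    if fit.residual_sd == 0:
        return 0.0 if resid == 0 else math.copysign(math.inf, resid)
    return resid / fit.residual_sd
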