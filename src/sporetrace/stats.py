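"""Fate classification, distribution fits and two-condition comparisons.

A spore's fate over the observation window is one of: it germinates and
grows out into a microcolony; it germinates but never grows out; or it stays
phase-bright (dormant, possibly superdormant).  Population fractions of
germinated and outgrown spores are reported over all assessed spores, while
timing metrics (start of germination, germination time, outgrowth time,
generation time) are distributions over the spores for which the event was
measured — so the n varies per metric.

Two conditions are compared metric-by-metric: an F-test on the variances
decides whether the pooled or the Welch t-test is appropriate, both at
alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SporeRecord",
    "FateSummary",
    "ConditionComparison",
    "classify_fates",
    "fit_distribution",
    "compare_conditions",
    "condition_deltas",
]

ALPHA = 0.05

Fate = Literal["outgrow", "germinate_only", "dormant", "pre_germinated", "excluded"]

TIMING_METRICS = (
    "t_start_min",
    "germ_duration_min",
    "outgrowth_time_min",
    "generation_time_min",
)


@dataclass
class SporeRecord:
    """Final per-spore result row: fate plus every timing metric measured."""

    spore_id: int
    fate: Fate
    t_start_min: float | None = None
    germ_duration_min: float | None = None
    outgrowth_time_min: float | None = None
    generation_time_min: float | None = None
    fit_r_value: float | None = None
    burst_times_min: list[float] = field(default_factory=list)
    censor_reason: str | None = None
    division_source: str | None = None
    origin_name: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.fate in ("dormant", "pre_germinated", "excluded"):
            if self.t_start_min is not None or self.germ_duration_min is not None:
                raise ValueError(f"{self.fate} record cannot carry germination metrics")
        if self.fate != "outgrow":
            if self.outgrowth_time_min is not None or self.generation_time_min is not None:
                raise ValueError(
                    f"{self.fate} record cannot carry outgrowth/generation metrics"
                )


@dataclass(frozen=True)
class FateSummary:
    """Population fate counts and the two headline fractions (percent)."""

    n_assessed: int
    n_outgrow: int
    n_germinate_only: int
    n_dormant: int
    n_pre_germinated: int
    n_excluded: int
    fraction_germinated_pct: float
    fraction_outgrown_pct: float


def classify_fates(records: Sequence[SporeRecord], movie_duration_min: float | None = None) -> FateSummary:
    """Score a population for its ability to germinate and grow out.

    Germinated = outgrown + germinated-but-not-outgrown; both fractions are
    percentages of all assessed (non-excluded) spores.  ``movie_duration_min``
    is carried for reporting only — fates are already resolved per record.
    """
    counts = {"outgrow": 0, "germinate_only": 0, "dormant": 0,
              "pre_germinated": 0, "excluded": 0}
    for rec in records:
        counts[rec.fate] += 1
    n_assessed = sum(v for k, v in counts.items() if k != "excluded")
    n_germ = counts["outgrow"] + counts["germinate_only"]
    frac_g = 100.0 * n_germ / n_assessed if n_assessed else 0.0
    frac_o = 100.0 * counts["outgrow"] / n_assessed if n_assessed else 0.0
    return FateSummary(
        n_assessed=n_assessed,
        n_outgrow=counts["outgrow"],
        n_germinate_only=counts["germinate_only"],
        n_dormant=counts["dormant"],
        n_pre_germinated=counts["pre_germinated"],
        n_excluded=counts["excluded"],
        fraction_germinated_pct=frac_g,
        fraction_outgrown_pct=frac_o,
    )


def fit_distribution(
    values: Sequence[float], family: Literal["normal", "lognormal"]
) -> tuple[float, float, float]:
    """Maximum-likelihood (location, scale, log-likelihood) for one family.

    ``normal`` returns (mean, sd); ``lognormal`` the mean and sd of
    log(values).  The log-likelihood lets callers pick the better-fitting
    family.  A degenerate sample (zero scale) yields ``-inf`` log-likelihood.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to fit a distribution")
    if family == "lognormal":
        if np.any(x <= 0):
            raise ValueError("lognormal fit requires strictly positive values")
        logx = np.log(x)
        mu, sigma = float(logx.mean()), float(logx.std(ddof=0))
        if sigma == 0:
            return mu, 0.0, -math.inf
        ll = float(np.sum(sps.lognorm.logpdf(x, s=sigma, scale=math.exp(mu))))
        return mu, sigma, ll
    if family == "normal":
        mu, sigma = float(x.mean()), float(x.std(ddof=0))
        if sigma == 0:
            return mu, 0.0, -math.inf
        ll = float(np.sum(sps.norm.logpdf(x, loc=mu, scale=sigma)))
        return mu, sigma, ll
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class ConditionComparison:
    """F-then-t comparison of one metric between two conditions."""

    metric_name: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    f_statistic: float
    f_p_value: float
    t_statistic: float
    t_p_value: float
    t_variant: Literal["pooled", "welch"]
    mean_diff: float  # mean_b - mean_a
    alpha: float = ALPHA

    @property
    def variances_differ(self) -> bool:
        return self.f_p_value < self.alpha

    @property
    def means_differ(self) -> bool:
        return self.t_p_value < self.alpha


def variance_f_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided variance-ratio F-test; returns (F, p)."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("F-test undefined for zero-variance samples")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def compare_conditions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric_name: str = "",
    alpha: float = ALPHA,
) -> ConditionComparison:
    """F-test on the variances, then the appropriate t-test on the means.

    The pooled two-sample t-test is used when the F-test does not reject
    equality of variances at ``alpha``; otherwise Welch's t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per condition")
    f_stat, f_p = variance_f_test(a, b)
    equal_var = f_p >= alpha
    t_res = sps.ttest_ind(a, b, equal_var=equal_var)
    return ConditionComparison(
        metric_name=metric_name,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        f_statistic=f_stat,
        f_p_value=f_p,
        t_statistic=float(t_res.statistic),
        t_p_value=float(t_res.pvalue),
        t_variant="pooled" if equal_var else "welch",
        mean_diff=float(b.mean() - a.mean()),
        alpha=alpha,
    )


def condition_deltas(
    summary_a: dict[str, float], summary_b: dict[str, float]
) -> dict[str, float]:
    """Per-metric differences between two condition summaries (b - a).

    Keys ending in ``_pct`` are percentage-point differences of fractions;
    keys ending in ``_min`` are minute differences of means.  Both summaries
    must cover the same metrics.
    """
    if set(summary_a) != set(summary_b):
        raise ValueError(
            f"summaries cover different metrics: {sorted(set(summary_a) ^ set(summary_b))}"
        )
    return {k: summary_b[k] - summary_a[k] for k in summary_a}
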