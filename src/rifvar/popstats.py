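"""Descriptive statistics, dose-response fits, Q-Q comparison and tail metrics.

The statistics mirror the descriptive tables of focus-count studies: per
population n, mean, median, mode, variance, SD and relative SD (SD/mean);
fold changes of SD and SD_rel along a dose-doubling ladder; an ordinary
least-squares dose-response line over replicate means; a quantile-quantile
comparison of observed counts against simulated specific energies whose
regression slope estimates the focus yield per gray; and tail metrics that
quantify how far the low tail of a high-dose population falls below a lower
reference dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PopulationStats",
    "DoseResponseFit",
    "QQResult",
    "TailMetrics",
    "describe_counts",
    "fold_change_series",
    "fit_dose_response",
    "qq_compare",
    "tail_metrics",
]


@dataclass(frozen=True)
class PopulationStats:
    """n, mean, median, mode, var, sd, sd_rel of one population."""

    n: int
    mean: float
    median: float
    mode: float
    var: float
    sd: float
    sd_rel: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "mode": self.mode,
            "var": self.var,
            "sd": self.sd,
            "sd_rel": self.sd_rel,
        }


def describe_counts(counts) -> PopulationStats:
    """Descriptive statistics of a count population.

    Sample variance (n-1 denominator); the mode is the most frequent value
    with ties broken toward the smallest; sd_rel = sd / mean, reported as
    NaN when the mean is zero.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("describe_counts needs at least 2 values")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    sd = float(np.sqrt(var))
    values, freq = np.unique(x, return_counts=True)
    mode = float(values[np.argmax(freq)])  # np.unique sorts ascending -> smallest tie wins
    sd_rel = sd / mean if mean > 0 else float("nan")
    return PopulationStats(
        n=int(x.size),
        mean=mean,
        median=float(np.median(x)),
        mode=mode,
        var=var,
        sd=sd,
        sd_rel=float(sd_rel),
    )


def fold_change_series(stats_by_dose, attr: str = "sd_rel") -> list[float]:
    """Ratios of a statistic between consecutive doses of a doubling ladder.

    Parameters
    ----------
    stats_by_dose : sequence of (dose_Gy, PopulationStats), ascending dose
    attr : "sd_rel" or "sd" (or any PopulationStats field)

    Returns the ratio at 2D relative to D for each consecutive pair.  A
    non-doubling ladder triggers a warning but the ratios are still computed.
    """
    pairs = list(stats_by_dose)
    if len(pairs) < 2:
        raise ValueError("need at least two dose points")
    doses = [d for d, _ in pairs]
    for lo, hi in zip(doses, doses[1:]):
        if lo <= 0 or abs(hi / lo - 2.0) > 1e-9:
            warnings.warn(
                f"doses {doses} do not form a doubling ladder; fold changes are "
                "not per-doubling ratios",
                stacklevel=2,
            )
            break
    vals = [getattr(s, attr) for _, s in pairs]
    return [b / a for a, b in zip(vals, vals[1:])]


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS line of mean focus count on dose, over replicate means."""

    slope: float
    intercept: float
    r_squared: float
    replicate_mean_sd: dict[float, float]
    slope_replicate_level: float
    intercept_replicate_level: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "replicate_mean_sd": {str(k): v for k, v in self.replicate_mean_sd.items()},
            "slope_replicate_level": self.slope_replicate_level,
            "intercept_replicate_level": self.intercept_replicate_level,
        }


def fit_dose_response(replicate_means: dict[float, "list[float]"]) -> DoseResponseFit:
    """Dose-response regression over per-replicate mean counts.

    The headline fit is unweighted OLS of the per-dose average of replicate
    means on dose (the straight line through the dose-group points); the SD
    of replicate means per dose is reported as the error-bar annotation, not
    as weights.  A replicate-level fit (every replicate mean as its own
    point) is reported alongside, since the two can differ slightly when
    replicates are unbalanced.
    """
    if len(replicate_means) < 3:
        raise ValueError("dose-response fit needs at least 3 dose points")
    doses = np.array(sorted(replicate_means))
    group_means = np.array([np.mean(replicate_means[d]) for d in doses])
    res = stats.linregress(doses, group_means)
    rep_d = np.concatenate([[d] * len(replicate_means[d]) for d in doses])
    rep_m = np.concatenate([np.asarray(replicate_means[d], dtype=float) for d in doses])
    res_rep = stats.linregress(rep_d, rep_m)
    return DoseResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        replicate_mean_sd={
            float(d): float(np.std(replicate_means[d], ddof=1)) if len(replicate_means[d]) > 1 else 0.0
            for d in doses
        },
        slope_replicate_level=float(res_rep.slope),
        intercept_replicate_level=float(res_rep.intercept),
    )


@dataclass(frozen=True)
class QQResult:
    """Paired quantiles (specific energy vs counts) with a fitted line."""

    quantiles_x: np.ndarray
    quantiles_y: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.quantiles_x) < 0) or np.any(np.diff(self.quantiles_y) < 0):
            raise ValueError("paired quantiles must be ascending in both coordinates")


def qq_compare(observed, energy_sample, trim_low_fraction: float = 0.0) -> QQResult:
    """Quantile-quantile comparison of observed counts vs simulated energies.

    Equal-sized samples are paired by sorted order statistics; otherwise the
    empirical quantiles of both samples are interpolated at plotting
    positions (i - 0.5) / n with n the smaller sample size.  An unweighted
    OLS line through the pairs summarizes the relation; when the count scale
    is focus number and the energy scale is Gy its slope estimates the focus
    yield per gray.  ``trim_low_fraction`` drops that fraction of the lowest
    quantile pairs before the fit (the low-count corner can bend away from
    the line).
    """
    obs = np.sort(np.asarray(observed, dtype=float))
    en = np.sort(np.asarray(energy_sample, dtype=float))
    if obs.size == 0 or en.size == 0:
        raise ValueError("both samples must be nonempty")
    if obs.size == en.size:
        qx, qy = en, obs
    else:
        n = min(obs.size, en.size)
        probs = (np.arange(n) + 0.5) / n
        qx = np.quantile(en, probs, method="linear")
        qy = np.quantile(obs, probs, method="linear")
    if not 0 <= trim_low_fraction < 1:
        raise ValueError("trim_low_fraction must be in [0, 1)")
    start = int(np.floor(trim_low_fraction * qx.size))
    fx, fy = qx[start:], qy[start:]
    if np.ptp(fx) == 0:
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        res = stats.linregress(fx, fy)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return QQResult(quantiles_x=qx, quantiles_y=qy, slope=slope, intercept=intercept, r_squared=r2)


@dataclass(frozen=True)
class TailMetrics:
    """Low-tail summary of a count population against a reference mean."""

    fraction_below: float
    percentile_deficit: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "fraction_below": self.fraction_below,
            "percentile_deficit": {str(k): v for k, v in self.percentile_deficit.items()},
        }


def tail_metrics(counts, reference_mean: float, percentiles=(15.0,)) -> TailMetrics:
    """Fraction of the population strictly below a reference mean, and the
    percent shortfall of given percentiles relative to the population mean:
    100 * (mean - p-th percentile) / mean."""
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("counts must be nonempty")
    frac = float(np.mean(x < reference_mean))
    mean = x.mean()
    deficits = {
        float(p): float(100.0 * (mean - np.percentile(x, p)) / mean) if mean != 0 else float("nan")
        for p in percentiles
    }
    return TailMetrics(fraction_below=frac, percentile_deficit=deficits)
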