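"""Model-independent peak-time analysis.

If the fluorescence peak marks the motor's arrival at the C-terminal dye,
then total substrate length plotted against peak time is a kinematic
position-versus-time plot: its slope is the overall unfolding/
translocation rate (aa/s) and its intercept is the pre-translocated
distance ``C`` (aa) at the moment of mixing.  Repeating the experiment at
several ATPgammaS delay times ``dt1`` and fitting the per-delay
intercepts against ``dt1`` yields the ATPgammaS-driven pre-translocation
rate (slope) and the excluded length (intercept at ``dt1 = 0``).

The finite number of steps biases each peak time slightly, which shifts
every intercept by (nearly) the same constant; the bias therefore cancels
in the intercept-versus-delay slope but is inherited by the excluded
length, and no correction is applied to it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import Dataset
from .errors import FitError, UsageError
from .preprocess import relative_enhancement, smooth
from .timecourse import TimeCourse

__all__ = [
    "PeakEstimate",
    "PeakTimeFit",
    "Dt1Fit",
    "detect_peak",
    "fit_length_vs_peaktime",
    "fit_pretranslocation_vs_dt1",
    "run_peaktime_pipeline",
    "PeakTimePipelineResult",
]


@dataclass(frozen=True)
class PeakEstimate:
    """Detected peak of one trace (flagged when no interior peak exists)."""

    time: float
    height: float
    has_peak: bool
    index: int = -1
    message: str = ""


@dataclass(frozen=True)
class PeakTimeFit:
    """Weighted line through (peak time, length): slope in aa/s,
    intercept = pre-translocated distance C in aa."""

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    points: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class Dt1Fit:
    """Weighted line through (dt1, C): slope = ATPgammaS-driven rate in
    aa/s, intercept = excluded length in aa."""

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    points: pd.DataFrame = field(repr=False, default=None)


def detect_peak(trace: TimeCourse, window: int = 1, poly_order: int = 3,
                edge_fraction: float = 0.01, refine: bool = True
                ) -> PeakEstimate:
    """Locate the global maximum of a (smoothed) trace.

    The first and last ``edge_fraction`` of points are excluded; a
    maximum landing on the boundary of the search window is flagged as
    "no interior peak" rather than reported.  Exact ties resolve to the
    earliest time.  The peak height is read from the *unsmoothed* trace
    at the detected index.  With ``refine=True`` the peak time is
    interpolated sub-grid by a parabola through the three points around
    the maximum of the smoothed signal.
    """
    ys = smooth(trace, window, poly_order).y if window > 1 else trace.y
    npts = len(trace)
    lo = max(int(np.floor(npts * edge_fraction)), 1)
    hi = min(npts - lo, npts - 1)
    if hi - lo < 3:
        raise UsageError("trace too short for peak detection")
    seg = ys[lo:hi]
    idx = lo + int(np.argmax(seg))  # argmax returns first index on ties
    if idx in (lo, hi - 1):
        return PeakEstimate(np.nan, np.nan, False, idx,
                            "maximum at search boundary; no interior peak")
    # a trace still sitting at its maximum at the window end (saturating
    # plateau) has no genuine interior peak either
    if ys[idx] - ys[hi - 1] <= 1e-9 * max(abs(ys[idx]), 1e-30):
        return PeakEstimate(np.nan, np.nan, False, idx,
                            "signal plateaus at its maximum; no interior peak")
    t_peak = float(trace.t[idx])
    if refine:
        t3 = trace.t[idx - 1:idx + 2]
        y3 = ys[idx - 1:idx + 2]
        denom = ((t3[0] - t3[1]) * (t3[0] - t3[2]) * (t3[1] - t3[2]))
        if denom != 0:
            # vertex of the parabola through the three bracketing points
            a = (t3[2] * (y3[1] - y3[0]) + t3[1] * (y3[0] - y3[2])
                 + t3[0] * (y3[2] - y3[1])) / denom
            b = (t3[2]**2 * (y3[0] - y3[1]) + t3[1]**2 * (y3[2] - y3[0])
                 + t3[0]**2 * (y3[1] - y3[2])) / denom
            if a < 0:
                tv = -b / (2 * a)
                if t3[0] < tv < t3[2]:
                    t_peak = float(tv)
    return PeakEstimate(t_peak, float(trace.y[idx]), True, idx)


def _wls_line(x: np.ndarray, y: np.ndarray, sd: np.ndarray | None):
    """Weighted (1/sd^2) or ordinary least-squares line of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise UsageError("need at least two points for a line fit")
    if np.ptp(x) == 0:
        raise FitError("regressor has zero variance; line is degenerate")
    X = sm.add_constant(x)
    if sd is not None:
        sd = np.asarray(sd, float)
        if np.any(sd < 0):
            raise UsageError("standard deviations must be >= 0")
        if np.all(sd > 0):
            model = sm.WLS(y, X, weights=1.0 / sd**2)
        else:
            model = sm.OLS(y, X)  # degenerate sds: unweighted fallback
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    se = res.bse if x.size > 2 else np.zeros(2)
    intercept, slope = res.params
    return float(slope), float(intercept), float(se[1]), float(se[0])


def fit_length_vs_peaktime(lengths, peak_times, sds=None) -> PeakTimeFit:
    """Weighted line of substrate length (response) on peak time.

    Weights are ``1/sd^2`` of the peak times (replicate scatter); with no
    usable sds the fit is unweighted.  Slope is in aa/s, intercept in aa.
    """
    slope, intercept, slope_sd, intercept_sd = _wls_line(
        np.asarray(peak_times, float), np.asarray(lengths, float),
        None if sds is None else np.asarray(sds, float))
    pts = pd.DataFrame({"peak_time_s": peak_times, "L_aa": lengths,
                        "peak_time_sd_s": (np.nan if sds is None else sds)})
    return PeakTimeFit(slope, intercept, slope_sd, intercept_sd, pts)


def fit_pretranslocation_vs_dt1(dt1_values, intercepts, sds=None) -> Dt1Fit:
    """Weighted line of pre-translocated distance C on delay time dt1."""
    slope, intercept, slope_sd, intercept_sd = _wls_line(
        np.asarray(dt1_values, float), np.asarray(intercepts, float),
        None if sds is None else np.asarray(sds, float))
    pts = pd.DataFrame({"dt1_s": dt1_values, "C_aa": intercepts,
                        "C_sd_aa": (np.nan if sds is None else sds)})
    return Dt1Fit(slope, intercept, slope_sd, intercept_sd, pts)


@dataclass
class PeakTimePipelineResult:
    """Per-delay length-vs-peak-time fits plus the intercept-vs-delay fit."""

    per_dt1: dict[float, PeakTimeFit]
    dt1_fit: Dt1Fit | None
    peaks: pd.DataFrame

    def table(self) -> pd.DataFrame:
        rows = [
            {"dt1_s": dt1, "slope_aa_per_s": f.slope,
             "slope_sd_aa_per_s": f.slope_sd, "intercept_aa": f.intercept,
             "intercept_sd_aa": f.intercept_sd}
            for dt1, f in sorted(self.per_dt1.items())
        ]
        return pd.DataFrame(rows)


def run_peaktime_pipeline(dataset: Dataset, n_baseline: int = 10,
                          window: int = 1, poly_order: int = 3,
                          refine: bool = True) -> PeakTimePipelineResult:
    """Full model-independent analysis of a multi-delay dataset.

    For every (dt1, substrate): normalize raw replicates, detect each
    replicate's peak, and summarize peak time as mean +/- sd across
    replicates.  Per dt1, fit length vs peak time weighted by replicate
    scatter; across dt1 values, fit the intercepts against dt1 (weighted
    by intercept uncertainty) to extract the ATPgammaS pre-translocation
    rate and the excluded length.
    """
    rows = []
    for dt1 in dataset.dt1_values:
        for name in dataset.substrates:
            reps = dataset.select(substrate=name, dt1=dt1)
            if not reps:
                continue
            times = []
            for tc in reps:
                rel = relative_enhancement(tc, n_baseline) if tc.is_raw else tc
                pk = detect_peak(rel, window, poly_order, refine=refine)
                if not pk.has_peak:
                    raise FitError(
                        f"no interior peak for {name} dt1={dt1} "
                        f"replicate {tc.replicate}: {pk.message}")
                times.append(pk.time)
            rows.append({
                "dt1_s": dt1, "substrate": name, "L_aa": reps[0].length,
                "peak_time_s": float(np.mean(times)),
                "peak_time_sd_s": (float(np.std(times, ddof=1))
                                   if len(times) > 1 else 0.0),
                "n_replicates": len(times),
            })
    peaks = pd.DataFrame(rows)
    if peaks.empty:
        raise UsageError("dataset contains no traces")
    per_dt1: dict[float, PeakTimeFit] = {}
    for dt1, grp in peaks.groupby("dt1_s"):
        if len(grp) < 2:
            raise UsageError(
                f"need >= 2 substrates per dt1 for a line fit (dt1={dt1})")
        sds = grp["peak_time_sd_s"].to_numpy()
        per_dt1[float(dt1)] = fit_length_vs_peaktime(
            grp["L_aa"].to_numpy(), grp["peak_time_s"].to_numpy(),
            sds if np.all(sds > 0) else None)
    dt1_fit = None
    if len(per_dt1) >= 2:
        dt1s = sorted(per_dt1)
        inter = [per_dt1[d].intercept for d in dt1s]
        isds = np.array([per_dt1[d].intercept_sd for d in dt1s])
        dt1_fit = fit_pretranslocation_vs_dt1(
            dt1s, inter, isds if np.all(isds > 0) else None)
    return PeakTimePipelineResult(per_dt1=per_dt1, dt1_fit=dt1_fit,
                                  peaks=peaks)
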