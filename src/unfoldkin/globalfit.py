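"""Model-dependent analysis: global fit of length-dependent time-courses.

All substrate traces are fit simultaneously to the n-step sequential
signal model with the kinetic step-size ``m`` and unfolding rate constant
``k_U`` *global* (shared across traces) and the terminal dissociation
rate ``k_end`` and the two amplitudes ``F1``/``F2`` *local* to each
trace.  The number of steps never appears as a free parameter in this
mode: it is tied to geometry by ``n_i = (L_i - C_i) / m`` with the
pre-translocated distance ``C`` supplied per trace (from the
model-independent peak-time intercept, or from a manifest in synthetic
closure tests).

A diagnostic *local-n* mode frees ``n`` per trace (with ``k_U`` still
shared) and fits a line to ``n`` versus ``L``; its slope estimates
``1/m`` and its x-intercept estimates the pre-translocated distance.

The optimizer is multi-start bounded trust-region least squares over the
*nonlinear* parameters only, with rate constants (and ``m``)
log-parameterized.  The signal is linear in the amplitudes, so for every
candidate rate set the optimal nonnegative (F1, F2) of each trace are
obtained by variable projection (non-negative least squares on the
two-column basis of last-intermediate and product fractions); this keeps
the search space low-dimensional and removes amplitude-induced local
minima.  Starts are drawn from the bounds with a seeded generator, plus
one data-driven heuristic start.  The fit refuses to report when the two
best optima are indistinguishable in objective but far apart in shared
parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .errors import FitError, MultimodalFitError, UsageError
from .mechanism import SchemeParams, species_fractions
from .peaktime import _wls_line, detect_peak
from .timecourse import TimeCourse

__all__ = [
    "FitBounds",
    "GlobalFitResult",
    "LocalNFit",
    "fit_global",
    "fit_local_n",
    "bootstrap_uncertainty",
    "replicate_summary",
]


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the optimizer (rates in s^-1, m in aa).

    Amplitudes are not searched (variable projection solves them exactly,
    constrained to be nonnegative); ``n`` bounds apply to the local-n
    diagnostic mode only.
    """

    k_U: tuple[float, float] = (1e-4, 10.0)
    k_end: tuple[float, float] = (1e-4, 10.0)
    m: tuple[float, float] = (5.0, 200.0)
    n: tuple[float, float] = (1e-3, 50.0)


@dataclass
class GlobalFitResult:
    """Best shared (m, k_U), per-trace locals, and diagnostics."""

    m: float
    k_U: float
    per_trace: pd.DataFrame
    rss: float
    mode: str = "constrained-n"
    flags: list[str] = field(default_factory=list)
    starts: pd.DataFrame | None = field(default=None, repr=False)
    n_starts: int = 0

    @property
    def mk_U(self) -> float:
        """Overall unfolding rate m * k_U in aa/s."""
        return self.m * self.k_U


@dataclass
class LocalNFit:
    """Local-n diagnostic fit and its n-versus-L line."""

    k_U: float
    per_trace: pd.DataFrame
    rss: float
    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    flags: list[str] = field(default_factory=list)

    @property
    def x_intercept(self) -> float:
        """Length at which the n-vs-L line crosses zero steps (aa);
        estimates the pre-translocated distance."""
        return -self.intercept / self.slope


def _prepare(traces: list[TimeCourse], C) -> tuple[list[TimeCourse], np.ndarray]:
    if not traces:
        raise UsageError("no traces to fit")
    for tc in traces:
        if tc.is_raw:
            raise UsageError(
                f"trace {tc.substrate!r} is raw; normalize before fitting")
    Cs = np.broadcast_to(np.asarray(C, float), (len(traces),)).copy()
    for tc, c in zip(traces, Cs):
        if c >= tc.length:
            raise UsageError(
                f"C={c} aa must be below substrate length L={tc.length} aa")
    return traces, Cs


def _projected_residual(tc: TimeCourse, k_U: float, k_end: float, n: float
                        ) -> tuple[np.ndarray, float, float]:
    """Residual after solving the optimal nonnegative (F1, F2) by
    non-negative least squares on the two-column species basis."""
    p = SchemeParams(k_U, k_end, max(n, 0.0), 1.0, 1.0)
    sp = species_fractions(p, tc.t)
    basis = np.column_stack([sp.last_intermediate, sp.product])
    if not np.all(np.isfinite(basis)) or np.all(basis == 0):
        return -tc.y, 0.0, 0.0
    try:
        amps, _ = nnls(basis, tc.y)
    except Exception:
        return -tc.y, 0.0, 0.0
    return basis @ amps - tc.y, float(amps[0]), float(amps[1])


def _residuals_constrained(theta, traces, Cs, amp_out=None):
    m = np.exp(theta[0])
    k_U = np.exp(theta[1])
    res = []
    for i, tc in enumerate(traces):
        k_end = np.exp(theta[2 + i])
        n = (tc.length - Cs[i]) / m
        r, F1, F2 = _projected_residual(tc, k_U, k_end, n)
        if amp_out is not None:
            amp_out[i] = (F1, F2)
        res.append(r)
    return np.concatenate(res)


def _residuals_local_n(theta, traces, amp_out=None):
    k_U = np.exp(theta[0])
    res = []
    for i, tc in enumerate(traces):
        n = theta[1 + 2 * i]
        k_end = np.exp(theta[2 + 2 * i])
        r, F1, F2 = _projected_residual(tc, k_U, k_end, n)
        if amp_out is not None:
            amp_out[i] = (F1, F2)
        res.append(r)
    return np.concatenate(res)


def _heuristic_rate(traces) -> float:
    """Crude overall rate (aa/s) from peak spacing of the two extreme
    lengths; falls back to L/t_peak for a single length."""
    peaks = []
    for tc in traces:
        pk = detect_peak(tc)
        if pk.has_peak:
            peaks.append((tc.length, pk.time))
    if len(peaks) >= 2:
        peaks.sort()
        (L0, t0), (L1, t1) = peaks[0], peaks[-1]
        if t1 > t0 and L1 > L0:
            return (L1 - L0) / (t1 - t0)
    if peaks:
        L0, t0 = peaks[0]
        return L0 / max(t0, 1e-6)
    return 0.1


def _run_starts(fun, starts, lower, upper, args=()) -> list:
    fits = []
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)
        try:
            sol = least_squares(fun, x0, bounds=(lower, upper), args=args,
                                method="trf", x_scale="jac",
                                ftol=1e-14, xtol=1e-12, gtol=None)
        except Exception:  # a start may wander into numerical trouble
            continue
        fits.append(sol)
    if not fits:
        raise FitError("no optimizer start converged")
    fits.sort(key=lambda s: s.cost)
    return fits


def _check_multimodal(fits, key_indices, scale) -> None:
    if len(fits) < 2:
        return
    best, second = fits[0], fits[1]
    close = (second.cost - best.cost) <= 0.01 * max(best.cost, 1e-12 * scale)
    if close:
        rel = np.abs(second.x[key_indices] - best.x[key_indices])
        # key parameters are logs, so a difference of log(1.2) is 20 %
        if np.any(rel > np.log(1.2)):
            raise MultimodalFitError(
                "two optima agree in objective within 1% but differ by "
                ">20% in shared parameters; the fit is multimodal")


def fit_global(traces: list[TimeCourse], C, *, seed: int,
               n_starts: int = 10, bounds: FitBounds = FitBounds()
               ) -> GlobalFitResult:
    """Simultaneous fit with global (m, k_U) and local (k_end, F1, F2).

    Parameters
    ----------
    traces : list of TimeCourse
        Normalized (relative-enhancement), typically replicate-averaged
        traces, one per substrate.
    C : float or sequence
        Pre-translocated distance per trace (aa); must be below every
        substrate length.
    seed : int
        Seeds the multi-start generator (required; no wall-clock entropy).
    n_starts : int
        Number of optimizer starts (>= 1); the first is data-driven, the
        rest are drawn log-uniformly from the bounds.
    """
    traces, Cs = _prepare(traces, C)
    if n_starts < 1:
        raise UsageError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    nt = len(traces)
    lower = np.array([np.log(bounds.m[0]), np.log(bounds.k_U[0])]
                     + [np.log(bounds.k_end[0])] * nt)
    upper = np.array([np.log(bounds.m[1]), np.log(bounds.k_U[1])]
                     + [np.log(bounds.k_end[1])] * nt)

    v = _heuristic_rate(traces)
    m0 = np.sqrt(bounds.m[0] * bounds.m[1])
    starts = []
    for j in range(n_starts):
        if j == 0:
            mj = m0
            kUj = np.clip(v / m0, *bounds.k_U)
            kends = [0.05] * nt
        else:
            mj = np.exp(rng.uniform(np.log(bounds.m[0]), np.log(bounds.m[1])))
            kUj = np.clip(v / mj * np.exp(rng.normal(0, 1)), *bounds.k_U)
            kends = np.exp(rng.uniform(np.log(bounds.k_end[0]),
                                       np.log(bounds.k_end[1]), nt))
        starts.append(np.concatenate([[np.log(mj), np.log(kUj)],
                                      np.log(kends)]))

    fits = _run_starts(_residuals_constrained, starts, lower, upper,
                       args=(traces, Cs))
    scale = sum(float(np.sum(tc.y**2)) for tc in traces)
    _check_multimodal(fits, [0, 1], scale)
    best = fits[0]
    m = float(np.exp(best.x[0]))
    k_U = float(np.exp(best.x[1]))
    amps: dict[int, tuple[float, float]] = {}
    _residuals_constrained(best.x, traces, Cs, amp_out=amps)
    rows = []
    for i, tc in enumerate(traces):
        rows.append({
            "substrate": tc.substrate, "L_aa": tc.length, "C_aa": Cs[i],
            "n_steps": (tc.length - Cs[i]) / m,
            "k_end_per_s": float(np.exp(best.x[2 + i])),
            "F1": amps[i][0], "F2": amps[i][1],
        })
    flags = []
    if len({tc.length for tc in traces}) < 2:
        flags.append(
            "weak-identifiability: a single substrate length cannot "
            "separate m from k_U; only their product is constrained")
    starts_df = pd.DataFrame({
        "cost": [s.cost for s in fits],
        "m_aa": [float(np.exp(s.x[0])) for s in fits],
        "k_U_per_s": [float(np.exp(s.x[1])) for s in fits],
    })
    return GlobalFitResult(m=m, k_U=k_U, per_trace=pd.DataFrame(rows),
                           rss=float(2 * best.cost), flags=flags,
                           starts=starts_df, n_starts=len(fits))


def fit_local_n(traces: list[TimeCourse], *, seed: int, n_starts: int = 10,
                bounds: FitBounds = FitBounds()) -> LocalNFit:
    """Diagnostic fit: shared k_U, per-trace free n (and k_end, F1, F2),
    followed by a line fit of n versus L.

    The line's slope estimates ``1/m``; its x-intercept estimates the
    pre-translocated distance.  Requires >= 2 distinct substrate lengths
    for the line stage.
    """
    traces, _ = _prepare(traces, 0.0)
    if len({tc.length for tc in traces}) < 2:
        raise FitError(
            "local-n line fit needs >= 2 distinct substrate lengths")
    rng = np.random.default_rng(seed)
    nt = len(traces)
    lower = np.array([np.log(bounds.k_U[0])]
                     + [bounds.n[0], np.log(bounds.k_end[0])] * nt)
    upper = np.array([np.log(bounds.k_U[1])]
                     + [bounds.n[1], np.log(bounds.k_end[1])] * nt)

    v = _heuristic_rate(traces)
    L_min = min(tc.length for tc in traces)
    starts = []
    # seed starts on the physically meaningful manifold: pick a step-size
    # and a pre-translocated distance, derive k_U and every n_i from them,
    # so the shared rate and the per-trace step counts begin mutually
    # consistent (the k_U <-> n trade-off makes incoherent starts stall
    # in shallow local optima)
    for j in range(n_starts):
        if j == 0:
            m_j, C_j = 50.0, 0.3 * L_min
        else:
            m_j = np.exp(rng.uniform(np.log(bounds.m[0]), np.log(bounds.m[1])))
            C_j = rng.uniform(0.0, 0.8 * L_min)
        kUj = float(np.clip(v / m_j, *bounds.k_U))
        x0 = [np.log(kUj)]
        for tc in traces:
            n_g = float(np.clip((tc.length - C_j) / m_j, *bounds.n))
            kend_j = 0.05 if j == 0 else np.exp(
                rng.uniform(np.log(bounds.k_end[0]), np.log(bounds.k_end[1])))
            x0 += [n_g, np.log(kend_j)]
        starts.append(np.array(x0))

    fits = _run_starts(_residuals_local_n, starts, lower, upper,
                       args=(traces,))
    best = fits[0]
    k_U = float(np.exp(best.x[0]))
    amps: dict[int, tuple[float, float]] = {}
    _residuals_local_n(best.x, traces, amp_out=amps)
    rows = []
    for i, tc in enumerate(traces):
        rows.append({
            "substrate": tc.substrate, "L_aa": tc.length,
            "n_steps": float(best.x[1 + 2 * i]),
            "k_end_per_s": float(np.exp(best.x[2 + 2 * i])),
            "F1": amps[i][0], "F2": amps[i][1],
        })
    df = pd.DataFrame(rows)
    slope, intercept, slope_sd, intercept_sd = _wls_line(
        df["L_aa"].to_numpy(), df["n_steps"].to_numpy(), None)
    return LocalNFit(k_U=k_U, per_trace=df, rss=float(2 * best.cost),
                     slope=slope, intercept=intercept, slope_sd=slope_sd,
                     intercept_sd=intercept_sd)


def _predict(fit: GlobalFitResult, tc: TimeCourse, row) -> np.ndarray:
    p = SchemeParams(fit.k_U, row["k_end_per_s"],
                     (tc.length - row["C_aa"]) / fit.m, 1.0, 1.0)
    sp = species_fractions(p, tc.t)
    return row["F1"] * sp.last_intermediate + row["F2"] * sp.product


def bootstrap_uncertainty(traces: list[TimeCourse], fit: GlobalFitResult,
                          n_boot: int, seed: int,
                          level: float = 0.95) -> dict:
    """Residual-resampling bootstrap intervals for a converged global fit.

    Residuals are resampled with replacement *within* each trace, added
    back to the best-fit prediction, and the model refit from the
    best-fit parameters (single warm start).  Returns percentile
    intervals for m and k_U plus the resampled values; aborts if more
    than 20 % of refits fail.
    """
    if n_boot < 1:
        raise UsageError("n_boot must be >= 1")
    traces, Cs = _prepare(traces, fit.per_trace["C_aa"].to_numpy())
    rng = np.random.default_rng(seed)
    preds = [_predict(fit, tc, fit.per_trace.iloc[i])
             for i, tc in enumerate(traces)]
    resid = [tc.y - p for tc, p in zip(traces, preds)]
    x_best = np.concatenate(
        [[np.log(fit.m), np.log(fit.k_U)],
         np.log(fit.per_trace["k_end_per_s"].to_numpy())])
    bounds = FitBounds()
    nt = len(traces)
    lower = np.array([np.log(bounds.m[0]), np.log(bounds.k_U[0])]
                     + [np.log(bounds.k_end[0])] * nt)
    upper = np.array([np.log(bounds.m[1]), np.log(bounds.k_U[1])]
                     + [np.log(bounds.k_end[1])] * nt)

    samples = []
    failures = 0
    for _ in range(n_boot):
        boot = [tc.with_signal(p + rng.choice(r, size=r.size, replace=True))
                for tc, p, r in zip(traces, preds, resid)]
        try:
            sol = least_squares(_residuals_constrained, x_best,
                                bounds=(lower, upper), args=(boot, Cs),
                                method="trf", x_scale="jac")
            samples.append((np.exp(sol.x[0]), np.exp(sol.x[1])))
        except Exception:
            failures += 1
        if failures > 0.2 * n_boot:
            raise FitError(
                f"bootstrap aborted: {failures} refit failures out of "
                f"{n_boot} resamples")
    arr = np.array(samples)
    alpha = (1.0 - level) / 2.0
    qs = np.quantile(arr, [alpha, 1.0 - alpha], axis=0)
    return {
        "m": (float(qs[0, 0]), float(qs[1, 0])),
        "k_U": (float(qs[0, 1]), float(qs[1, 1])),
        "samples": pd.DataFrame(arr, columns=["m_aa", "k_U_per_s"]),
        "n_failures": failures,
        "level": level,
    }


def replicate_summary(values, sds=None) -> tuple[float, float]:
    """Mean +/- sd of a parameter across replicates (or delay times).

    With per-value uncertainties the mean is inverse-variance weighted
    (equivalent to the best weighted zero-slope line); the reported
    spread is always the unweighted sample standard deviation.  A single
    value passes through with sd 0.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise UsageError("no values to summarize")
    if values.size == 1:
        return float(values[0]), 0.0
    if sds is not None:
        sds = np.asarray(sds, float)
        if np.all(sds > 0):
            w = 1.0 / sds**2
            mean = float(np.sum(w * values) / np.sum(w))
        else:
            mean = float(np.mean(values))
    else:
        mean = float(np.mean(values))
    return mean, float(np.std(values, ddof=1))
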