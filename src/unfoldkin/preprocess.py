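"""Trace preprocessing: normalization, replicate averaging, smoothing.

Raw stopped-flow traces are converted to *relative fluorescence
enhancement*,

    rel(t) = |F0_avg - F(t)| / F0_avg

where ``F0_avg`` is the mean of the first few constant pre-rise data
points.  The ratio is scale-invariant (multiplying the raw trace by any
positive constant leaves it unchanged), which is what makes traces from
substrates with different labeling efficiencies comparable.  The absolute
value is kept exactly as defined; for the enhancement (PIFE) signals this
package targets, the signal rises above baseline and the ratio is simply
``(F - F0_avg) / F0_avg``.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .errors import DataError, UsageError
from .timecourse import TimeCourse, same_grid

__all__ = ["relative_enhancement", "average_replicates", "smooth"]


def relative_enhancement(raw: TimeCourse, n_baseline: int = 10) -> TimeCourse:
    """Convert a raw trace to relative fluorescence enhancement.

    ``n_baseline`` leading points (default 10) are averaged to estimate
    the pre-rise baseline ``F0_avg``; it must be positive and the trace
    must still be in the raw state.
    """
    if not raw.is_raw:
        raise UsageError("trace is already normalized")
    if n_baseline < 2 or n_baseline > len(raw):
        raise UsageError(
            f"n_baseline must be in [2, {len(raw)}], got {n_baseline}")
    f0 = float(np.mean(raw.y[:n_baseline]))
    if f0 <= 0:
        raise DataError(f"baseline average must be > 0, got {f0}")
    out = raw.with_signal(np.abs(f0 - raw.y) / f0, state="relative")
    out.extras["F0_avg"] = f0
    out.extras["n_baseline"] = n_baseline
    return out


def average_replicates(traces: list[TimeCourse]) -> TimeCourse:
    """Pointwise mean of replicate traces, with per-point sample sd.

    All traces must share an identical time grid and normalization state;
    grids are never silently interpolated.  The result carries the sample
    standard deviation under ``extras["sd"]`` and the replicate count
    under ``extras["n_averaged"]``.
    """
    if len(traces) < 2:
        raise UsageError("need at least two replicates to average")
    first = traces[0]
    for tc in traces[1:]:
        if not same_grid(first, tc):
            raise UsageError("replicate grids differ; refusing to interpolate")
        if tc.state != first.state:
            raise UsageError("replicates mix raw and normalized traces")
    ys = np.stack([tc.y for tc in traces])
    out = first.with_signal(ys.mean(axis=0))
    out.extras["sd"] = ys.std(axis=0, ddof=1)
    out.extras["n_averaged"] = len(traces)
    out.replicate = -1
    return out


def smooth(trace: TimeCourse, window: int, poly_order: int = 3) -> TimeCourse:
    """Savitzky-Golay smoothing for peak detection.

    ``window`` must be odd, larger than ``poly_order`` and at most a third
    of the trace; ``window=1`` is the identity.  Endpoints are handled by
    fitting the edge polynomial to the first/last window (scipy's
    ``mode="interp"``), so polynomials of degree <= ``poly_order`` are
    reproduced exactly.
    """
    if window == 1:
        return trace.with_signal(trace.y.copy())
    if window % 2 == 0 or window <= poly_order or window > len(trace) // 3:
        raise UsageError(
            f"window must be odd, > poly_order and <= len/3; got "
            f"window={window}, poly_order={poly_order}, len={len(trace)}")
    return trace.with_signal(
        savgol_filter(trace.y, window, poly_order, mode="interp"))
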