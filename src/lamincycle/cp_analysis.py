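"""Continuous-photobleaching (CP) trace analysis: free/bound fraction of lamin A.

In a CP experiment a confocal laser is parked on one spot and the
fluorescence intensity is recorded for about a minute.  Molecules bound
at the spot bleach exponentially; freely diffusing molecules exchange
through the focal volume and contribute a slowly decreasing, nearly
linear component.  The trace after laser-on is therefore modelled as

    I(t) = a * exp(-b t) + c t + d

with amplitudes a (bound) and d (free) at t = 0, bleach rate b > 0 and
free-pool slope c <= 0.  After peak normalization I(0) = a + d ~= 1 and
the free fraction is d / (a + d).

Processing order: moving-average smoothing (0.1 s window), laser-on
detection from the maximal first difference of the smoothed trace,
truncation at that point, peak normalization, then bounded nonlinear
least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

#: Default smoothing window (seconds).
DEFAULT_SMOOTH_WINDOW_S = 0.1

#: Mean squared residual above which a fit is not trusted.
DEFAULT_MSR_MAX = 0.01

#: Bleach rates below this (1/s) make the exponential indistinguishable
#: from the linear term over a ~60 s trace.
ILL_CONDITIONED_B = 0.01


class NoLaserOnEdgeError(ValueError):
    """No positive intensity jump above the noise floor was found."""


@dataclass
class CPTrace:
    """A time-stamped photobleaching intensity trace."""

    time: np.ndarray  # seconds, strictly increasing
    intensity: np.ndarray  # a.u., >= 0
    cell_id: str = ""
    label: str = ""  # optional phase tag, e.g. "G1" or "S"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and intensity must be 1-D and the same length")
        if t.size < 2:
            raise ValueError("trace needs >= 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("intensity must be finite and >= 0")
        self.time, self.intensity = t, y

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def validate_acquisition(self, min_samples: int = 50, min_span_s: float = 10.0) -> None:
        """Check the trace against acquisition expectations (~60 s recordings)."""
        if self.n_samples < min_samples or self.duration < min_span_s:
            raise ValueError(
                f"trace too short: {self.n_samples} samples over {self.duration:.1f} s "
                f"(need >= {min_samples} samples spanning >= {min_span_s} s)"
            )


@dataclass
class CPFitResult:
    """Fitted exponential-plus-linear model and the derived free fraction."""

    cell_id: str
    label: str
    a: float
    b: float
    c: float
    d: float
    free_fraction: float
    t0_index: int
    rss: float
    converged: bool
    ill_conditioned: bool = False


@dataclass
class FreeFractionSummary:
    """Population summary of the free fraction, in percent."""

    label: str
    mean_percent: float
    std_percent: float
    n_fits: int
    curve_time: np.ndarray | None = None
    curve_mean: np.ndarray | None = None
    curve_std: np.ndarray | None = None


def cp_model(t: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return a * np.exp(-b * t) + c * t + d


def _smooth(y: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return y.astype(float)
    return ndimage.uniform_filter1d(y.astype(float), size=window_samples, mode="nearest")


def window_to_samples(window_s: float, dt: float) -> int:
    """Convert a time window to samples: round half-up, minimum 1, forced odd.

    An odd window keeps the moving average zero-phase (no half-sample
    delay), so smoothing shifts neither the detected laser-on edge nor
    the fitted amplitudes.
    """
    n = max(1, int(np.floor(window_s / dt + 0.5)))
    return n if n % 2 == 1 else n + 1


def detect_t0(trace: CPTrace, smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S) -> int:
    """Sample index of laser-on: the maximal first difference of the trace.

    A trace that already starts at its peak (monotone decay, no rising
    edge) returns 0 with a warning; a trace with no positive jump above
    the noise floor raises :class:`NoLaserOnEdgeError`.
    """
    dt = float(np.median(np.diff(trace.time)))
    window = window_to_samples(smooth_window_s, dt)
    y = _smooth(trace.intensity, window)
    diffs = np.diff(y)
    i = int(diffs.argmax())
    span = float(y.max() - y.min())
    # The jump must carry a meaningful share of the dynamic range.
    if span > 0 and diffs[i] >= 0.1 * span:
        # Smoothing spreads the edge over the window; refine on the raw
        # first differences in its neighborhood.
        lo = max(0, i - window)
        hi = min(diffs.size, i + window + 1)
        raw = np.diff(trace.intensity)
        i = lo + int(raw[lo:hi].argmax())
        return i + 1
    if int(y.argmax()) <= max(1, y.size // 20):
        warnings.warn("trace already starts at its peak; using index 0 as t0")
        return 0
    raise NoLaserOnEdgeError("no laser-on edge found")


def preprocess(
    trace: CPTrace, smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S
) -> tuple[CPTrace, int]:
    """Smooth, truncate at laser-on and peak-normalize a trace.

    Returns the processed trace (time re-zeroed at laser-on, peak
    intensity exactly 1) together with the detected t0 sample index.
    Samples within one smoothing window of the laser-on edge mix pre- and
    post-jump intensities, so they are dropped (when the trace is long
    enough to afford it) before normalization.
    """
    dt = float(np.median(np.diff(trace.time)))
    window = window_to_samples(smooth_window_s, dt)
    smoothed = _smooth(trace.intensity, window)
    t0 = detect_t0(trace, smooth_window_s)
    start = t0 + window if trace.n_samples - (t0 + window) >= 10 else t0
    # Time is re-zeroed at laser-on (t0), not at the first kept sample, so
    # the fitted amplitudes a and d extrapolate to the true t = 0.
    t = trace.time[start:] - trace.time[t0]
    y = smoothed[start:]
    peak = float(y.max())
    if peak <= 0:
        raise ValueError("post-t0 peak intensity is not positive")
    return replace(trace, time=t, intensity=y / peak), t0


def fit_cp(
    trace: CPTrace,
    t0_index: int = 0,
    msr_max: float = DEFAULT_MSR_MAX,
) -> CPFitResult:
    """Bounded least-squares fit of the exponential-plus-linear model.

    Expects a preprocessed (truncated, peak-normalized) trace whose time
    axis is zero at laser-on, so a and d are the t = 0 amplitudes.  Bounds:
    a, d in [0, 1.5]; b in (0, 100] 1/s; c in [-1, 0] a.u./s — which
    guarantee free_fraction = d/(a+d) in [0, 1].  Initialization uses the
    trace tail, where the bound component has bleached out: d0 = I(end),
    a0 = 1 - I(end), b0 = 1/s, c0 = slope of the last third (clipped into
    bounds).  ``converged`` requires optimizer success and a mean squared
    residual below ``msr_max``; b below 0.01/s flags the fit as
    ill-conditioned (exponential indistinguishable from the line, as when
    binding-unbinding happens on the measurement timescale).
    """
    t = trace.time
    y = trace.intensity
    tail = slice(2 * y.size // 3, None)
    d0 = float(np.clip(y[tail].mean(), 0.0, 1.5))
    a0 = float(np.clip(1.0 - d0, 0.0, 1.5))
    c0 = float(np.clip(np.polyfit(t[tail], y[tail], 1)[0], -1.0, 0.0))
    bounds = ([0.0, 1e-6, -1.0, 0.0], [1.5, 100.0, 0.0, 1.5])
    p0 = [a0, 1.0, c0, d0]
    try:
        popt, _ = curve_fit(cp_model, t, y, p0=p0, bounds=bounds, maxfev=20000)
        success = True
    except (RuntimeError, ValueError):
        popt = np.array([np.nan] * 4)
        success = False
    if success:
        a, b, c, d = (float(v) for v in popt)
        residuals = y - cp_model(t, a, b, c, d)
        rss = float((residuals**2).sum())
        msr = rss / y.size
        converged = msr <= msr_max
        free = d / (a + d) if (a + d) > 0 else float("nan")
    else:
        a = b = c = d = rss = free = float("nan")
        converged = False
    return CPFitResult(
        cell_id=trace.cell_id,
        label=trace.label,
        a=a, b=b, c=c, d=d,
        free_fraction=free,
        t0_index=t0_index,
        rss=rss,
        converged=converged,
        ill_conditioned=bool(success and b < ILL_CONDITIONED_B),
    )


def analyze_trace(trace: CPTrace, smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S) -> CPFitResult:
    """Full single-trace pipeline: preprocess then fit."""
    processed, t0 = preprocess(trace, smooth_window_s)
    return fit_cp(processed, t0_index=t0)


def aggregate_free_fraction(
    results: Sequence[CPFitResult],
    traces: Sequence[CPTrace] | None = None,
    label: str = "",
) -> FreeFractionSummary:
    """Mean and sample STD of the free fraction over converged fits, in percent.

    When the preprocessed ``traces`` are supplied, the mean normalized
    curve and its per-timepoint STD band are computed on a common time
    grid spanning the shortest trace.
    """
    good = [r for r in results if r.converged and np.isfinite(r.free_fraction)]
    if len(good) < 2:
        raise ValueError("need >= 2 converged fits to aggregate")
    ff = np.array([r.free_fraction for r in good])
    curve_time = curve_mean = curve_std = None
    if traces:
        t_max = min(tr.time[-1] - tr.time[0] for tr in traces)
        n = min(tr.n_samples for tr in traces)
        curve_time = np.linspace(0.0, t_max, n)
        stack = np.vstack(
            [np.interp(curve_time, tr.time - tr.time[0], tr.intensity) for tr in traces]
        )
        curve_mean = stack.mean(axis=0)
        curve_std = stack.std(axis=0, ddof=1)
    return FreeFractionSummary(
        label=label,
        mean_percent=float(ff.mean() * 100.0),
        std_percent=float(ff.std(ddof=1) * 100.0),
        n_fits=len(good),
        curve_time=curve_time,
        curve_mean=curve_mean,
        curve_std=curve_std,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_traces_csv(path: str | Path) -> list[CPTrace]:
    """Read traces from CSV with columns time_s,intensity[,cell_id,label].

    A file without a cell_id column holds one trace; otherwise rows are
    grouped by cell_id (long format).
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "intensity" not in df.columns:
        raise ValueError("trace CSV needs time_s and intensity columns")
    if "cell_id" not in df.columns:
        label = str(df["label"].iloc[0]) if "label" in df.columns else ""
        return [CPTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(),
                        cell_id=Path(path).stem, label=label)]
    traces = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        label = str(group["label"].iloc[0]) if "label" in group.columns else ""
        traces.append(
            CPTrace(group["time_s"].to_numpy(), group["intensity"].to_numpy(),
                    cell_id=str(cell_id), label=label)
        )
    return traces


def write_traces_csv(traces: Iterable[CPTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "time_s": tr.time, "intensity": tr.intensity,
            "cell_id": tr.cell_id, "label": tr.label,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fits_to_frame(results: Iterable[CPFitResult]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": r.cell_id, "label": r.label,
            "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "free_fraction": r.free_fraction, "rss": r.rss,
            "converged": r.converged, "ill_conditioned": r.ill_conditioned,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "cell_id", "label", "a", "b", "c", "d",
        "free_fraction", "rss", "converged", "ill_conditioned",
    ])
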