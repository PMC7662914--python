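"""Chronobiology statistics: periodogram, waveform/MESOR, phase, monthly means.

The Lomb-Scargle periodogram handles the irregular sampling left by sensor
gaps natively.  Power is expressed as percent of total series variance
explained by the sinusoid at each trial period, scanned on an evenly spaced
period grid (default 1-min resolution over 600-1620 min, i.e. 10-27 h,
covering semidiurnal/diurnal tides and the day-night cycle).  Significance
combines the beta-distribution tail of the variance-fraction statistic at a
single frequency with a Baluev-style Davies bound for the maximum over the
scanned band (bandwidth times effective timespan), which stays calibrated
on densely oversampled period grids.

Waveform analysis folds a series into 24-h segments, averages values at
corresponding clock hours, and summarizes the daily profile by the MESOR
(midline estimated statistic of rhythm: the re-average of the hourly means).
The phase of the rhythm is the set of hours whose mean lies strictly above
the MESOR, reported as maximal contiguous intervals that may wrap midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["PeriodogramResult", "WaveformResult", "lomb_scargle", "waveform",
           "phase_intervals", "monthly_summary"]


@dataclass
class PeriodogramResult:
    periods_min: np.ndarray
    power_pct: np.ndarray  # % of total variance explained per trial period
    threshold_pct: float  # power level with band-wide false-alarm prob = alpha
    peaks: list[tuple[float, float, float]]  # (period_min, power_pct, p) by power desc
    alpha: float
    n_samples: int
    n_independent: int
    constant: bool = False

    @property
    def top_peak(self) -> tuple[float, float, float] | None:
        return self.peaks[0] if self.peaks else None


def _series_to_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, pd.Series):
        t = (series.index - series.index[0]).total_seconds().to_numpy() / 60.0
        y = series.to_numpy(dtype=float)
    else:
        t, y = series
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(t)
    return t[keep], y[keep]


def lomb_scargle(
    series,
    period_range: tuple[float, float] = (600.0, 1620.0),
    grid_step_min: float = 1.0,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Lomb-Scargle periodogram over an evenly spaced period grid (minutes).

    ``series`` is either a pandas Series with a DatetimeIndex or a pair
    ``(t_minutes, y)``.  Missing values are dropped; at least 48 finite
    samples are required.  Peaks are local maxima whose band-corrected
    false-alarm probability is below ``alpha``.
    """
    t, y = _series_to_arrays(series)
    n = len(y)
    if n < 48:
        raise ValueError(f"need >= 48 finite samples for a periodogram, got {n}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    lo, hi = period_range
    if not (0 < lo < hi):
        raise ValueError("invalid period range")

    periods = np.arange(lo, hi + 0.5 * grid_step_min, grid_step_min)
    # Davies bound: effective number of trials over the scanned band is the
    # bandwidth times the effective timespan sqrt(4 pi var(t))
    t_eff = np.sqrt(4 * np.pi * t.var())
    band_w = t_eff * (1.0 / lo - 1.0 / hi)
    n_indep = max(1, int(round(band_w)))

    var = y.var()
    if var == 0:
        return PeriodogramResult(periods, np.zeros_like(periods), 100.0, [], alpha, n, n_indep,
                                 constant=True)

    omega = 2 * np.pi / periods
    frac = signal.lombscargle(t, y - y.mean(), omega, normalize=True)
    frac = np.clip(frac, 0.0, 1.0)
    power_pct = 100.0 * frac

    from scipy.special import gammaln

    nh, nk = n - 1, n - 3
    log_gam = gammaln(nh / 2.0) - gammaln((nh - 1) / 2.0) + 0.5 * np.log(2.0 / nh)

    def fap(z: float) -> float:
        """Band-wide false-alarm probability of a variance fraction z."""
        if z >= 1.0:
            return 0.0
        p_single = (1.0 - z) ** (nk / 2.0)
        tau = np.exp(log_gam) * band_w * (1.0 - z) ** ((nk - 1) / 2.0) * np.sqrt(0.5 * nh * z)
        return float(1.0 - (1.0 - p_single) * np.exp(-tau))

    # invert fap() for the alpha-level power threshold
    z_lo, z_hi = 1e-9, 1.0 - 1e-12
    for _ in range(80):
        mid = 0.5 * (z_lo + z_hi)
        if fap(mid) > alpha:
            z_lo = mid
        else:
            z_hi = mid
    thr_frac = 0.5 * (z_lo + z_hi)
    threshold_pct = 100.0 * thr_frac

    peaks = []
    for i in range(len(periods)):
        left = frac[i - 1] if i > 0 else -np.inf
        right = frac[i + 1] if i < len(periods) - 1 else -np.inf
        if frac[i] > thr_frac and frac[i] >= left and frac[i] > right:
            peaks.append((float(periods[i]), float(power_pct[i]), fap(frac[i])))
    peaks.sort(key=lambda pk: -pk[1])
    return PeriodogramResult(periods, power_pct, threshold_pct, peaks, alpha, n, n_indep)


# --------------------------------------------------------------------------
# waveform / MESOR
# --------------------------------------------------------------------------


@dataclass
class WaveformResult:
    hours: np.ndarray  # bin start hours (fractional when bin != 60 min)
    mean: np.ndarray  # NaN where a bin has no samples
    sd: np.ndarray
    n: np.ndarray
    mesor: float
    phase: list[int]  # bin indices with mean strictly above MESOR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hour": self.hours, "mean": self.mean, "sd": self.sd, "n": self.n})


def waveform(series: pd.Series, segment_hours: int = 24, bin_minutes: int = 60,
             bin_offset_minutes: int = 0) -> WaveformResult:
    """Fold a clock-timed series into the average daily (or other) profile.

    Values are grouped by their clock time within a ``segment_hours`` cycle
    into ``bin_minutes`` bins (optionally shifted by ``bin_offset_minutes``
    so that e.g. HH:30 samples sit mid-bin); per-bin mean, SD and n are
    reported.  The MESOR is the mean of the non-empty bin means, and the
    phase the bins strictly above it.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("waveform needs a DatetimeIndex carrying clock time")
    y = series.to_numpy(dtype=float)
    keep = np.isfinite(y)
    idx = series.index[keep]
    y = y[keep]

    cycle_min = segment_hours * 60
    n_bins = cycle_min // bin_minutes
    minutes = (idx.hour * 60 + idx.minute + idx.second / 60.0 - bin_offset_minutes) % cycle_min
    bins = (minutes // bin_minutes).astype(int)

    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        vals = y[bins == b]
        n[b] = len(vals)
        if len(vals):
            mean[b] = vals.mean()
            sd[b] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    filled = np.isfinite(mean)
    if not filled.any():
        raise ValueError("no finite samples to fold")
    mesor = float(mean[filled].mean())
    phase = [int(b) for b in range(n_bins) if filled[b] and mean[b] > mesor]
    hours = (np.arange(n_bins) * bin_minutes + bin_offset_minutes) / 60.0
    return WaveformResult(hours, mean, sd, n, mesor, phase)


def phase_intervals(wf: WaveformResult) -> list[tuple[int, int]]:
    """Maximal contiguous above-MESOR bin runs, wrapping the cycle boundary.

    Returns inclusive ``(start_bin, end_bin)`` pairs; a singleton bin is the
    degenerate pair ``(b, b)``.  An empty phase gives an empty list; a phase
    covering every bin gives the full cycle ``(0, n_bins - 1)``.
    """
    n_bins = len(wf.hours)
    in_phase = np.zeros(n_bins, dtype=bool)
    in_phase[wf.phase] = True
    if not in_phase.any():
        return []
    if in_phase.all():
        return [(0, n_bins - 1)]
    # rotate so the sequence starts just after a gap, then scan runs
    start0 = int(np.flatnonzero(~in_phase)[0]) + 1
    runs = []
    run_start = None
    for k in range(n_bins):
        b = (start0 + k) % n_bins
        if in_phase[b]:
            if run_start is None:
                run_start = b
            run_end = b
        elif run_start is not None:
            runs.append((run_start, run_end))
            run_start = None
    if run_start is not None:
        runs.append((run_start, run_end))
    runs.sort(key=lambda r: r[0])
    return runs


def monthly_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Calendar-month mean, SD and n for every numeric column.

    Missing values are excluded column-wise.  The result has a PeriodIndex
    (one row per month) and a (column, statistic) MultiIndex on columns.
    """
    if not isinstance(df.index, pd.DatetimeIndex):
        raise TypeError("monthly_summary needs a DatetimeIndex")
    num = df.select_dtypes(include=[np.number])
    grouped = num.groupby(df.index.to_period("M"))
    out = grouped.agg(["mean", "std", "count"])
    out.index.name = "month"
    return out
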