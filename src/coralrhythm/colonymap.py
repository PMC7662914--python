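"""Whole-frame segmentation and behavioral time-series compilation.

The trained patch classifier is slid over a frame as overlapping windows
(default 30x30 at step 10).  The resulting map lives on the stride grid: one
cell per window position.  Because windows overlap, several windows cover
each cell's anchor pixel (the center of its own window); their softmax
vectors are averaged before the argmax, which smooths the map.  Coverage
percentages are computed over coral (non-background) cells only, and each
frame's percentages are joined with the nearest-in-time oceanographic record
to form the behavioral + environmental series downstream statistics consume.

Chlorophyll fluorescence is converted to concentration by the sensor's
day/night affine calibration (default dawn 06:00, dusk 21:30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time as dtime
from typing import Sequence

import numpy as np
import pandas as pd

from .fixtures import CLASS_IDS, OCEAN_COLUMNS
from .patchcnn import PatchClassifier

__all__ = ["StatusMap", "ChlCalibration", "segment_frame", "status_percentages",
           "calibrate_chlorophyll", "compile_series", "truth_to_grid"]

# ties in the averaged softmax resolve toward the more "active" class
_TIE_PRIORITY = (CLASS_IDS["bloated"], CLASS_IDS["non_bloated"],
                 CLASS_IDS["semi_bloated"], CLASS_IDS["background"])


@dataclass
class StatusMap:
    """Per-cell class assignment of one frame at stride resolution."""

    grid: np.ndarray  # int class ids, shape (floor((H-w)/s)+1, floor((W-w)/s)+1)
    window: int
    step: int
    aggregation: str = "softmax_mean"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")


@dataclass(frozen=True)
class ChlCalibration:
    """Day/night affine fluorescence-to-chlorophyll-a calibration."""

    day_slope: float = 1.050
    day_intercept: float = 1.0129
    night_slope: float = 0.963
    night_intercept: float = 0.2159
    dawn: dtime = dtime(6, 0)
    dusk: dtime = dtime(21, 30)

    def validate(self) -> None:
        if self.day_slope <= 0 or self.night_slope <= 0:
            raise ValueError("calibration slopes must be positive")


def segment_frame(
    img: np.ndarray,
    model: PatchClassifier,
    window: int = 30,
    step: int = 10,
    batch: int = 1024,
) -> StatusMap:
    """Classify every sliding-window position of a frame into a StatusMap."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    if step <= 0:
        raise ValueError("step must be positive")
    if window < 1 or window > min(h, w):
        raise ValueError(f"window {window} incompatible with frame {h}x{w}")
    g1 = (h - window) // step + 1
    g2 = (w - window) // step + 1

    probs = np.empty((g1, g2, 4), dtype=np.float32)
    # classify row-bands of windows to bound peak memory
    positions = [(i, j) for i in range(g1) for j in range(g2)]
    for k0 in range(0, len(positions), batch):
        chunk = positions[k0 : k0 + batch]
        stack = np.stack([img[i * step : i * step + window, j * step : j * step + window]
                          for i, j in chunk])
        p = model.predict_proba(stack)
        for (i, j), row in zip(chunk, p):
            probs[i, j] = row

    # average the softmax of all windows covering each cell's anchor pixel
    # (the center of the cell's own window)
    half = window // 2
    lo = int(np.ceil((half - window + 1) / step))
    hi = int(np.floor(half / step))
    acc = np.zeros_like(probs)
    cnt = np.zeros((g1, g2, 1), dtype=np.float32)
    for di in range(lo, hi + 1):
        for dj in range(lo, hi + 1):
            src_i0, src_i1 = max(0, di), min(g1, g1 + di)
            dst_i0, dst_i1 = max(0, -di), min(g1, g1 - di)
            src_j0, src_j1 = max(0, dj), min(g2, g2 + dj)
            dst_j0, dst_j1 = max(0, -dj), min(g2, g2 - dj)
            acc[dst_i0:dst_i1, dst_j0:dst_j1] += probs[src_i0:src_i1, src_j0:src_j1]
            cnt[dst_i0:dst_i1, dst_j0:dst_j1] += 1.0
    mean = acc / cnt

    # argmax with deterministic tie-break by class priority
    reordered = mean[..., list(_TIE_PRIORITY)]
    grid = np.asarray(_TIE_PRIORITY)[reordered.argmax(axis=-1)]
    return StatusMap(grid.astype(np.int64), window, step)


def status_percentages(status_map: StatusMap) -> tuple[float, float, float, bool]:
    """Coverage of (bloated, semi, non-bloated) over coral cells, plus empty flag.

    Background cells are excluded from the denominator; an all-background map
    returns (0, 0, 0, True).
    """
    grid = status_map.grid
    if grid.size == 0:
        raise ValueError("empty status map")
    coral = grid != CLASS_IDS["background"]
    n = int(coral.sum())
    if n == 0:
        return 0.0, 0.0, 0.0, True
    blo = 100.0 * float((grid == CLASS_IDS["bloated"]).sum()) / n
    semi = 100.0 * float((grid == CLASS_IDS["semi_bloated"]).sum()) / n
    non = 100.0 * float((grid == CLASS_IDS["non_bloated"]).sum()) / n
    return blo, semi, non, False


def truth_to_grid(truth: np.ndarray, window: int = 30, step: int = 10) -> StatusMap:
    """Downsample a per-pixel ground-truth label map to the stride grid.

    Each cell takes the label of its anchor pixel (window center), matching
    the geometry of :func:`segment_frame` — used to score segmentations
    against generator ground truth.
    """
    truth = np.asarray(truth)
    h, w = truth.shape
    g1 = (h - window) // step + 1
    g2 = (w - window) // step + 1
    half = window // 2
    rows = np.arange(g1) * step + half
    cols = np.arange(g2) * step + half
    return StatusMap(truth[np.ix_(rows, cols)].astype(np.int64), window, step)


def calibrate_chlorophyll(fl, t, cal: ChlCalibration | None = None):
    """Convert a fluorescence reading to chlorophyll-a via the day/night affine map.

    Daytime (dawn <= clock time < dusk) uses the day coefficients, otherwise
    the night ones.  ``fl`` may be scalar or array (with matching ``t``).
    """
    cal = cal or ChlCalibration()
    cal.validate()
    fl_arr = np.asarray(fl, dtype=float)
    if np.any(fl_arr < 0):
        raise ValueError("fluorescence must be >= 0")
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(t, dtype="datetime64[ns]")))
    clock = ts.hour * 60 + ts.minute
    dawn = cal.dawn.hour * 60 + cal.dawn.minute
    dusk = cal.dusk.hour * 60 + cal.dusk.minute
    is_day = (clock >= dawn) & (clock < dusk)
    out = np.where(is_day, cal.day_slope * fl_arr + cal.day_intercept,
                   cal.night_slope * fl_arr + cal.night_intercept)
    return float(out[0]) if np.isscalar(fl) or fl_arr.ndim == 0 else out


def compile_series(
    frames: Sequence[tuple, ],
    ocean: pd.DataFrame | None = None,
    tolerance: str | pd.Timedelta = "30min",
    chl_cal: ChlCalibration | None = None,
) -> pd.DataFrame:
    """Build the behavioral + oceanographic series from segmented frames.

    ``frames`` is a sequence of ``(timestamp, StatusMap)``; ``ocean`` a
    DataFrame of sensor records indexed (or keyed by a ``timestamp`` column)
    in time.  Sensor values are joined by nearest timestamp within
    ``tolerance``; frames without a match keep NaN sensor fields.  When
    ``chl_cal`` is given, a ``chl_a`` column is derived from
    ``chl_fluorescence``.
    """
    if not len(frames):
        raise ValueError("no frames to compile")
    ts = pd.DatetimeIndex([pd.Timestamp(t) for t, _ in frames])
    if ts.has_duplicates:
        raise ValueError("duplicate frame timestamps")
    rows = []
    for t, smap in frames:
        blo, semi, non, empty = status_percentages(smap)
        rows.append({"timestamp": pd.Timestamp(t), "bloated_pct": blo,
                     "semi_bloated_pct": semi, "non_bloated_pct": non, "empty_frame": empty})
    beh = pd.DataFrame(rows).sort_values("timestamp").reset_index(drop=True)

    if ocean is not None:
        oc = ocean.reset_index() if ocean.index.name == "timestamp" else ocean.copy()
        if "timestamp" not in oc.columns:
            raise ValueError("ocean data needs a 'timestamp' column or index")
        oc["timestamp"] = pd.to_datetime(oc["timestamp"])
        # a sensor record may carry behavioral columns (e.g. a simulated study
        # record); the compiled series keeps the frame-derived ones
        clash = [c for c in ("bloated_pct", "semi_bloated_pct", "non_bloated_pct",
                             "empty_frame") if c in oc.columns]
        oc = oc.drop(columns=clash).sort_values("timestamp")
        beh = pd.merge_asof(beh, oc, on="timestamp", direction="nearest",
                            tolerance=pd.Timedelta(tolerance))
    else:
        for col in OCEAN_COLUMNS:
            beh[col] = np.nan

    if chl_cal is not None and "chl_fluorescence" in beh.columns:
        mask = beh["chl_fluorescence"].notna()
        beh.loc[mask, "chl_a"] = calibrate_chlorophyll(
            beh.loc[mask, "chl_fluorescence"].to_numpy(),
            beh.loc[mask, "timestamp"].to_numpy(), chl_cal)
    return beh.set_index("timestamp")
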