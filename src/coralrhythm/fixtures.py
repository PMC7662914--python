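"""Synthetic ground-truthed fixtures: coral-like colony frames and rhythmic series.

The image generator paints rectangular colony regions in one of the three
polyp-activity statuses on a dark seafloor background.  Statuses differ by
texture, not by geometry: a bloated colony surface (polyps extruded) reads as
bright red speckled with near-white polyp dots, a non-bloated surface (polyps
retracted) as darker, smoother red, and the transient semi-bloated state as a
spatial mixture of both.  The series generator emits an hourly behavioral +
oceanographic record with a circadian activity rhythm, a semidiurnal
tidal-like depth cycle, sensor noise and optional acquisition gaps, matching
the structure of a cabled-observatory deployment record.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "STATUS_NAMES",
    "CLASS_IDS",
    "SceneSpec",
    "SeriesSpec",
    "generate_colony_image",
    "generate_series",
    "scene_for_coverage",
    "truth_percentages",
    "save_scene",
    "OCEAN_COLUMNS",
    "SERIES_COLUMNS",
]

#: class-id convention shared by the whole package
CLASS_IDS = {"background": 0, "bloated": 1, "semi_bloated": 2, "non_bloated": 3}
STATUS_NAMES = ("bloated", "semi_bloated", "non_bloated")

OCEAN_COLUMNS = (
    "temperature_C",
    "salinity_PSU",
    "turbidity_NTU",
    "chl_fluorescence",
    "depth_m",
)
SERIES_COLUMNS = ("bloated_pct", "semi_bloated_pct", "non_bloated_pct") + OCEAN_COLUMNS


@dataclass(frozen=True)
class SceneSpec:
    """Layout of one synthetic colony frame.

    ``regions`` is a list of ``(rect, status)`` where ``rect`` is a half-open
    0-based rectangle ``(row0, col0, row1, col1)`` and ``status`` one of
    :data:`STATUS_NAMES`.  Overlapping rectangles are only legal when they
    agree on the status.
    """

    width_px: int = 256
    height_px: int = 256
    regions: Sequence[tuple[tuple[int, int, int, int], str]] = ()
    background_color: tuple[int, int, int] = (16, 20, 26)
    base_red: tuple[int, int, int] = (180, 45, 38)
    brightness_jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < 30 or self.height_px < 30:
            raise ValueError("frame must be at least 30x30 px")
        for rect, status in self.regions:
            r0, c0, r1, c1 = rect
            if status not in STATUS_NAMES:
                raise ValueError(f"unknown status {status!r}")
            if not (0 <= r0 < r1 <= self.height_px and 0 <= c0 < c1 <= self.width_px):
                raise ValueError(f"rect {rect} outside {self.height_px}x{self.width_px} frame")
        if not 0.0 <= self.brightness_jitter < 1.0:
            raise ValueError("brightness_jitter must be in [0, 1)")


def _poisson_disk(rng: np.random.Generator, h: int, w: int, min_dist: float, n_target: int):
    """Dart-throwing Poisson-disk sample: random points no closer than min_dist."""
    pts: list[tuple[float, float]] = []
    for _ in range(n_target * 30):
        p = (rng.uniform(0, h), rng.uniform(0, w))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_dist**2 for q in pts):
            pts.append(p)
            if len(pts) >= n_target:
                break
    return np.asarray(pts).reshape(-1, 2)


def _bloated_texture(rng: np.random.Generator, h: int, w: int, base: np.ndarray) -> np.ndarray:
    """Bright red base + Poisson-disk near-white dots emulating extruded polyps."""
    tex = base[None, None, :] + rng.normal(0, 6, (h, w, 3))
    tex[..., 0] += 25.0  # extruded polyps catch the lamp: brighter red overall
    n_dots = max(4, int(h * w / 36))
    pts = _poisson_disk(rng, h, w, min_dist=5.0, n_target=n_dots)
    rr, cc = np.mgrid[0:h, 0:w]
    for pr, pc in pts:
        d2 = (rr - pr) ** 2 + (cc - pc) ** 2
        dot = np.exp(-d2 / (2 * 1.3**2))
        tex[..., 0] += 70 * dot
        tex[..., 1] += 80 * dot
        tex[..., 2] += 60 * dot
    return tex


def _non_bloated_texture(rng: np.random.Generator, h: int, w: int, base: np.ndarray) -> np.ndarray:
    """Darker, smooth red: retracted polyps leave the bare rind visible."""
    tex = base[None, None, :] * 0.6 + rng.normal(0, 10, (h, w, 3))
    for ch in range(3):
        tex[..., ch] = ndimage.gaussian_filter(tex[..., ch], sigma=2.5)
    return tex


def _semi_texture(rng: np.random.Generator, h: int, w: int, base: np.ndarray) -> np.ndarray:
    """Half-and-half checkerboard tiling of the two pure textures."""
    tile = 10
    blo = _bloated_texture(rng, h, w, base)
    non = _non_bloated_texture(rng, h, w, base)
    rr, cc = np.mgrid[0:h, 0:w]
    chk = ((rr // tile) + (cc // tile)) % 2 == 0
    return np.where(chk[..., None], blo, non)


_TEXTURES = {
    "bloated": _bloated_texture,
    "semi_bloated": _semi_texture,
    "non_bloated": _non_bloated_texture,
}


def generate_colony_image(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a colony frame and its per-pixel ground truth.

    Returns
    -------
    image : uint8 array, shape (H, W, 3), RGB
    truth : uint8 array, shape (H, W), values per :data:`CLASS_IDS`
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    bg = np.asarray(spec.background_color, float)
    img = bg[None, None, :] + rng.normal(0, 3, (h, w, 3))
    truth = np.zeros((h, w), dtype=np.uint8)

    base = np.asarray(spec.base_red, float)
    for rect, status in spec.regions:
        r0, c0, r1, c1 = rect
        prior = truth[r0:r1, c0:c1]
        conflict = (prior != 0) & (prior != CLASS_IDS[status])
        if conflict.any():
            raise ValueError(f"rect {rect} overlaps a region with a different status")
        img[r0:r1, c0:c1] = _TEXTURES[status](rng, r1 - r0, c1 - c0, base)
        truth[r0:r1, c0:c1] = CLASS_IDS[status]

    if spec.brightness_jitter:
        img *= 1.0 + rng.uniform(-spec.brightness_jitter, spec.brightness_jitter)
    return np.clip(img, 0, 255).astype(np.uint8), truth


def truth_percentages(truth: np.ndarray) -> dict[str, float]:
    """Coverage percentage of each status over coral (non-background) pixels."""
    coral = truth != 0
    n = int(coral.sum())
    if n == 0:
        return {s: 0.0 for s in STATUS_NAMES}
    return {s: 100.0 * float((truth == CLASS_IDS[s]).sum()) / n for s in STATUS_NAMES}


def save_scene(image: np.ndarray, truth: np.ndarray, stem) -> None:
    """Write ``<stem>.png``, ``<stem>_truth.png`` and a JSON class legend."""
    import imageio.v3 as iio

    stem = str(stem)
    iio.imwrite(stem + ".png", image)
    iio.imwrite(stem + "_truth.png", truth)
    with open(stem + "_legend.json", "w") as fh:
        json.dump(CLASS_IDS, fh, indent=1)


def scene_for_coverage(
    bloated_pct: float,
    semi_pct: float = 0.0,
    width_px: int = 256,
    height_px: int = 256,
    margin: int = 24,
    seed: int = 0,
) -> SceneSpec:
    """Scene whose colony shows the requested status coverage.

    A single colony rectangle (frame minus ``margin``) is split into three
    vertical bands — bloated, semi-bloated, non-bloated — whose widths match
    the requested percentages, so the ground-truth coverage equals the input
    up to pixel quantization.  Used to turn a behavioral series into a frame
    sequence with known truth.
    """
    if not (0 <= bloated_pct <= 100 and 0 <= semi_pct <= 100 - bloated_pct):
        raise ValueError("percentages must be within [0, 100] and sum to <= 100")
    r0, c0 = margin, margin
    r1, c1 = height_px - margin, width_px - margin
    w = c1 - c0
    cb = c0 + int(round(w * bloated_pct / 100.0))
    cs = cb + int(round(w * semi_pct / 100.0))
    regions = []
    if cb > c0:
        regions.append(((r0, c0, r1, cb), "bloated"))
    if cs > cb:
        regions.append(((r0, cb, r1, cs), "semi_bloated"))
    if c1 > cs:
        regions.append(((r0, cs, r1, c1), "non_bloated"))
    return SceneSpec(width_px=width_px, height_px=height_px, regions=tuple(regions), seed=seed)


# --------------------------------------------------------------------------
# rhythmic multiparametric series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SeriesSpec:
    """Parameters of the synthetic hourly behavioral + oceanographic record.

    The bloated percentage follows ``mesor + amplitude*cos(...)`` with the
    peak at ``rhythm_peak_hour`` (clock hours); the remaining surface is split
    between non-bloated (55%) and semi-bloated (45%), putting both in
    antiphase with the bloated rhythm.  Depth oscillates at
    ``depth_period_min`` (default the semidiurnal lunar tide, ~12.4 h).
    Oceanographic columns are NaN inside ``gap_windows``.
    """

    start: str = "2018-02-02T00:30:00"
    n_hours: int = 720
    rhythm_period_min: float = 1440.0
    rhythm_peak_hour: float = 21.5
    rhythm_mesor: float = 50.0
    rhythm_amplitude: float = 30.0
    noise_sd: float = 5.0
    depth_period_min: float = 745.0
    gap_windows: Sequence[tuple[str, str]] = ()
    n_fov_switches: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.rhythm_period_min <= 0:
            raise ValueError("rhythm_period_min must be positive")
        if self.depth_period_min <= 0:
            raise ValueError("depth_period_min must be positive")
        if self.n_hours < 1:
            raise ValueError("n_hours must be >= 1")
        if not (0 <= self.rhythm_mesor - self.rhythm_amplitude
                and self.rhythm_mesor + self.rhythm_amplitude <= 100):
            raise ValueError("mesor +/- amplitude must stay within [0, 100]")


def generate_series(spec: SeriesSpec) -> pd.DataFrame:
    """Simulate an hourly activity + oceanography record.

    Returns a DataFrame indexed by timestamp with columns
    :data:`SERIES_COLUMNS` plus a binary ``fov`` camera-geometry dummy that
    flips at ``n_fov_switches`` random epochs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    idx = pd.date_range(spec.start, periods=spec.n_hours, freq="1h")
    t_min = (idx - idx[0]).total_seconds().to_numpy() / 60.0
    clock0 = idx[0].hour + idx[0].minute / 60.0

    phase = 2 * np.pi * (t_min / 60.0 + clock0 - spec.rhythm_peak_hour) / (spec.rhythm_period_min / 60.0)
    bloated = spec.rhythm_mesor + spec.rhythm_amplitude * np.cos(phase)
    bloated = np.clip(bloated + rng.normal(0, spec.noise_sd, spec.n_hours), 0.0, 100.0)
    rest = 100.0 - bloated
    non_bloated = rest * 0.55
    semi = rest - non_bloated

    tide = np.cos(2 * np.pi * t_min / spec.depth_period_min)
    sun = np.cos(2 * np.pi * (t_min / 60.0 + clock0 - 14.0) / 24.0)
    df = pd.DataFrame(
        {
            "bloated_pct": bloated,
            "semi_bloated_pct": semi,
            "non_bloated_pct": non_bloated,
            "temperature_C": 6.52 + 0.25 * sun + rng.normal(0, 0.08, spec.n_hours),
            "salinity_PSU": 34.74 + rng.normal(0, 0.05, spec.n_hours),
            "turbidity_NTU": np.maximum(
                0.0, 6.6 + 2.0 * np.cos(2 * np.pi * (t_min - 120.0) / spec.depth_period_min)
                + rng.normal(0, 0.8, spec.n_hours)
            ),
            "chl_fluorescence": np.maximum(
                0.0, 6.0 + 1.5 * np.cos(phase) + rng.normal(0, 0.5, spec.n_hours)
            ),
            "depth_m": 250.10 + 1.05 * tide + rng.normal(0, 0.03, spec.n_hours),
        },
        index=idx,
    )
    df.index.name = "timestamp"

    fov = np.zeros(spec.n_hours, dtype=int)
    if spec.n_fov_switches > 0 and spec.n_hours > 2:
        cuts = np.sort(rng.choice(np.arange(1, spec.n_hours), size=min(spec.n_fov_switches, spec.n_hours - 1), replace=False))
        state = 0
        prev = 0
        for c in list(cuts) + [spec.n_hours]:
            fov[prev:c] = state
            state ^= 1
            prev = c
    df["fov"] = fov

    for start, end in spec.gap_windows:
        in_gap = (df.index >= pd.Timestamp(start)) & (df.index <= pd.Timestamp(end))
        df.loc[in_gap, list(OCEAN_COLUMNS)] = np.nan
    return df
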