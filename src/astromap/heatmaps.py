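"""Activity heatmaps, the random-placement null, and translated-PCC similarity.

A heatmap sums binarized event footprints over time: each pixel counts the
events whose footprint covers it during a chosen set of frames.  Hotspot
structure is judged against a Monte-Carlo null in which ellipses — with areas
resampled from the real event pool, random orientation and eccentricity —
are placed uniformly inside the cell mask until their cumulative area matches
the real total.  Heatmap similarity is the maximum Pearson correlation over
integer translations of one map against the other, the same metric used for
within-day subsequences, rest-vs-run state maps, and between-day stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .behavior import StateLabels
from .events import EventTable
from .footprints import decode_rle, rasterize_ellipse
from .synth import AstrocyteMask

__all__ = [
    "ActivityHeatmap",
    "NullConfig",
    "HeatmapComparison",
    "build_heatmap",
    "restrict_to_state",
    "simulate_random_heatmap",
    "max_xcorr_pcc",
    "align_by_activity_mask",
    "activity_mask",
    "shift_heatmap",
    "split_state_subsequences",
    "subsequence_similarity_curve",
    "heatmap_intensity_histogram",
]


@dataclass
class ActivityHeatmap:
    """Time-summed footprint counts with normalization bookkeeping.

    ``raw`` grids hold integer event counts per pixel; ``per_minute`` divides
    by the minutes of frames used; ``max_one`` additionally rescales so the
    maximum pixel is exactly 1.
    """

    grid: np.ndarray
    frames_used: int
    minutes_used: float
    normalization: str = "raw"
    source_state: str = "all"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if (self.grid < 0).any():
            raise ValueError("heatmap values must be nonnegative")
        if self.normalization not in ("raw", "per_minute", "max_one"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "max_one" and self.grid.any():
            if not np.isclose(self.grid.max(), 1.0):
                raise ValueError("max_one heatmap must have maximum exactly 1")


@dataclass
class NullConfig:
    """Random-placement null: ellipse areas resampled from real events."""

    mask: AstrocyteMask
    area_pool: np.ndarray  # um^2 per real event
    seed: int = 0
    eccentricity_range: tuple[float, float] = (0.0, 0.95)
    max_placement_attempts: int = 100_000

    def __post_init__(self):
        self.area_pool = np.asarray(self.area_pool, dtype=float)
        if self.area_pool.size == 0:
            raise ValueError("area_pool must be nonempty")
        if (self.area_pool <= 0).any():
            raise ValueError("event areas must be positive")
        lo, hi = self.eccentricity_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("eccentricity_range must satisfy 0 <= lo <= hi < 1")


@dataclass(frozen=True)
class HeatmapComparison:
    """Best integer translation of b against a and the Pearson correlation there."""

    translation: tuple[int, int]  # (d_row, d_col) applied to the second map
    max_pcc: float


def _normalize(grid: np.ndarray, frames_used: int, frame_rate: float, normalization: str):
    minutes = frames_used / frame_rate / 60.0
    out = grid.astype(float)
    if normalization in ("per_minute", "max_one"):
        out = out / minutes
    if normalization == "max_one" and out.max() > 0:
        out = out / out.max()
    return out, minutes


def build_heatmap(
    table: EventTable,
    frame_subset: np.ndarray | None = None,
    normalization: str = "raw",
    source_state: str = "all",
    membership: str = "interval",
) -> ActivityHeatmap:
    """Sum binarized event footprints over a frame subset.

    ``frame_subset`` is a boolean mask over recording frames (``None`` means
    all frames).  With ``membership='interval'`` an event contributes when its
    active span ``[t0, t1]`` intersects the subset; ``'onset'`` requires the
    onset frame itself to be in the subset.  Each contributing event adds 1
    to every pixel of its footprint.
    """
    shape = tuple(table.meta["grid_shape"])
    n_frames = int(table.meta.get("n_frames", table.df.t1_frame.max() + 1 if len(table.df) else 1))
    if frame_subset is None:
        frame_subset = np.ones(n_frames, dtype=bool)
    frame_subset = np.asarray(frame_subset, dtype=bool)
    if not frame_subset.any():
        raise ValueError("empty frame subset")
    if membership not in ("interval", "onset"):
        raise ValueError("membership must be 'interval' or 'onset'")

    t0 = table.df.t0_frame.to_numpy()
    t1 = table.df.t1_frame.to_numpy()
    if membership == "onset":
        include = frame_subset[np.clip(t0, 0, frame_subset.size - 1)]
    else:
        csum = np.concatenate(([0], np.cumsum(frame_subset)))
        lo = np.clip(t0, 0, frame_subset.size - 1)
        hi = np.clip(t1, 0, frame_subset.size - 1)
        include = (csum[hi + 1] - csum[lo]) > 0

    flat = np.zeros(shape[0] * shape[1], dtype=float)
    for rle in table.df.footprint[include]:
        flat[decode_rle(rle)] += 1.0
    frames_used = int(frame_subset.sum())
    grid, minutes = _normalize(flat.reshape(shape), frames_used, table.frame_rate, normalization)
    return ActivityHeatmap(grid, frames_used, minutes, normalization, source_state)


def restrict_to_state(labels: StateLabels, state: str) -> np.ndarray:
    """Boolean frame mask for a behavioral state (base or substate) or 'all'."""
    return labels.frames_in_state(state)


def simulate_random_heatmap(
    config: NullConfig, frame_rate: float = 10.3, frames_used: int | None = None,
    normalization: str = "raw",
) -> ActivityHeatmap:
    """Monte-Carlo null heatmap from randomly placed ellipses inside the mask.

    Areas are sampled with replacement from the real event pool; orientation
    is uniform, eccentricity uniform in the configured range, and centers
    uniform over mask pixels.  Ellipses are clipped to the mask and their
    clipped area counts toward the stopping total; placement stops once the
    cumulative placed area reaches the pool's total area (the last ellipse
    may overshoot).
    """
    rng = np.random.default_rng(config.seed)
    mask = config.mask.grid
    px2 = config.mask.pixel_size**2
    mask_flat = mask.ravel()
    candidates = np.flatnonzero(mask_flat)
    target = config.area_pool.sum()
    grid = np.zeros(mask.size, dtype=float)
    placed = 0.0
    attempts = 0
    lo_e, hi_e = config.eccentricity_range
    while placed < target:
        attempts += 1
        if attempts > config.max_placement_attempts:
            raise RuntimeError(
                f"random placement did not reach the target area in "
                f"{config.max_placement_attempts} attempts"
            )
        area = rng.choice(config.area_pool)
        ecc = rng.uniform(lo_e, hi_e)
        axis_ratio = float(np.sqrt(1.0 - ecc**2))
        theta = rng.uniform(0.0, np.pi)
        center = candidates[rng.integers(candidates.size)]
        r0, c0 = divmod(int(center), mask.shape[1])
        pix = rasterize_ellipse((float(r0), float(c0)), area / px2, axis_ratio, theta, mask.shape)
        pix = pix[mask_flat[pix]]
        if pix.size == 0:
            continue
        grid[pix] += 1.0
        placed += pix.size * px2
    frames_used = frames_used if frames_used is not None else 1
    grid2, minutes = _normalize(grid.reshape(mask.shape), frames_used, frame_rate, normalization)
    return ActivityHeatmap(grid2, frames_used, minutes, normalization, "null")


def _as_grid(h) -> np.ndarray:
    return h.grid if isinstance(h, ActivityHeatmap) else np.asarray(h, dtype=float)


def max_xcorr_pcc(
    a, b, max_shift: int | None = None, min_overlap_fraction: float = 0.5
) -> HeatmapComparison:
    """Maximum Pearson correlation over integer translations of b against a.

    For every translation within ``+/- max_shift`` (default: a quarter of the
    grid), the Pearson correlation is computed over the overlap region with
    zeros included; translations whose overlap is below
    ``min_overlap_fraction`` of the grid are excluded.  Sliding sums are
    FFT-accelerated and match an exhaustive per-shift computation.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    if ga.shape != gb.shape:
        raise ValueError("heatmaps must share a grid shape")
    if np.allclose(ga, ga.flat[0]) or np.allclose(gb, gb.flat[0]):
        raise ValueError("constant image: Pearson correlation undefined")
    if max_shift is None:
        max_shift = min(ga.shape) // 4
    ones_a = np.ones_like(ga)
    flip = lambda x: x[::-1, ::-1]  # noqa: E731
    n = fftconvolve(ones_a, flip(np.ones_like(gb)), mode="full")
    sa = fftconvolve(ga, flip(np.ones_like(gb)), mode="full")
    sb = fftconvolve(ones_a, flip(gb), mode="full")
    sab = fftconvolve(ga, flip(gb), mode="full")
    saa = fftconvolve(ga**2, flip(np.ones_like(gb)), mode="full")
    sbb = fftconvolve(ones_a, flip(gb**2), mode="full")

    c0, c1 = ga.shape[0] - 1, ga.shape[1] - 1  # zero-shift index in 'full' output
    sl0 = slice(c0 - max_shift, c0 + max_shift + 1)
    sl1 = slice(c1 - max_shift, c1 + max_shift + 1)
    n, sa, sb, sab, saa, sbb = (m[sl0, sl1] for m in (n, sa, sb, sab, saa, sbb))
    n = np.rint(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sab - sa * sb
        var_a = n * saa - sa**2
        var_b = n * sbb - sb**2
        r = cov / np.sqrt(var_a * var_b)
    r[(var_a <= 1e-9) | (var_b <= 1e-9)] = np.nan
    r[n < min_overlap_fraction * ga.size] = np.nan
    if np.isnan(r).all():
        raise ValueError("no translation satisfies the overlap requirement")
    idx = np.unravel_index(np.nanargmax(r), r.shape)
    # report the displacement of b relative to a: if b equals a translated by
    # (dr, dc), the returned translation is (dr, dc)
    d_row = int(max_shift - idx[0])
    d_col = int(max_shift - idx[1])
    return HeatmapComparison((d_row, d_col), float(r[idx]))


def activity_mask(table: EventTable) -> np.ndarray:
    """Union of all event footprints: the boundary of observed cell activity."""
    shape = tuple(table.meta["grid_shape"])
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    for rle in table.df.footprint:
        flat[decode_rle(rle)] = True
    if not flat.any():
        raise ValueError("recording has no event footprints")
    return flat.reshape(shape)


def align_by_activity_mask(a: EventTable, b: EventTable, max_shift: int | None = None) -> tuple[int, int]:
    """Translation aligning two recordings via their binary activity masks.

    Builds the union-of-footprints mask of each recording and returns the
    displacement of b's mask relative to a's at maximum Pearson
    cross-correlation.  Undo it with ``shift_heatmap(b_map, (-dr, -dc))``
    before comparing heatmaps across days.
    """
    ma = activity_mask(a).astype(float)
    mb = activity_mask(b).astype(float)
    return max_xcorr_pcc(ma, mb, max_shift=max_shift).translation


def shift_heatmap(h: ActivityHeatmap, translation: tuple[int, int]) -> ActivityHeatmap:
    """Integer-translate a heatmap, zero-filling the exposed border."""
    g = np.zeros_like(h.grid)
    dr, dc = translation
    src = h.grid
    r_lo, r_hi = max(0, dr), min(src.shape[0], src.shape[0] + dr)
    c_lo, c_hi = max(0, dc), min(src.shape[1], src.shape[1] + dc)
    g[r_lo:r_hi, c_lo:c_hi] = src[r_lo - dr : r_hi - dr, c_lo - dc : c_hi - dc]
    return ActivityHeatmap(g, h.frames_used, h.minutes_used, h.normalization, h.source_state)


def split_state_subsequences(labels: StateLabels, state: str, k: int = 3) -> list[np.ndarray]:
    """Partition a state's frames into k contiguous-in-state-time blocks.

    Blocks are contiguous in the ordered sequence of state frames (state
    time), not wall-clock time, and their sizes differ by at most one frame.
    Returns k boolean frame masks whose union is the state frame set.
    """
    frames = np.flatnonzero(labels.frames_in_state(state))
    if frames.size < k:
        raise ValueError(f"state {state!r} occupies {frames.size} frames; need at least {k}")
    out = []
    for chunk in np.array_split(frames, k):
        m = np.zeros(labels.n_frames, dtype=bool)
        m[chunk] = True
        out.append(m)
    return out


def subsequence_similarity_curve(
    table: EventTable,
    durations_min: list[float],
    max_shift: int | None = None,
) -> list[tuple[float, float]]:
    """Similarity of initial-subsequence heatmaps to the full-recording heatmap.

    For each duration (minutes) the heatmap of the recording's first
    ``duration`` minutes is compared (max translated PCC) to the heatmap of
    the whole recording; durations exceeding the recording are skipped with a
    warning.  On a stationary hotspot process the curve rises toward 1.
    """
    n_frames = int(table.meta["n_frames"])
    fr = table.frame_rate
    full = build_heatmap(table, None, normalization="max_one")
    out = []
    for d in durations_min:
        n_sub = int(round(d * 60.0 * fr))
        if n_sub > n_frames:
            warnings.warn(f"duration {d} min exceeds the recording; skipped", stacklevel=2)
            continue
        subset = np.zeros(n_frames, dtype=bool)
        subset[:n_sub] = True
        sub = build_heatmap(table, subset, normalization="max_one")
        out.append((d, max_xcorr_pcc(full, sub, max_shift=max_shift).max_pcc))
    return out


def heatmap_intensity_histogram(
    h: ActivityHeatmap, n_bins: int = 20, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of heatmap pixel intensities over the mask (or whole grid).

    Returns ``(counts, bin_edges)``; counts sum to the number of pixels
    considered.  Comparing these histograms between real and null maps shows
    the heavier high-intensity tail that hotspot structure produces.
    """
    values = h.grid[mask] if mask is not None else h.grid.ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, max(values.max(), 1e-12)))
    return counts, edges
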