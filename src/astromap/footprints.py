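"""Binary event footprints: run-length codec and ellipse rasterization.

A footprint is the set of pixels covered by one Ca2+ microdomain event at its
maximal spatial extent.  Footprints travel inside flat CSV event tables as
run-length-encoded strings over 0-based, row-major flat pixel indices.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "encode_rle",
    "decode_rle",
    "rasterize_ellipse",
    "footprint_to_mask",
]


def encode_rle(flat_indices: np.ndarray) -> str:
    """Encode sorted flat pixel indices as ``start:length`` runs joined by ``;``."""
    idx = np.asarray(flat_indices, dtype=np.int64)
    if idx.size == 0:
        return ""
    idx = np.unique(idx)
    breaks = np.flatnonzero(np.diff(idx) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return ";".join(f"{idx[s]}:{e - s + 1}" for s, e in zip(starts, ends))


def decode_rle(rle: str) -> np.ndarray:
    """Decode a run-length string back to sorted flat pixel indices."""
    if not rle:
        return np.empty(0, dtype=np.int64)
    parts = [run.split(":") for run in rle.split(";")]
    chunks = [np.arange(int(s), int(s) + int(n), dtype=np.int64) for s, n in parts]
    return np.concatenate(chunks)


def footprint_to_mask(rle: str, shape: tuple[int, int]) -> np.ndarray:
    """Render a run-length footprint as a binary 2D array."""
    mask = np.zeros(int(shape[0]) * int(shape[1]), dtype=bool)
    mask[decode_rle(rle)] = True
    return mask.reshape(shape)


def rasterize_ellipse(
    center_rc: tuple[float, float],
    area_px: float,
    axis_ratio: float,
    theta: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Pixels of an ellipse of the given area, clipped to the grid.

    Parameters
    ----------
    center_rc : (row, col) center in pixel coordinates.
    area_px : target area in pixels; semi-axes are ``a = sqrt(area/(pi*q))``
        and ``b = q*a`` with ``q = axis_ratio``.
    axis_ratio : minor/major semi-axis ratio in (0, 1].
    theta : orientation of the major axis, radians.
    shape : grid shape; pixels outside are clipped.

    Returns
    -------
    Flat (row-major) pixel indices.  Always contains at least the center
    pixel when the center lies on the grid, so sub-pixel areas do not vanish.
    """
    if area_px <= 0:
        raise ValueError("area_px must be positive")
    if not (0 < axis_ratio <= 1):
        raise ValueError("axis_ratio must be in (0, 1]")
    r0, c0 = center_rc
    a = np.sqrt(area_px / (np.pi * axis_ratio))
    b = axis_ratio * a
    half = int(np.ceil(a)) + 1
    rows = np.arange(max(0, int(np.floor(r0)) - half), min(shape[0], int(np.ceil(r0)) + half + 1))
    cols = np.arange(max(0, int(np.floor(c0)) - half), min(shape[1], int(np.ceil(c0)) + half + 1))
    if rows.size == 0 or cols.size == 0:
        return np.empty(0, dtype=np.int64)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    dy = rr - r0
    dx = cc - c0
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    flat = (rr[inside] * shape[1] + cc[inside]).astype(np.int64)
    if flat.size == 0:
        ri, ci = int(round(r0)), int(round(c0))
        if 0 <= ri < shape[0] and 0 <= ci < shape[1]:
            flat = np.array([ri * shape[1] + ci], dtype=np.int64)
    return flat
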