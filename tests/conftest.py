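import numpy as np
import pytest

import astromap as am
from astromap.behavior import StateLabels


def make_labels(base, frame_rate=10.3):
    base = np.asarray(base, dtype=object)
    return StateLabels(base, np.full(base.size, "none", dtype=object), frame_rate)


def rest_labels(seconds, frame_rate=10.3):
    n = int(round(seconds * frame_rate))
    return make_labels(["rest"] * n, frame_rate)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced grid that preserves the real field-of-view geometry (94 um)."""
    return am.GeneratorConfig(grid_shape=(64, 64), pixel_size=94 / 64, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    rng = small_cfg.rng()
    mask = am.make_astrocyte_mask(small_cfg, rng)
    field = am.make_hotspot_field(mask, small_cfg, rng)
    return mask, field


@pytest.fixture(scope="session")
def default_events_50k():
    """50,000 events from the default generator configuration, fixed seed.

    A mixed rest/run recording long enough to yield > 50k events at the
    default rates; the first 50k events are kept.
    """
    cfg = am.GeneratorConfig(seed=0)
    rng = cfg.rng()
    mask = am.make_astrocyte_mask(cfg, rng)
    field = am.make_hotspot_field(mask, cfg, rng)
    trace = am.make_behavior_trace(25_000, config=cfg, rng=rng)
    labels = am.segment_run_rest(trace)
    table = am.sample_events(field, labels, cfg, rng)
    assert len(table) >= 50_000
    return am.EventTable(table.df.iloc[:50_000].reset_index(drop=True), table.meta)


# ----------------------------------------------------------------------
# brute-force reference implementations


def oracle_segment(speed, frame_rate, gap_tolerance=1.5, motion_epsilon=0.5):
    """Literal reading of the continuity rule, one frame at a time."""
    n = len(speed)
    moving = [s > motion_epsilon for s in speed]
    out = list(moving)
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            gap_s = (j - i) / frame_rate
            interior = i > 0 and j < n
            if interior and gap_s < gap_tolerance:
                for k in range(i, j):
                    out[k] = True
            i = j
        else:
            i += 1
    return ["run" if m else "rest" for m in out]


def oracle_transitions(base, frame_rate, pre_stable=3.0, post_stable=6.0):
    """Window-scanning reference for stable rest/run transitions."""
    import math

    n_pre = math.ceil(pre_stable * frame_rate)
    n_post = math.ceil(post_stable * frame_rate)
    n = len(base)
    found = []
    for f in range(1, n):
        if base[f] == base[f - 1]:
            continue
        kind = "rest_to_run" if base[f] == "run" else "run_to_rest"
        before = "rest" if kind == "rest_to_run" else "run"
        after = "run" if kind == "rest_to_run" else "rest"
        if f - n_pre < 0 or f + n_post > n:
            continue
        if all(base[k] == before for k in range(f - n_pre, f)) and all(
            base[k] == after for k in range(f, f + n_post)
        ):
            found.append((kind, f))
    return found


def oracle_max_pcc(a, b, max_shift, min_overlap_fraction=0.5):
    """Exhaustive per-shift Pearson correlation over the overlap region.

    Reports the displacement (dr, dc) of b relative to a: hypothesize
    b == a translated by (dr, dc) and correlate a with b moved back.
    """
    import numpy as np

    best = (None, -np.inf)
    rows, cols = a.shape
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            # b moved back by (dr, dc): b'[i, j] = b[i + dr, j + dc]
            r_lo, r_hi = max(0, -dr), min(rows, rows - dr)
            c_lo, c_hi = max(0, -dc), min(cols, cols - dc)
            if (r_hi - r_lo) * (c_hi - c_lo) < min_overlap_fraction * a.size:
                continue
            pa = a[r_lo:r_hi, c_lo:c_hi].ravel()
            pb = b[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc].ravel()
            if pa.std() == 0 or pb.std() == 0:
                continue
            r = np.corrcoef(pa, pb)[0, 1]
            if r > best[1]:
                best = ((dr, dc), r)
    return best
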