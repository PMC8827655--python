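"""End-to-end orchestration: synthesize or load a recording, then analyze it.

``run_pipeline`` chains the full analysis — state segmentation, event-state
assignment, per-state summaries, transition-aligned profiles, activity
heatmaps, the random-placement null, and heatmap comparisons — writing every
artifact plus a run log with seeds, the config hash, and library versions.
All randomness flows from the single config seed, so two runs with the same
config produce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import io as amio
from .behavior import annotate_touch_states, extract_transitions, segment_run_rest
from .events import (
    assign_states,
    load_and_filter_events,
    state_summary,
    summaries_to_frame,
    transition_profile,
)
from .heatmaps import (
    NullConfig,
    build_heatmap,
    max_xcorr_pcc,
    restrict_to_state,
    simulate_random_heatmap,
    split_state_subsequences,
)
from .synth import (
    GeneratorConfig,
    make_astrocyte_mask,
    make_behavior_trace,
    make_hotspot_field,
    sample_events,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the demo pipeline; round-trips losslessly through JSON."""

    out_dir: str = "astromap_run"
    seed: int = 0
    duration_s: float = 600.0
    grid_shape: tuple[int, int] = (128, 128)
    events_csv: str | None = None  # analyze an existing table instead of synthesizing
    behavior_csv: str | None = None
    gap_tolerance_s: float = 1.5
    stim_window_s: float = 1.5
    min_area_um2: float = 2.0
    pre_stable_s: float = 3.0
    post_stable_s: float = 6.0
    window_s: tuple[float, float] = (-3.0, 6.0)
    bin_width_s: float = 1.0
    max_shift_px: int | None = None
    n_subsequences: int = 3

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        for key in ("grid_shape", "window_s"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write its artifact bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    gen = GeneratorConfig(grid_shape=config.grid_shape, seed=config.seed)

    if config.events_csv is None:
        rng = np.random.default_rng(seeds[0])
        mask = _stage("mask")(make_astrocyte_mask)(gen, rng)
        field_ = _stage("hotspots")(make_hotspot_field)(mask, gen, rng)
        trace = _stage("behavior")(make_behavior_trace)(config.duration_s, config=gen, rng=rng)
        labels = segment_run_rest(trace, config.gap_tolerance_s)
        labels = annotate_touch_states(labels, trace, config.stim_window_s)
        table = _stage("events")(sample_events)(field_, labels, gen, rng)
        tifffile.imwrite(out / "mask.tif", mask.grid.astype(np.uint8))
        amio.write_behavior_csv(trace, out / "behavior.csv")
        amio.write_event_table(table, out / "events.csv")
    else:
        table = _stage("load")(amio.read_event_table)(config.events_csv)
        trace = _stage("load")(amio.read_behavior_csv)(config.behavior_csv)
        labels = segment_run_rest(trace, config.gap_tolerance_s)
        labels = annotate_touch_states(labels, trace, config.stim_window_s)
        mask = None

    amio.write_states_csv(labels, out / "states.csv")
    table = _stage("filter")(load_and_filter_events)(table, config.min_area_um2)
    table = _stage("assign")(assign_states)(table, labels)

    summaries = summaries_to_frame(state_summary(table, labels))
    summaries.to_csv(out / "state_summary.csv", index=False)

    transitions = extract_transitions(labels, config.pre_stable_s, config.post_stable_s)
    profiles = {}
    for kind in ("rest_to_run", "run_to_rest"):
        sub = [t for t in transitions if t.kind == kind]
        if sub:
            prof = _stage("transitions")(transition_profile)(
                table, sub, config.window_s, config.bin_width_s, kind=kind
            )
            prof.table.to_csv(out / f"profile_{kind}.csv", index=False)
            profiles[kind] = prof

    heatmaps = {}
    for state in ("all", "rest", "run"):
        frames = restrict_to_state(labels, state)
        if frames.any():
            h = _stage("heatmap")(build_heatmap)(table, frames, "max_one", state)
            tifffile.imwrite(out / f"heatmap_{state}.tif", h.grid.astype(np.float32))
            heatmaps[state] = h

    comparisons = {}
    if mask is not None and len(table):
        null_cfg = NullConfig(
            mask, table.df.area_um2.to_numpy(), seed=int(seeds[1].generate_state(1)[0] % 2**31)
        )
        null = _stage("null")(simulate_random_heatmap)(
            null_cfg, table.frame_rate, heatmaps["all"].frames_used, "max_one"
        )
        tifffile.imwrite(out / "heatmap_null.tif", null.grid.astype(np.float32))
        comparisons["real_vs_null"] = max_xcorr_pcc(
            heatmaps["all"], null, config.max_shift_px
        ).max_pcc
    if "rest" in heatmaps and "run" in heatmaps:
        comparisons["rest_vs_run"] = max_xcorr_pcc(
            heatmaps["rest"], heatmaps["run"], config.max_shift_px
        ).max_pcc
    try:
        blocks = split_state_subsequences(labels, "rest", config.n_subsequences)
        pccs = []
        maps = [build_heatmap(table, b, "max_one", "rest") for b in blocks]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                pccs.append(max_xcorr_pcc(maps[i], maps[j], config.max_shift_px).max_pcc)
        comparisons["rest_subsequence_self"] = float(np.mean(pccs))
    except ValueError:
        pass
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=1))

    import astromap

    log = {
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "versions": {"astromap": astromap.__version__, "numpy": np.__version__, "pandas": pd.__version__},
        "n_events": int(len(table)),
        "n_transitions": len(transitions),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return {
        "table": table,
        "labels": labels,
        "summaries": summaries,
        "profiles": profiles,
        "heatmaps": heatmaps,
        "comparisons": comparisons,
        "out_dir": out,
    }
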