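"""Event-characteristic statistics for Ca2+ microdomain signals.

Events arrive as a flat table in the format an event-based detector exports:
per-event 2D binary footprint, onset frame ``t0``, offset frame ``t1``, peak
dF/F amplitude, and footprint area in um^2.  Size is the maximal spatial
extent of the signal, duration is ``(t1 - t0) / frame_rate``, and frequency
is events per unit time in a behavioral state.

This module groups events by behavioral state, aligns them to stable state
transitions in 1-s bins, fits the marginal distributions (skew-normal for
amplitude/duration, heavy-tail families for size), and applies the study's
statistical protocol: normality screening (Shapiro-Wilk below 50 samples,
Kolmogorov-Smirnov otherwise), then parametric (t-test / ANOVA + Tukey) or
nonparametric (Mann-Whitney / Kruskal-Wallis + Bonferroni) testing, all
two-tailed at alpha = 0.05, with means reported as mean +/- 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .behavior import EXPLORE, REST, RUN, STIM, StateLabels, Transition

__all__ = [
    "EventTable",
    "StateSummary",
    "TransitionProfile",
    "TailFitResult",
    "UltrafastStats",
    "load_and_filter_events",
    "assign_states",
    "state_summary",
    "percent_change",
    "transition_profile",
    "ultrafast_stats",
    "size_duration_correlation",
    "fit_skew_normal",
    "compare_size_tails",
    "normalize_to_rest",
    "compare_groups",
]

REQUIRED_COLUMNS = ("id", "t0_frame", "t1_frame", "dff_max", "area_um2")
CHARACTERISTICS = ("dff_max", "duration_s", "area_um2")


@dataclass
class EventTable:
    """Event table plus recording metadata (pixel size, frame rate, grid)."""

    df: pd.DataFrame
    meta: dict

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table is missing required column(s): {missing}")
        for key in ("pixel_size_um", "frame_rate_hz"):
            if key not in self.meta:
                raise ValueError(f"event metadata is missing field {key!r}")
        if "duration_s" not in self.df.columns:
            self.df = self.df.assign(
                duration_s=(self.df.t1_frame - self.df.t0_frame) / self.meta["frame_rate_hz"]
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def frame_rate(self) -> float:
        return self.meta["frame_rate_hz"]

    @property
    def pixel_size(self) -> float:
        return self.meta["pixel_size_um"]

    def copy(self) -> "EventTable":
        return EventTable(self.df.copy(), dict(self.meta))


def load_and_filter_events(table: EventTable, min_area: float = 2.0) -> EventTable:
    """Validate an event table and drop events below the size floor.

    Events smaller than ``min_area`` um^2 (twice the point spread function,
    by default) are removed; events of exactly the floor area are kept.
    Rows with ``t1 < t0`` violate the event contract and are rejected.
    """
    df = table.df
    bad = df.index[df.t1_frame < df.t0_frame]
    if len(bad):
        raise ValueError(f"t1_frame < t0_frame at row(s) {list(bad[:5])}")
    kept = df[df.area_um2 >= min_area].reset_index(drop=True)
    out = EventTable(kept, dict(table.meta))
    out.meta["min_area_um2"] = min_area
    return out


def assign_states(table: EventTable, labels: StateLabels) -> EventTable:
    """Tag each event with the behavioral state of its onset frame.

    The onset frame ``t0`` alone decides the state; substates take precedence
    over their base state, so every event maps to exactly one of the four
    states.
    """
    t0 = table.df.t0_frame.to_numpy()
    if len(t0) and (t0.min() < 0 or t0.max() >= labels.n_frames):
        raise ValueError("event onset frame outside the labeled recording")
    eff = labels.effective_state()
    out = table.copy()
    if len(t0):
        out.df["state"] = eff[t0]
        out.df["base_state"] = labels.base_state[t0]
    else:
        out.df["state"] = pd.Series(dtype=object)
        out.df["base_state"] = pd.Series(dtype=object)
    return out


@dataclass
class StateSummary:
    """Per-state event counts, frequency, and characteristic means with 95% CI."""

    state: str
    n_events: int
    seconds_in_state: float
    frequency: float  # events/s; nan when the state has zero duration
    means: dict  # characteristic -> (mean, ci95 half-width)


def _mean_ci95(x: np.ndarray) -> tuple[float, float]:
    """Sample mean and t-based 95% CI half-width; nan half-width for n < 2."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return np.nan, np.nan
    if x.size == 1:
        return float(x[0]), np.nan
    half = stats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    return float(x.mean()), float(half)


def state_summary(table: EventTable, labels: StateLabels) -> list[StateSummary]:
    """Summarize events per behavioral state at both granularities.

    Rest and run rows use the base state of each event's onset frame (an
    event inside a stimulation window still counts as run activity), so the
    two base rows partition all events.  The substate rows additionally
    summarize the touch-triggered subsets; their frequency denominator is
    total substate time.  A state never visited gets nan frequency; a
    visited state without events gets frequency 0 and missing means.
    """
    if "state" not in table.df.columns:
        table = assign_states(table, labels)
    out = []
    for state in (REST, RUN, STIM, EXPLORE):
        seconds = labels.seconds_in_state(state)
        column = "base_state" if state in (REST, RUN) else "state"
        sub = table.df[table.df[column] == state]
        freq = len(sub) / seconds if seconds > 0 else np.nan
        means = {c: _mean_ci95(sub[c].to_numpy()) for c in CHARACTERISTICS}
        out.append(StateSummary(state, len(sub), seconds, freq, means))
    return out


def summaries_to_frame(summaries: list[StateSummary], recording_id: str | None = None) -> pd.DataFrame:
    """Flatten StateSummary objects into a tidy DataFrame."""
    rows = []
    for s in summaries:
        row = {
            "state": s.state,
            "n_events": s.n_events,
            "seconds_in_state": s.seconds_in_state,
            "frequency": s.frequency,
        }
        for c, (m, ci) in s.means.items():
            row[f"mean_{c}"] = m
            row[f"ci95_{c}"] = ci
        if recording_id is not None:
            row["recording_id"] = recording_id
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(reference: float, comparison: float) -> float:
    """Percent change of ``comparison`` relative to ``reference``.

    Note the documented asymmetry: ``percent_change(a, b)`` and
    ``percent_change(b, a)`` are reciprocal on the multiplicative scale, not
    additive inverses.
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (comparison - reference) / reference


@dataclass
class TransitionProfile:
    """Binned peri-transition event statistics with tests against the -1 s bin."""

    kind: str
    n_transitions: int
    bin_edges: np.ndarray
    table: pd.DataFrame  # per-bin frequency, characteristic means, p-values
    reference_bin: int


def transition_profile(
    table: EventTable,
    transitions: list[Transition],
    window: tuple[float, float] = (-3.0, 6.0),
    bin_width: float = 1.0,
    kind: str | None = None,
) -> TransitionProfile:
    """Pool events across transitions into peri-transition time bins.

    Event onset times are expressed relative to each transition; the bin
    frequency is pooled count / (number of transitions x bin width).  Each
    bin is compared to the reference bin containing -1 s with a
    Kruskal-Wallis test — on per-transition counts for frequency and on
    pooled event values for amplitude/duration/size — Bonferroni-corrected
    over the non-reference bins.
    """
    if kind is not None:
        transitions = [t for t in transitions if t.kind == kind]
    else:
        kinds = {t.kind for t in transitions}
        if len(kinds) > 1:
            raise ValueError(f"mixed transition kinds {sorted(kinds)}; pass kind=")
        kind = kinds.pop() if kinds else "none"
    if not transitions:
        raise ValueError("no transitions to align to")
    edges = np.arange(window[0], window[1] + 1e-9, bin_width)
    if edges.size < 2:
        raise ValueError("window does not cover a single bin")
    n_bins = edges.size - 1
    ref_bin = int(np.searchsorted(edges, -1.0, side="right") - 1)
    ref_bin = min(max(ref_bin, 0), n_bins - 1)

    fr = table.frame_rate
    t0 = table.df.t0_frame.to_numpy() / fr
    n_tr = len(transitions)
    # per-transition per-bin counts and pooled per-bin event rows
    counts = np.zeros((n_tr, n_bins), dtype=int)
    pooled: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    values = table.df[list(CHARACTERISTICS)].to_numpy()
    for j, tr in enumerate(transitions):
        rel = t0 - tr.time_s
        inside = (rel >= window[0]) & (rel < window[1])
        b = np.floor((rel[inside] - window[0]) / bin_width).astype(int)
        b = np.clip(b, 0, n_bins - 1)
        np.add.at(counts[j], b, 1)
        for bb, vv in zip(b, values[inside]):
            pooled[bb].append(vv)

    rows = []
    m = n_bins - 1  # Bonferroni family: non-reference bins
    any_events = counts.sum() > 0
    for b in range(n_bins):
        vals = np.array(pooled[b]) if pooled[b] else np.empty((0, len(CHARACTERISTICS)))
        row = {
            "bin_left": edges[b],
            "bin_right": edges[b + 1],
            "count": int(counts[:, b].sum()),
            "frequency": counts[:, b].sum() / (n_tr * bin_width),
            "is_reference": b == ref_bin,
        }
        for k, c in enumerate(CHARACTERISTICS):
            row[f"mean_{c}"] = vals[:, k].mean() if len(vals) else np.nan
        if b != ref_bin and any_events:
            row["p_frequency"] = _kw_p(counts[:, b], counts[:, ref_bin])
            ref_vals = np.array(pooled[ref_bin]) if pooled[ref_bin] else np.empty((0, 3))
            for k, c in enumerate(CHARACTERISTICS):
                row[f"p_{c}"] = _kw_p(
                    vals[:, k] if len(vals) else np.empty(0),
                    ref_vals[:, k] if len(ref_vals) else np.empty(0),
                )
        else:
            row["p_frequency"] = np.nan
            for c in CHARACTERISTICS:
                row[f"p_{c}"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in ["p_frequency"] + [f"p_{c}" for c in CHARACTERISTICS]:
        out[col.replace("p_", "p_adj_", 1)] = np.minimum(1.0, out[col] * m)
    return TransitionProfile(kind, n_tr, edges, out, ref_bin)


def _kw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Kruskal-Wallis p-value for two groups; nan when undefined."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        return np.nan
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.kruskal(a, b).pvalue)


@dataclass
class UltrafastStats:
    """Share and characteristics of events at the temporal resolution limit."""

    threshold_s: float
    fraction: float
    n_ultrafast: int
    mean_amplitude: float
    amplitude_ci95: float
    amplitude_sd: float
    mean_area_um2: float
    area_ci95: float
    area_sd: float
    fraction_ci95: float = np.nan  # across recordings, when recording_id present
    fraction_sd: float = np.nan


def ultrafast_stats(table: EventTable, threshold: float = 0.3) -> UltrafastStats:
    """Fraction of ultrafast events (duration <= threshold, default 300 ms).

    Reports the pooled fraction and the mean amplitude/size of ultrafast
    events with 95% CI and SD.  When the table carries a ``recording_id``
    column, the fraction's CI and SD are computed across recordings.
    """
    df = table.df
    ultra = df[df.duration_s <= threshold]
    frac = len(ultra) / len(df) if len(df) else np.nan
    amp_mean, amp_ci = _mean_ci95(ultra.dff_max.to_numpy())
    area_mean, area_ci = _mean_ci95(ultra.area_um2.to_numpy())
    frac_ci = frac_sd = np.nan
    if "recording_id" in df.columns and df.recording_id.nunique() > 1:
        per_rec = df.groupby("recording_id").apply(
            lambda g: (g.duration_s <= threshold).mean(), include_groups=False
        )
        _, frac_ci = _mean_ci95(per_rec.to_numpy())
        frac_sd = float(per_rec.std(ddof=1))
    return UltrafastStats(
        threshold,
        frac,
        len(ultra),
        amp_mean,
        amp_ci,
        float(ultra.dff_max.std(ddof=1)) if len(ultra) > 1 else np.nan,
        area_mean,
        area_ci,
        float(ultra.area_um2.std(ddof=1)) if len(ultra) > 1 else np.nan,
        frac_ci,
        frac_sd,
    )


def size_duration_correlation(table: EventTable) -> tuple[float, float]:
    """Pearson r between natural-log event size and duration, with p-value.

    Returns ``(nan, nan)`` when either margin is constant.
    """
    df = table.df
    if len(df) < 3:
        raise ValueError("need at least 3 events")
    if (df.area_um2 <= 0).any():
        raise ValueError("areas must be positive to take logs")
    x = np.log(df.area_um2.to_numpy())
    y = df.duration_s.to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fit_skew_normal(samples: np.ndarray) -> dict:
    """Maximum-likelihood skew-normal fit (shape, location, scale, fitted mean)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 30:
        raise ValueError(f"need at least 30 samples to fit a skew-normal, got {x.size}")
    shape, loc, scale = stats.skewnorm.fit(x)
    fitted_mean = float(stats.skewnorm.mean(shape, loc=loc, scale=scale))
    if not np.isfinite([shape, loc, scale, fitted_mean]).all():
        raise RuntimeError(
            f"skew-normal fit did not converge: shape={shape}, loc={loc}, scale={scale}"
        )
    return {"shape": shape, "location": loc, "scale": scale, "mean": fitted_mean}


# --------------------------------------------------------------------------
# heavy-tail model comparison for event sizes


@dataclass
class TailFitResult:
    """Competing fits to the event-size tail above ``xmin``.

    ``comparisons`` holds pairwise normalized log-likelihood ratios (positive
    favors the first-named family) with two-sided p-values from the Vuong
    test; ``best`` names the family preferred by total log-likelihood among
    those not significantly beaten.
    """

    xmin: float
    n_tail: int
    params: dict
    logliks: dict
    comparisons: pd.DataFrame
    best: str
    ccdf: pd.DataFrame


def _powerlaw_ll(x: np.ndarray, xmin: float) -> tuple[dict, np.ndarray]:
    alpha = 1.0 + x.size / np.sum(np.log(x / xmin))
    ll = np.log(alpha - 1.0) - np.log(xmin) - alpha * np.log(x / xmin)
    return {"alpha": float(alpha)}, ll


def _exponential_ll(x: np.ndarray, xmin: float) -> tuple[dict, np.ndarray]:
    lam = 1.0 / (x.mean() - xmin)
    ll = np.log(lam) - lam * (x - xmin)
    return {"lam": float(lam)}, ll


def _lognormal_ll(x: np.ndarray, xmin: float) -> tuple[dict, np.ndarray]:
    logx = np.log(x)

    def nll(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        dens = stats.norm.logpdf(logx, mu, sigma) - logx
        tail = stats.norm.logsf(np.log(xmin), mu, sigma)
        return -(dens.sum() - x.size * tail)

    res = optimize.minimize(nll, x0=[logx.mean(), np.log(max(logx.std(), 1e-3))], method="Nelder-Mead")
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    ll = stats.norm.logpdf(logx, mu, sigma) - logx - stats.norm.logsf(np.log(xmin), mu, sigma)
    return {"mu": float(mu), "sigma": sigma}, ll


_TAIL_FAMILIES = {
    "power_law": _powerlaw_ll,
    "lognormal": _lognormal_ll,
    "exponential": _exponential_ll,
}


def _tail_ccdf(family: str, params: dict, x: np.ndarray, xmin: float) -> np.ndarray:
    if family == "power_law":
        return (x / xmin) ** (1.0 - params["alpha"])
    if family == "exponential":
        return np.exp(-params["lam"] * (x - xmin))
    if family == "lognormal":
        return stats.norm.sf(np.log(x), params["mu"], params["sigma"]) / stats.norm.sf(
            np.log(xmin), params["mu"], params["sigma"]
        )
    raise ValueError(family)


def compare_size_tails(
    areas: np.ndarray, xmin: float = 5.0, min_tail: int = 100
) -> TailFitResult:
    """Fit and compare power-law, lognormal, and exponential size tails.

    Only sizes >= ``xmin`` (um^2) enter the fits.  Each family is fit by
    maximum likelihood on the conditional (truncated) density; pairs are
    compared with the normalized log-likelihood ratio test (Vuong), whose
    sign prefers the first family and whose two-sided p-value states whether
    the preference is significant.
    """
    x = np.asarray(areas, dtype=float)
    x = x[x >= xmin]
    if x.size < min_tail:
        raise ValueError(f"need at least {min_tail} tail samples >= xmin={xmin}, got {x.size}")

    params: dict = {}
    per_sample: dict = {}
    for name, fit in _TAIL_FAMILIES.items():
        params[name], per_sample[name] = fit(x, xmin)
    logliks = {name: float(ll.sum()) for name, ll in per_sample.items()}

    rows = []
    beaten = set()
    names = list(_TAIL_FAMILIES)
    for i, f1 in enumerate(names):
        for f2 in names[i + 1 :]:
            d = per_sample[f1] - per_sample[f2]
            r_total = float(d.sum())
            sd = d.std(ddof=0)
            if sd == 0:
                norm_llr, p = 0.0, 1.0
            else:
                norm_llr = r_total / (sd * np.sqrt(d.size))
                p = float(2.0 * stats.norm.sf(abs(norm_llr)))
            preferred = f1 if r_total > 0 else f2
            if p < 0.05:
                beaten.add(f2 if r_total > 0 else f1)
            rows.append(
                {
                    "family_1": f1,
                    "family_2": f2,
                    "llr": r_total,
                    "normalized_llr": norm_llr,
                    "p_value": p,
                    "preferred": preferred,
                }
            )
    candidates = [n for n in names if n not in beaten] or names
    best = max(candidates, key=lambda n: logliks[n])

    xs = np.sort(x)
    emp = 1.0 - np.arange(xs.size) / xs.size
    ccdf = pd.DataFrame({"x": xs, "empirical": emp})
    for name in names:
        ccdf[name] = _tail_ccdf(name, params[name], xs, xmin)
    return TailFitResult(xmin, x.size, params, logliks, pd.DataFrame(rows), best, ccdf)


def normalize_to_rest(summaries: pd.DataFrame) -> pd.DataFrame:
    """Normalize per-recording state summaries by the same recording's rest row.

    Expects a tidy frame with ``recording_id``, ``state`` and characteristic
    columns (``frequency`` and any ``mean_*``).  Each value is divided by the
    rest-state value of the same recording, so rest rows become exactly 1;
    recordings without a usable rest row are excluded with a warning.  This
    removes between-recording baseline variability before comparing states.
    """
    value_cols = [c for c in summaries.columns if c == "frequency" or c.startswith("mean_")]
    out = []
    for rec, group in summaries.groupby("recording_id"):
        rest = group[group.state == REST]
        if len(rest) != 1 or rest[value_cols].isna().any(axis=None) or (rest[value_cols] == 0).any(
            axis=None
        ):
            warnings.warn(f"recording {rec!r} has no usable rest summary; excluded", stacklevel=2)
            continue
        g = group.copy()
        g[value_cols] = group[value_cols].to_numpy() / rest[value_cols].to_numpy()
        out.append(g)
    if not out:
        return summaries.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> tuple[bool, str, float]:
    """Normality per the sample-size rule: Shapiro-Wilk under 50, KS otherwise."""
    x = np.asarray(x, dtype=float)
    if np.allclose(x, x[0]):
        return False, "constant", np.nan
    if x.size < 50:
        p = float(stats.shapiro(x).pvalue)
        return p >= alpha, "shapiro", p
    p = float(stats.kstest((x - x.mean()) / x.std(ddof=1), "norm").pvalue)
    return p >= alpha, "ks", p


def compare_groups(
    groups: dict[str, np.ndarray], design: str = "independent"
) -> dict:
    """Compare group means per the study's statistical protocol.

    Normality is assessed per group (Shapiro-Wilk for n < 50, Kolmogorov-
    Smirnov otherwise, alpha 0.05).  If all groups pass: t-test for two
    groups or one-way ANOVA with Tukey post hoc for more.  Otherwise:
    Mann-Whitney / Wilcoxon for two groups or Kruskal-Wallis with
    Bonferroni-corrected pairwise tests for more.  All tests two-tailed.
    """
    if design not in ("independent", "paired"):
        raise ValueError("design must be 'independent' or 'paired'")
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")

    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        return {
            "test": "degenerate (all values identical)",
            "statistic": 0.0,
            "p_value": 1.0,
            "normality": {},
            "all_normal": False,
            "posthoc": None,
        }

    normality = {}
    for k, v in arrays.items():
        ok, method, p = _is_normal(v)
        normality[k] = {"normal": ok, "method": method, "p_value": p}
    all_normal = all(d["normal"] for d in normality.values())

    posthoc = None
    a, b = arrays[names[0]], arrays[names[1]]
    if len(names) == 2:
        if all_normal:
            test = "paired t-test" if design == "paired" else "unpaired t-test"
            res = stats.ttest_rel(a, b) if design == "paired" else stats.ttest_ind(a, b)
        elif design == "paired":
            test, res = "wilcoxon signed-rank", stats.wilcoxon(a, b)
        else:
            test, res = "mann-whitney U", stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        samples = list(arrays.values())
        if all_normal and design == "independent":
            test = "one-way ANOVA + Tukey"
            res = stats.f_oneway(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            flat = np.concatenate(samples)
            labels = np.concatenate([[k] * arrays[k].size for k in names])
            tk = pairwise_tukeyhsd(flat, labels)
            posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        elif all_normal:
            test = "repeated-measures ANOVA"
            sizes = {v.size for v in samples}
            if len(sizes) != 1:
                raise ValueError("paired design requires equal group sizes")
            data = np.column_stack(samples)
            grand = data.mean()
            ss_between = data.shape[0] * ((data.mean(axis=0) - grand) ** 2).sum()
            ss_subject = data.shape[1] * ((data.mean(axis=1) - grand) ** 2).sum()
            ss_total = ((data - grand) ** 2).sum()
            ss_err = ss_total - ss_between - ss_subject
            df1 = data.shape[1] - 1
            df2 = df1 * (data.shape[0] - 1)
            stat = (ss_between / df1) / (ss_err / df2)
            p = float(stats.f.sf(stat, df1, df2))
        else:
            if design == "paired":
                test = "friedman + bonferroni wilcoxon"
                res = stats.friedmanchisquare(*samples)
                pair = lambda x, y: stats.wilcoxon(x, y).pvalue  # noqa: E731
            else:
                test = "kruskal-wallis + bonferroni mann-whitney"
                res = stats.kruskal(*samples)
                pair = lambda x, y: stats.mannwhitneyu(x, y, alternative="two-sided").pvalue  # noqa: E731
            stat, p = float(res.statistic), float(res.pvalue)
            m = len(names) * (len(names) - 1) // 2
            rows = []
            for i, k1 in enumerate(names):
                for k2 in names[i + 1 :]:
                    praw = float(pair(arrays[k1], arrays[k2]))
                    rows.append(
                        {"group_1": k1, "group_2": k2, "p_raw": praw, "p_bonferroni": min(1.0, praw * m)}
                    )
            posthoc = pd.DataFrame(rows)

    return {
        "test": test,
        "statistic": stat,
        "p_value": p,
        "normality": normality,
        "all_normal": all_normal,
        "posthoc": posthoc,
    }
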