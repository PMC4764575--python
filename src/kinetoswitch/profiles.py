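"""Event-aligned and run-rescaled averaging of mechanical signals.

These operations extract the cohort-level mechanical signatures of
directional switching: a scalar signal (inter-sister distance, percent
stretch, or twist) is stacked across events aligned at the first sister's
switching frame, or linearly rescaled over entire coherent runs to a
common [0, 1] grid, and summarised as mean +/- SEM per lag.  Rank-based
group comparisons, the sister-centre displacement autocorrelation (which
sets the oscillation half-period), the twist-distance correlation and the
two-Gaussian bimodality criterion live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import CoherentRun, DirectionalSwitchEvent

__all__ = [
    "AlignedProfile", "RescaledRunProfile",
    "align_event_windows", "rescale_runs", "displacement_autocorrelation",
    "compare_distributions", "twist_distance_correlation",
    "bimodality_separation",
]


@dataclass
class AlignedProfile:
    """Mean +/- SEM of a signal at lags around an alignment point."""

    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    count: np.ndarray
    n_events: int
    alignment: str = "event"
    condition: str = ""


@dataclass
class RescaledRunProfile:
    """Mean +/- SEM of a signal over runs rescaled to unit length."""

    grid: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_runs: int
    min_frames: int = 6
    max_frames: int = 20
    condition: str = ""


def _stack_stats(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column mean, SEM and count of a stack with NaN gaps."""
    count = np.sum(np.isfinite(stack), axis=0)
    mean = np.where(count > 0, np.nanmean(stack, axis=0), np.nan)
    with np.errstate(invalid="ignore"):
        sd = np.where(count > 1, np.nanstd(stack, axis=0, ddof=1), 0.0)
    sem = np.where(count > 0, sd / np.sqrt(np.maximum(count, 1)), np.nan)
    return mean, sem, count


def align_event_windows(signals: dict[str, np.ndarray],
                        events: list[DirectionalSwitchEvent],
                        window_s: float = 40.0, dt: float = 2.0,
                        event_type: str | None = None,
                        prior_type: str | None = None,
                        align_on: str = "first") -> AlignedProfile:
    """Stack signal windows centred on the switching frame of each event.

    ``signals`` maps pair_id to that pair's per-frame signal.  Windows span
    +/- ``window_s`` seconds around the aligned frame (the first switching
    sister by default, the second with ``align_on="second"``); windows
    truncated by the trajectory ends contribute only to the lags they
    cover.  ``event_type``/``prior_type`` condition the event set.
    """
    half = int(round(window_s / dt))
    lags = np.arange(-half, half + 1)
    rows = []
    for ev in events:
        if event_type is not None and ev.event_type != event_type:
            continue
        if prior_type is not None and ev.prior_type != prior_type:
            continue
        sig = signals[ev.pair_id]
        t0 = (ev.first_switch_frame if align_on == "first"
              else max(ev.switch_frame_sister1, ev.switch_frame_sister2))
        row = np.full(len(lags), np.nan)
        idx = t0 + lags
        ok = (idx >= 0) & (idx < len(sig))
        row[ok] = sig[idx[ok]]
        rows.append(row)
    if not rows:
        raise ValueError("no events match the requested condition")
    stack = np.vstack(rows)
    mean, sem, count = _stack_stats(stack)
    keep = count > 0
    cond = "/".join(filter(None, [event_type or "", prior_type and f"prior {prior_type}" or ""]))
    return AlignedProfile(lags_s=lags[keep] * dt, mean=mean[keep],
                          sem=sem[keep], count=count[keep],
                          n_events=len(rows), alignment="event",
                          condition=cond)


def rescale_runs(signals: dict[str, np.ndarray],
                 runs_by_pair: dict[str, list[CoherentRun]],
                 events_by_pair: dict[str, list[DirectionalSwitchEvent]],
                 preceding_type: str | None = None,
                 following_type: str | None = None,
                 min_frames: int = 6, max_frames: int = 20,
                 grid_size: int = 101) -> RescaledRunProfile:
    """Average a signal over coherent runs rescaled to unit length.

    Only runs of ``min_frames``-``max_frames`` frames (inclusive) bounded
    by directional events on both sides are admitted; conditioning on the
    preceding and/or following event type selects run classes.  Each run's
    signal is linearly interpolated onto a common [0, 1] grid.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    for pair_id, runs in runs_by_pair.items():
        events = events_by_pair.get(pair_id, [])
        sig = signals[pair_id]
        for run in runs:
            prev_ev = next((e for e in events if e.run_after is run), None)
            next_ev = next((e for e in events if e.run_before is run), None)
            if prev_ev is None or next_ev is None:
                continue
            if preceding_type is not None and prev_ev.event_type != preceding_type:
                continue
            if following_type is not None and next_ev.event_type != following_type:
                continue
            if not (min_frames <= run.length <= max_frames):
                continue
            frames = np.arange(run.start_frame, run.end_frame + 1)
            frames = frames[frames < len(sig)]
            if len(frames) < 2:
                continue
            frac = (frames - frames[0]) / (frames[-1] - frames[0])
            rows.append(np.interp(grid, frac, sig[frames]))
    if not rows:
        raise ValueError("no runs match the requested condition")
    stack = np.vstack(rows)
    mean, sem, _ = _stack_stats(stack)
    cond = "/".join(filter(None, [preceding_type and f"after {preceding_type}" or "",
                                  following_type and f"before {following_type}" or ""]))
    return RescaledRunProfile(grid=grid, mean=mean, sem=sem,
                              n_runs=len(rows), min_frames=min_frames,
                              max_frames=max_frames, condition=cond)


def displacement_autocorrelation(centres: list[np.ndarray],
                                 displacement_lag: int = 4, dt: float = 2.0,
                                 max_lag_s: float = 100.0,
                                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Autocorrelation of sister-centre displacements, pooled over
    trajectories, and the implied oscillation half-period.

    Displacements are overlapping ``displacement_lag``-frame differences of
    the pair-centre position along the plate normal.  The half-period is
    the lag (s) of the global minimum of the pooled autocorrelation.
    """
    max_lag = int(round(max_lag_s / dt))
    num = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1)
    var_acc = 0.0
    n_acc = 0
    series = []
    for c in centres:
        c = np.asarray(c, dtype=float)
        if len(c) <= displacement_lag:
            continue
        d = c[displacement_lag:] - c[:-displacement_lag]
        d = d - d.mean()
        series.append(d)
        var_acc += float(d @ d)
        n_acc += len(d)
    if n_acc == 0 or var_acc == 0.0:
        raise ValueError("degenerate input: no displacement variance "
                         "(constant positions?)")
    var = var_acc / n_acc
    for d in series:
        for lag in range(0, min(max_lag, len(d) - 1) + 1):
            prod = d[:len(d) - lag] @ d[lag:]
            num[lag] += prod
            cnt[lag] += len(d) - lag
    acf = num / np.maximum(cnt, 1) / var
    lags_s = np.arange(max_lag + 1) * dt
    valid = cnt > 0
    acf, lags_s = acf[valid], lags_s[valid]
    half_period = float(lags_s[1:][np.argmin(acf[1:])]) if len(acf) > 1 else math.nan
    return lags_s, acf, half_period


def compare_distributions(samples_by_group: dict[str, np.ndarray],
                          test: str = "rank-sum") -> tuple[float, float]:
    """Two-sided rank-based comparison of group distributions.

    ``rank-sum`` (two groups) tests for identical medians (Mann-Whitney);
    ``rank-homogeneity`` (>= 2 groups) tests homogeneity (Kruskal-Wallis).
    """
    groups = [np.asarray(v, dtype=float) for v in samples_by_group.values()]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if test == "rank-sum":
        if len(groups) != 2:
            raise ValueError("rank-sum test requires exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif test == "rank-homogeneity":
        res = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def twist_distance_correlation(twist: np.ndarray | list[np.ndarray],
                               distance: np.ndarray | list[np.ndarray],
                               ) -> tuple[float, float]:
    """Pearson correlation between twist and inter-sister distance over all
    pooled frames."""
    if isinstance(twist, (list, tuple)):
        twist = np.concatenate([np.ravel(t) for t in twist])
        distance = np.concatenate([np.ravel(d) for d in distance])
    twist = np.ravel(twist)
    distance = np.ravel(distance)
    ok = np.isfinite(twist) & np.isfinite(distance)
    r, p = stats.pearsonr(twist[ok], distance[ok])
    return float(r), float(p)


def bimodality_separation(values_a: np.ndarray, values_b: np.ndarray,
                          ) -> tuple[float, bool]:
    """Median separation of two groups in units of their pooled
    within-group SD, with the two-Gaussian bimodality verdict.

    A mixture of two Gaussians is bimodal only when the component means are
    separated by at least 2 SDs; the verdict reports that criterion.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    va = a.var(ddof=1) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) if len(b) > 1 else 0.0
    pooled_sd = math.sqrt(0.5 * (va + vb))
    sep = abs(float(np.median(a)) - float(np.median(b)))
    ratio = sep / pooled_sd if pooled_sd > 0 else (0.0 if sep == 0 else math.inf)
    return ratio, ratio >= 2.0
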