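"""Coherent runs, directional switching events and LIDS/TIDS/JDS classification.

A *coherent run* is a maximal interval (>= 5 frames by default) over which
the inferred pair state is one of the two coherent states and unchanged.
Two consecutive runs of opposite direction delimit a *directional switching
event*: both sisters flip in the gap between the runs.  The event is
classified by which sister flips first — the lead (depolymerising) sister
of the preceding run (LIDS), the trailing sister (TIDS), or both within the
same frame (JDS).  Consecutive runs of the *same* direction (one sister
flips and flips back, a "revert") produce no directional event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (COHERENT_STATES, STATE_LABELS, SISTER1_PLUS, SISTER2_PLUS,
                   TruthRecord, is_coherent, lead_sister_of_state,
                   run_direction)

__all__ = [
    "CoherentRun", "DirectionalSwitchEvent", "EventStats", "ScoreResult",
    "point_state_estimate", "detect_coherent_runs", "match_directional_events",
    "count_reverts", "classify_event", "event_statistics", "score_against_truth",
    "events_from_path", "MIN_RUN_FRAMES",
]

MIN_RUN_FRAMES = 5


@dataclass
class CoherentRun:
    """Maximal constant coherent-state interval of a state path.

    Frames index the hidden-state path (displacement steps), inclusive at
    both ends.
    """

    start_frame: int
    end_frame: int
    state: int

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def direction(self) -> int:
        return run_direction(self.state)

    @property
    def lead_sister(self) -> int:
        return lead_sister_of_state(self.state)


@dataclass
class DirectionalSwitchEvent:
    """A matched pair of sister switches taking the pair between two
    oppositely-directed coherent runs."""

    run_before: CoherentRun
    run_after: CoherentRun
    switch_frame_sister1: int
    switch_frame_sister2: int
    lead_sister: int            # depolymerising sister of run_before (1 or 2)
    event_type: str             # "LIDS" | "TIDS" | "JDS"
    first_switcher: str         # "lead" | "trail" | "joint"
    dt: float = 2.0
    pair_id: str = ""
    prior_type: str | None = None   # type of the previous event on this pair

    @property
    def lead_switch_frame(self) -> int:
        return (self.switch_frame_sister1 if self.lead_sister == 1
                else self.switch_frame_sister2)

    @property
    def trail_switch_frame(self) -> int:
        return (self.switch_frame_sister2 if self.lead_sister == 1
                else self.switch_frame_sister1)

    @property
    def first_switch_frame(self) -> int:
        return min(self.switch_frame_sister1, self.switch_frame_sister2)

    @property
    def completion_time_s(self) -> float:
        return abs(self.switch_frame_sister1 - self.switch_frame_sister2) * self.dt


@dataclass
class EventStats:
    """Cohort-level directional-switch statistics."""

    n_events: int
    fraction_lids: float
    fraction_tids: float
    fraction_jds: float
    lead_bias: float                    # fraction(LIDS)/fraction(TIDS)
    lead_bias_undefined: bool
    run_mean_s: float
    run_sd_s: float
    run_median_s: float
    run_cv: float
    completion_median_s: dict = field(default_factory=dict)


def point_state_estimate(state_marginals: np.ndarray) -> np.ndarray:
    """Per-frame modal pair state from posterior state marginals.

    Ties (within floating-point tolerance) are broken towards the previous
    frame's state so that the estimate is persistent; at the first frame a
    tie falls to the lowest state code.
    """
    m = np.asarray(state_marginals, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("state_marginals must have shape (n_frames, 4)")
    path = np.empty(m.shape[0], dtype=np.int8)
    prev = -1
    for t in range(m.shape[0]):
        row = m[t]
        top = row.max()
        cand = np.flatnonzero(row >= top - 1e-12 * max(1.0, abs(top)))
        if prev in cand:
            path[t] = prev
        else:
            path[t] = cand[0]
        prev = path[t]
    return path


def detect_coherent_runs(path: np.ndarray,
                         min_frames: int = MIN_RUN_FRAMES) -> list[CoherentRun]:
    """Maximal constant coherent-state intervals of length >= ``min_frames``."""
    path = np.asarray(path)
    runs: list[CoherentRun] = []
    n = len(path)
    t = 0
    while t < n:
        s = int(path[t])
        if s in COHERENT_STATES:
            e = t
            while e + 1 < n and path[e + 1] == s:
                e += 1
            if e - t + 1 >= min_frames:
                runs.append(CoherentRun(t, e, s))
            t = e + 1
        else:
            t += 1
    return runs


def _sister_states(path: np.ndarray, sister: int) -> np.ndarray:
    return (SISTER1_PLUS if sister == 1 else SISTER2_PLUS)[np.asarray(path)]


def _switch_frame(path: np.ndarray, sister: int, gap_start: int,
                  gap_end: int) -> int:
    """First frame in ``(gap_start, gap_end]`` from which the sister holds its
    final (run_after) state through to ``gap_end``.

    If a sister flips more than once inside the gap, this selects the flip
    that persists into the following run.
    """
    s = _sister_states(path, sister)
    final = s[gap_end]
    t = gap_end
    while t - 1 > gap_start and s[t - 1] == final:
        t -= 1
    return t


def classify_event(event: DirectionalSwitchEvent) -> str:
    """LIDS if the lead sister switched at least one frame before the
    trailing sister, TIDS symmetrically, JDS if both switch in the same frame."""
    lead_f, trail_f = event.lead_switch_frame, event.trail_switch_frame
    if lead_f < trail_f:
        return "LIDS"
    if trail_f < lead_f:
        return "TIDS"
    return "JDS"


def match_directional_events(runs: list[CoherentRun], path: np.ndarray,
                             dt: float = 2.0,
                             pair_id: str = "") -> list[DirectionalSwitchEvent]:
    """Match sister switch points between consecutive opposite-direction runs.

    Each consecutive run pair with opposite direction yields one
    directional event; same-direction consecutive runs (reverts) yield
    none.  The per-sister switch frame is the flip that persists into the
    following run.
    """
    path = np.asarray(path)
    events: list[DirectionalSwitchEvent] = []
    prior_type: str | None = None
    for rb, ra in zip(runs[:-1], runs[1:]):
        if ra.direction == rb.direction:
            continue
        f1 = _switch_frame(path, 1, rb.end_frame, ra.start_frame)
        f2 = _switch_frame(path, 2, rb.end_frame, ra.start_frame)
        ev = DirectionalSwitchEvent(
            run_before=rb, run_after=ra,
            switch_frame_sister1=f1, switch_frame_sister2=f2,
            lead_sister=rb.lead_sister, event_type="", first_switcher="",
            dt=dt, pair_id=pair_id, prior_type=prior_type)
        ev.event_type = classify_event(ev)
        ev.first_switcher = {"LIDS": "lead", "TIDS": "trail",
                             "JDS": "joint"}[ev.event_type]
        prior_type = ev.event_type
        events.append(ev)
    return events


def count_reverts(runs: list[CoherentRun]) -> int:
    """Consecutive same-direction run pairs (transient flips that reverted)."""
    return sum(1 for rb, ra in zip(runs[:-1], runs[1:])
               if ra.direction == rb.direction)


def events_from_path(path: np.ndarray, dt: float = 2.0, pair_id: str = "",
                     min_frames: int = MIN_RUN_FRAMES,
                     ) -> tuple[list[CoherentRun], list[DirectionalSwitchEvent]]:
    """Convenience: runs and matched directional events of a state path."""
    runs = detect_coherent_runs(path, min_frames)
    return runs, match_directional_events(runs, path, dt=dt, pair_id=pair_id)


def event_statistics(events: list[DirectionalSwitchEvent],
                     runs: list[CoherentRun], dt: float = 2.0) -> EventStats:
    """Fractions of LIDS/TIDS/JDS, lead bias and run-duration statistics."""
    if not events:
        raise ValueError("event_statistics requires at least one event")
    n = len(events)
    n_l = sum(e.event_type == "LIDS" for e in events)
    n_t = sum(e.event_type == "TIDS" for e in events)
    n_j = n - n_l - n_t
    undefined = n_t == 0
    bias = math.inf if undefined else n_l / n_t
    durations = np.array([r.length * dt for r in runs], dtype=float)
    comp = {}
    for typ in ("LIDS", "TIDS", "JDS"):
        vals = [e.completion_time_s for e in events if e.event_type == typ]
        comp[typ] = float(np.median(vals)) if vals else math.nan
    mean = float(durations.mean())
    sd = float(durations.std(ddof=1)) if len(durations) > 1 else 0.0
    return EventStats(
        n_events=n,
        fraction_lids=n_l / n, fraction_tids=n_t / n, fraction_jds=n_j / n,
        lead_bias=bias, lead_bias_undefined=undefined,
        run_mean_s=mean, run_sd_s=sd,
        run_median_s=float(np.median(durations)),
        run_cv=sd / mean if mean else math.nan,
        completion_median_s=comp,
    )


@dataclass
class ScoreResult:
    """Accuracy of detected events against simulation truth."""

    accuracy: float
    n_true: int
    n_matched: int
    n_correct: int
    n_unmatched_true: int
    n_unmatched_detected: int


def score_against_truth(events: list[DirectionalSwitchEvent],
                        truth: TruthRecord,
                        min_frames: int = MIN_RUN_FRAMES) -> ScoreResult:
    """Score detected directional events against the generative truth.

    True events are derived from the true state path with the same run and
    matching machinery.  A detected event matches the nearest unclaimed true
    event whose first-switch frame lies within half the median true run
    length.  Accuracy = correctly typed matches / (true events + unmatched
    detections): a true switch that is missed, typed wrongly, or shadowed
    by a spurious detection all count against the detector.
    """
    true_runs, true_events = events_from_path(truth.state_path,
                                              min_frames=min_frames)
    if not true_events:
        # nothing to match: every detection is spurious
        n_det = len(events)
        return ScoreResult(accuracy=0.0 if n_det else math.nan,
                           n_true=0, n_matched=0, n_correct=0,
                           n_unmatched_true=0, n_unmatched_detected=n_det)
    window = 0.5 * float(np.median([r.length for r in true_runs]))
    true_frames = np.array([e.first_switch_frame for e in true_events])
    claimed = np.zeros(len(true_events), dtype=bool)
    n_correct = 0
    n_matched = 0
    n_unmatched_det = 0
    for ev in events:
        d = np.abs(true_frames - ev.first_switch_frame).astype(float)
        d[claimed] = np.inf
        j = int(np.argmin(d))
        if d[j] <= window:
            claimed[j] = True
            n_matched += 1
            if ev.event_type == true_events[j].event_type:
                n_correct += 1
        else:
            n_unmatched_det += 1
    denom = len(true_events) + n_unmatched_det
    return ScoreResult(
        accuracy=n_correct / denom if denom else math.nan,
        n_true=len(true_events), n_matched=n_matched, n_correct=n_correct,
        n_unmatched_true=len(true_events) - n_matched,
        n_unmatched_detected=n_unmatched_det,
    )
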