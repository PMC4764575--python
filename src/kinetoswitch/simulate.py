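"""Generative simulator of the two-sister switching autoregressive model.

Stands in for live-cell metaphase trajectory data: saw-tooth quasi-periodic
oscillations of two elastically coupled sister kinetochores relative to the
metaphase plate, with per-frame hidden polymerisation states and full truth
bookkeeping (state path, switch list, true directional events).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (COHERENT_STATES, SISTER1_PLUS, SISTER2_PLUS, ModelParams,
                   PairedTrajectory, TruthRecord, state_from_signs)
from .events import events_from_path

__all__ = [
    "step_displacements", "advance_state", "simulate_trajectory",
    "simulate_cohort", "make_idealized_sawtooth", "CohortTruthSummary",
]

log = logging.getLogger(__name__)

#: Default initial half-separation (nm): sisters start at +/- 450 nm,
#: roughly the observed metaphase separation scale.
DEFAULT_INIT_OFFSET = 450.0


def step_displacements(x1: float, x2: float, state: int, params: ModelParams,
                       noise: tuple[float, float] = (0.0, 0.0),
                       ) -> tuple[float, float]:
    """One-step displacements of the two sisters given the pair state.

    dx1 = c0 + c(s1) - a*x1 + b*x2 + noise1
    dx2 = -c0 - c(s2) - a*x2 + b*x1 + noise2
    """
    if not (np.isfinite(x1) and np.isfinite(x2)):
        raise ValueError(f"non-finite positions x1={x1}, x2={x2}")
    c1 = params.drive(bool(SISTER1_PLUS[state]))
    c2 = params.drive(bool(SISTER2_PLUS[state]))
    dx1 = params.c0 + c1 - params.a * x1 + params.b * x2 + noise[0]
    dx2 = -params.c0 - c2 - params.a * x2 + params.b * x1 + noise[1]
    return dx1, dx2


def advance_state(state: int, params: ModelParams, rng: np.random.Generator,
                  forced_variant: bool = False,
                  last_switcher: int | None = None) -> tuple[int, int | None]:
    """Advance the pair state by one frame.

    With probability ``p_coherent`` (coherent state) or ``p_incoherent``
    (incoherent) exactly one sister flips, chosen uniformly at random.
    Under ``forced_variant``, when the state is incoherent the sister who
    switched last cannot switch, so every excursion out of coherence
    resolves as a directional switch of the pair.

    Returns the new state and the sister that flipped (``None`` if no flip).
    """
    coherent = state in COHERENT_STATES
    p = params.p_coherent if coherent else params.p_incoherent
    if rng.random() >= p:
        return state, last_switcher
    if forced_variant and not coherent and last_switcher is not None:
        sister = 2 if last_switcher == 1 else 1
    else:
        sister = 1 if rng.random() < 0.5 else 2
    s1 = bool(SISTER1_PLUS[state])
    s2 = bool(SISTER2_PLUS[state])
    if sister == 1:
        s1 = not s1
    else:
        s2 = not s2
    return state_from_signs(s1, s2), sister


def _record_truth(states: np.ndarray, dt: float) -> TruthRecord:
    truth = TruthRecord(state_path=states)
    s1 = SISTER1_PLUS[states]
    s2 = SISTER2_PLUS[states]
    for t in range(1, len(states)):
        if states[t] != states[t - 1]:
            if s1[t] != s1[t - 1]:
                truth.switch_list.append(
                    (t, 1, int(states[t - 1]), int(states[t])))
            if s2[t] != s2[t - 1]:
                truth.switch_list.append(
                    (t, 2, int(states[t - 1]), int(states[t])))
    _, truth.event_list = events_from_path(states, dt=dt)
    return truth


def simulate_trajectory(params: ModelParams, n_frames: int = 150,
                        init: tuple[float, float, int] | None = None,
                        forced_variant: bool = False,
                        seed: int | np.random.Generator | None = None,
                        pair_id: str = "pair0", cell_id: str = "cell0",
                        ) -> tuple[PairedTrajectory, TruthRecord]:
    """Simulate one paired trajectory with full truth bookkeeping.

    ``init`` is ``(x1_0, x2_0, state_0)``; by default the sisters start at
    +/- 450 nm and the initial state is drawn uniformly from the two
    coherent states.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if not params.oscillatory:
        log.warning("parameters outside the oscillatory regime "
                    "(need a > b and p_incoherent > p_coherent)")
    if init is None:
        state = int(rng.choice(COHERENT_STATES))
        x1, x2 = DEFAULT_INIT_OFFSET, -DEFAULT_INIT_OFFSET
    else:
        x1, x2, state = float(init[0]), float(init[1]), int(init[2])

    xs1 = np.empty(n_frames)
    xs2 = np.empty(n_frames)
    states = np.empty(n_frames - 1, dtype=np.int8)
    xs1[0], xs2[0] = x1, x2
    sd = np.sqrt(params.s2)
    last_switcher: int | None = None
    for t in range(n_frames - 1):
        if t > 0:
            state, last_switcher = advance_state(
                state, params, rng, forced_variant, last_switcher)
        states[t] = state
        noise = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
        dx1, dx2 = step_displacements(xs1[t], xs2[t], state, params,
                                      noise=(noise[0], noise[1]))
        xs1[t + 1] = xs1[t] + dx1
        xs2[t + 1] = xs2[t] + dx2

    traj = PairedTrajectory(frames=np.arange(n_frames), x1=xs1, x2=xs2,
                            dt=params.dt, pair_id=pair_id, cell_id=cell_id)
    return traj, _record_truth(states, params.dt)


@dataclass
class CohortTruthSummary:
    """Truth-level summary of a simulated cohort."""

    n_events: int
    n_lids: int
    n_tids: int
    n_jds: int

    @property
    def lead_bias(self) -> float:
        return self.n_lids / self.n_tids if self.n_tids else float("inf")


def simulate_cohort(params: ModelParams, n_traj: int, n_frames: int = 150,
                    forced_variant: bool = False,
                    seed: int | None = None,
                    ) -> tuple[list[tuple[PairedTrajectory, TruthRecord]],
                               CohortTruthSummary]:
    """Simulate ``n_traj`` independent trajectories with per-trajectory
    seeds derived from one root seed."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_traj)
    cohort = []
    n_l = n_t = n_j = 0
    for i, child in enumerate(children):
        traj, truth = simulate_trajectory(
            params, n_frames=n_frames, forced_variant=forced_variant,
            seed=np.random.default_rng(child), pair_id=f"pair{i}")
        cohort.append((traj, truth))
        for ev in truth.event_list:
            n_l += ev.event_type == "LIDS"
            n_t += ev.event_type == "TIDS"
            n_j += ev.event_type == "JDS"
    return cohort, CohortTruthSummary(n_events=n_l + n_t + n_j,
                                      n_lids=n_l, n_tids=n_t, n_jds=n_j)


def make_idealized_sawtooth(n_frames: int = 150, half_period: int = 17,
                            amplitude: float = 1000.0,
                            separation: float = 900.0, dt: float = 2.0,
                            ) -> tuple[PairedTrajectory, TruthRecord]:
    """Noise-free triangle-wave pair motion with constant separation.

    Both sisters follow the same triangle wave (offset by ``separation``),
    reversing direction exactly every ``half_period`` frames; reversals are
    simultaneous within one frame, so all true events are joint (JDS).
    """
    if half_period < 5:
        raise ValueError("half_period must be >= 5 frames")
    t = np.arange(n_frames)
    if amplitude == 0.0:
        centre = np.zeros(n_frames)
        states = np.full(n_frames - 1, 1, dtype=np.int8)  # constant +-
    else:
        phase = t % (2 * half_period)
        centre = amplitude * np.where(phase < half_period,
                                      phase / half_period,
                                      2.0 - phase / half_period)
        dc = np.diff(centre)
        states = np.where(dc > 0, 1, 2).astype(np.int8)  # +- right, -+ left
    x1 = centre + separation / 2.0
    x2 = centre - separation / 2.0
    traj = PairedTrajectory(frames=t, x1=x1, x2=x2, dt=dt,
                            pair_id="sawtooth")
    return traj, _record_truth(states, dt)
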