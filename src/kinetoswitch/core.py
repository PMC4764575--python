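"""Core domain types for sister-kinetochore oscillation analysis.

Positions are in nanometres, measured along the metaphase-plate normal
(sister 1 on the positive side, sister 2 on the negative side, so typically
``x1 > x2``).  Time is discrete at the imaging frame interval ``dt``
(default 2 s).  Each sister's K-fibre is in one of two states, polymerising
(``+``) or depolymerising (``-``); the pair state therefore takes one of
four values ``++, +-, -+, --``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PP", "PM", "MP", "MM",
    "STATE_LABELS", "COHERENT_STATES", "SISTER1_PLUS", "SISTER2_PLUS",
    "state_from_signs", "is_coherent", "run_direction", "lead_sister_of_state",
    "transition_matrix",
    "ModelParams", "SIMULATION_PARAMS",
    "PairedTrajectory", "TruthRecord",
]

# Pair-state codes.  Entry k of the label gives sister k's K-fibre state.
PP, PM, MP, MM = 0, 1, 2, 3
STATE_LABELS = ("++", "+-", "-+", "--")
#: Coherent pair states: the sisters move in the same spatial direction.
COHERENT_STATES = (PM, MP)
#: sister 1 / sister 2 polymerising indicator per state code
SISTER1_PLUS = np.array([True, True, False, False])
SISTER2_PLUS = np.array([True, False, True, False])


def state_from_signs(s1_plus: bool, s2_plus: bool) -> int:
    """Pair-state code from per-sister polymerising flags."""
    return (0 if s1_plus else 2) + (0 if s2_plus else 1)


def is_coherent(state: int | np.ndarray) -> bool | np.ndarray:
    """Coherent iff the pair state is ``+-`` or ``-+`` (sisters co-moving)."""
    return (state == PM) | (state == MP)


def run_direction(state: int) -> int:
    """Sign of the pair's drift in a coherent state.

    In state ``+-`` the centre drive is ``c(+) - c(-) > 0`` (rightward, +1);
    in ``-+`` it is the mirror image (-1).
    """
    if state == PM:
        return +1
    if state == MP:
        return -1
    raise ValueError(f"state {STATE_LABELS[state]} is not coherent")


def lead_sister_of_state(state: int) -> int:
    """Lead sister (the depolymerising, poleward-pulling one) of a coherent state."""
    if state == PM:
        return 2  # sister 2 is '-'
    if state == MP:
        return 1
    raise ValueError(f"state {STATE_LABELS[state]} is not coherent")


def transition_matrix(p_incoherent: float, p_coherent: float) -> np.ndarray:
    """Per-frame 4x4 pair-state transition matrix.

    Exactly one sister may flip per frame, chosen uniformly at random; the
    flip occurs with probability ``p_coherent`` out of a coherent state and
    ``p_incoherent`` out of an incoherent one.  Double flips (``++`` to
    ``--`` and ``+-`` to ``-+``) have probability zero.
    """
    pi, pc = p_incoherent, p_coherent
    return np.array([
        [1 - pi, pi / 2, pi / 2, 0.0],
        [pc / 2, 1 - pc, 0.0, pc / 2],
        [pc / 2, 0.0, 1 - pc, pc / 2],
        [0.0, pi / 2, pi / 2, 1 - pi],
    ])


@dataclass
class ModelParams:
    """Parameters of the switching autoregressive sister-pair model.

    Frame-to-frame displacements are

        dx1 = c0 + c(s1) - a*x1 + b*x2 + N(0, s2)
        dx2 = -c0 - c(s2) - a*x2 + b*x1 + N(0, s2)

    with ``c(+) = c_plus`` and ``c(-) = c_minus``.  ``a`` relaxes each
    sister towards the plate, ``b`` couples the sisters; with drives off the
    pair relaxes to an inter-sister separation of ``2*c0/(b+a)``.

    Parameters
    ----------
    a, b : float
        Per-frame relaxation and sister-coupling coefficients (dimensionless).
    c0 : float
        Baseline drive maintaining the inter-sister separation (nm/frame).
    c_plus, c_minus : float
        Switching drive components for the polymerising (+, > 0) and
        depolymerising (-, < 0) K-fibre states (nm/frame).
    s2 : float
        Gaussian displacement-noise variance (nm^2).
    p_incoherent, p_coherent : float
        Per-frame probability that one sister flips, out of an incoherent /
        coherent pair state.
    dt : float
        Frame interval in seconds.
    """

    a: float
    b: float
    c0: float
    c_plus: float
    c_minus: float
    s2: float
    p_incoherent: float
    p_coherent: float
    dt: float = 2.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.c0, self.c_plus,
                                self.c_minus, self.s2,
                                self.p_incoherent, self.p_coherent])):
            raise ValueError("ModelParams fields must be finite")
        if self.c0 <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("c0, a, b must be positive (2*c0/(b+a) > 0)")
        if not (self.c_plus > 0 > self.c_minus):
            raise ValueError("require c_plus > 0 > c_minus")
        if not (0 <= self.p_incoherent <= 1 and 0 <= self.p_coherent <= 1):
            raise ValueError("switch probabilities must lie in [0, 1]")
        if self.s2 < 0:
            raise ValueError("noise variance s2 must be >= 0")

    @property
    def equilibrium_separation(self) -> float:
        """Relaxed inter-sister separation 2*c0/(b+a) with drives off (nm)."""
        return 2.0 * self.c0 / (self.a + self.b)

    @property
    def oscillatory(self) -> bool:
        """Regime producing pseudo-periodic saw-tooth oscillations."""
        return self.a > self.b and self.p_incoherent > self.p_coherent

    def drive(self, plus: bool) -> float:
        return self.c_plus if plus else self.c_minus

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


#: Reference parameter set for the simulation study: produces qualitatively
#: realistic saw-tooth oscillations of a sister pair (noise variance read in
#: micrometre units, 1/1000 um^2 = 1000 nm^2).
SIMULATION_PARAMS = ModelParams(
    a=0.056, b=0.04, c0=667.0, c_plus=30.0, c_minus=-100.0,
    s2=1000.0, p_incoherent=0.39, p_coherent=0.063, dt=2.0,
)


@dataclass
class PairedTrajectory:
    """One sister-kinetochore pair tracked over contiguous frames.

    ``x1``/``x2`` are signed distances from the metaphase plate along its
    normal (nm).  Optional full 3D positions (``pos1``/``pos2``, shape
    ``(n, 3)`` in nm) are carried when the track comes from 3D data.
    """

    frames: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    dt: float = 2.0
    pos1: np.ndarray | None = None
    pos2: np.ndarray | None = None
    pair_id: str = "pair0"
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x1 = np.asarray(self.x1, dtype=np.float64)
        self.x2 = np.asarray(self.x2, dtype=np.float64)
        if not (len(self.frames) == len(self.x1) == len(self.x2)):
            raise ValueError("frames, x1, x2 must have equal length")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def time_s(self) -> np.ndarray:
        return self.frames * self.dt

    @property
    def n_steps(self) -> int:
        """Number of frame-to-frame displacement steps (= hidden-state path length)."""
        return len(self.frames) - 1

    def displacements(self) -> tuple[np.ndarray, np.ndarray]:
        return np.diff(self.x1), np.diff(self.x2)


@dataclass
class TruthRecord:
    """Generative bookkeeping for a simulated trajectory.

    ``state_path[t]`` is the pair state driving the displacement from frame
    ``t`` to ``t+1``.  ``switch_list`` holds every frame-to-frame state
    change as ``(step_index, sister, from_state, to_state)``.  ``event_list``
    holds the true directional switching events (filled by the events
    module) with their true LIDS/TIDS/JDS labels.
    """

    state_path: np.ndarray
    switch_list: list[tuple[int, int, int, int]] = field(default_factory=list)
    event_list: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.state_path = np.asarray(self.state_path, dtype=np.int8)
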