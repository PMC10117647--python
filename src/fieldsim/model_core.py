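"""Well-mixed hybrid Moran/branching model of cancer initiation and recurrence.

The tissue is a constant-size Moran population of ``N`` cells carrying 0,
1 or S-1 driver mutations (Type 0, Type 1, Type S-1).  Turnover happens at
rate ``d*N``: a uniformly chosen cell dies and the vacancy is filled by a
fitness-weighted division draw, with per-division mutation probabilities
``mu1`` (0 -> 1), ``muS1`` (1 -> S-1) and ``muS`` (S-1 -> S).  A division of
a Type S-1 cell can instead produce a malignant Type S daughter; malignant
cells are not part of the tissue and grow as a supercritical birth-death
(branching) process with birth rate ``rS`` and death rate ``dS`` per cell.
When the malignant count reaches ``detection_threshold`` (10^9 cells, about
1 cm^3) the tumor is detected and resected; the tissue composition — the
cancerized field — is preserved, and the clock to locoregional recurrence
starts.

Once the malignant clone exceeds ``hybrid_switch * N`` cells its extinction
probability is negligible and the remaining growth is treated as
deterministic exponential expansion; tissue turnover continues to be
simulated during that interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Optional, Union

import numpy as np

from . import _kernels

__all__ = [
    "FrozenTissueError",
    "DivisionOutcome",
    "ModelParameters",
    "TissueState",
    "TumorState",
    "DetectionResult",
    "SimulationOutcome",
    "waiting_time",
    "event_channel_probabilities",
    "division_distribution",
    "turnover_step",
    "deterministic_growth_time",
    "apply_surgery",
    "simulate_to_detection",
    "run_full",
    "birth_death_passage_time",
    "proportion_bin",
    "REDRAW_CAP",
]

REDRAW_CAP = _kernels.REDRAW_CAP

RngLike = Union[int, np.random.Generator, None]


class FrozenTissueError(RuntimeError):
    """Raised when every event rate is zero and no further event can occur."""


class DivisionOutcome(IntEnum):
    """The four possible daughters of a single division draw."""

    DAUGHTER_TYPE0 = 0
    DAUGHTER_TYPE1 = 1
    DAUGHTER_TYPES1 = 2
    TYPES_BIRTH = 3


@dataclass(frozen=True)
class ModelParameters:
    """All rates, fitnesses and sizes of the hybrid model.

    Attributes
    ----------
    N : int
        Tissue size (number of Moran-compartment cells), at least 2.
    d : float
        Tissue turnover rate; turnover events occur at total rate ``d*N``.
    r0, r1, rS1 : float
        Fitness weights of Type 0 / Type 1 / Type S-1 cells in the
        division draw (dimensionless; ``r0`` is conventionally 1).
    rS, dS : float
        Per-cell birth and death rates of malignant Type S cells.  The
        model assumes net growth ``rS - dS > 0``; a warning is emitted
        otherwise.
    mu1, muS1, muS : float
        Per-division mutation probabilities for the transitions
        0 -> 1, 1 -> S-1 and S-1 -> S; each in [0, 1].
    detection_threshold : float
        Malignant cell count that triggers detection and surgery
        (default 1e9, roughly a 1 cm^3 tumor).
    hybrid_switch : float
        Multiple of N above which malignant growth is treated as
        deterministic (default 2).
    max_time : float
        Simulation-time cap per phase; runs that have not detected by
        then are censored.
    """

    N: int
    d: float = 1.0
    r0: float = 1.0
    r1: float = 1.0
    rS1: float = 1.0
    rS: float = 1.5
    dS: float = 1.0
    mu1: float = 0.0
    muS1: float = 0.0
    muS: float = 0.0
    detection_threshold: float = 1e9
    hybrid_switch: float = 2.0
    max_time: float = 1e4

    def __post_init__(self):
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N}")
        for name in ("d", "r0", "r1", "rS1", "rS", "dS",
                     "hybrid_switch", "max_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("mu1", "muS1", "muS"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.detection_threshold <= self.hybrid_switch * self.N:
            raise ValueError(
                "detection_threshold must exceed hybrid_switch * N "
                f"({self.detection_threshold} <= {self.hybrid_switch * self.N})"
            )
        if self.rS <= self.dS:
            warnings.warn(
                "rS <= dS: the malignant clone has no net growth and "
                "detection will essentially always censor",
                UserWarning,
                stacklevel=2,
            )

    @property
    def switch_count(self) -> float:
        """Malignant count at which growth becomes deterministic."""
        return self.hybrid_switch * self.N


@dataclass(frozen=True)
class TissueState:
    """Counts of the three tissue cell types; X0 + X1 + XS1 is the size N."""

    X0: int
    X1: int
    XS1: int

    def __post_init__(self):
        if min(self.X0, self.X1, self.XS1) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def N(self) -> int:
        return self.X0 + self.X1 + self.XS1

    @classmethod
    def all_type0(cls, N: int) -> "TissueState":
        return cls(N, 0, 0)

    def counts(self) -> np.ndarray:
        return np.array([self.X0, self.X1, self.XS1], dtype=np.int64)

    def fractions(self) -> np.ndarray:
        return self.counts() / self.N


@dataclass(frozen=True)
class TumorState:
    """Off-tissue malignant compartment: cell count XS at simulation time t."""

    XS: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        if self.XS < 0:
            raise ValueError("XS must be non-negative")
        if self.t < 0:
            raise ValueError("t must be non-negative")


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of a single initiation phase (start of tissue to detection)."""

    detected: bool
    t_detect: float
    composition: TissueState


@dataclass(frozen=True)
class SimulationOutcome:
    """One full run: initiation, surgery at detection, then recurrence.

    When ``detected`` (or ``recurred``) is False the corresponding time
    holds the censoring horizon ``max_time`` rather than an event time.
    """

    detected: bool
    t_detect: float
    composition_at_surgery: Optional[TissueState]
    recurred: bool
    t_recur: float
    rng_seed: int


# ---------------------------------------------------------------------------
# event algebra


def waiting_time(params: ModelParameters, XS: float) -> float:
    """Mean waiting time 1 / (d*N + rS*XS + dS*XS) to the next event."""
    if XS < 0:
        raise ValueError("XS must be non-negative")
    total = params.d * params.N + (params.rS + params.dS) * XS
    if total <= 0.0:
        raise FrozenTissueError("all event rates are zero; the system is frozen")
    return 1.0 / total


def event_channel_probabilities(params: ModelParameters, XS: float):
    """Probabilities of (tissue turnover, Type S birth, Type S death).

    Each is its event rate times the mean waiting time, so the three
    sum to one.
    """
    dt = waiting_time(params, XS)
    return (
        params.d * params.N * dt,
        params.rS * XS * dt,
        params.dS * XS * dt,
    )


def division_distribution(state: TissueState,
                          params: ModelParameters) -> np.ndarray:
    """Distribution over :class:`DivisionOutcome` for one vacancy draw.

    The dividing cell is selected with probability proportional to
    fitness times count over the full (pre-death) composition, and its
    daughter may carry one additional mutation.  Indexed by
    ``DivisionOutcome``; sums to one.
    """
    F = (params.r0 * state.X0 + params.r1 * state.X1
         + params.rS1 * state.XS1)
    if F <= 0.0:
        raise FrozenTissueError("no cell can divide (zero total fitness)")
    p = np.empty(4)
    p[DivisionOutcome.DAUGHTER_TYPE0] = (
        params.r0 * state.X0 * (1.0 - params.mu1) / F)
    p[DivisionOutcome.DAUGHTER_TYPE1] = (
        (params.r1 * state.X1 * (1.0 - params.muS1)
         + params.r0 * state.X0 * params.mu1) / F)
    p[DivisionOutcome.DAUGHTER_TYPES1] = (
        (params.rS1 * state.XS1 * (1.0 - params.muS)
         + params.r1 * state.X1 * params.muS1) / F)
    p[DivisionOutcome.TYPES_BIRTH] = (
        params.rS1 * state.XS1 * params.muS / F)
    return p


def _draw_outcome(probs: np.ndarray, rng: np.random.Generator) -> int:
    u = rng.random()
    acc = 0.0
    for k in range(3):
        acc += probs[k]
        if u < acc:
            return k
    return int(DivisionOutcome.TYPES_BIRTH)


def turnover_step(state: TissueState, tumor: TumorState,
                  params: ModelParameters,
                  rng: np.random.Generator):
    """One Moran turnover: a uniform death and a division filling the vacancy.

    Every malignant-birth draw adds one Type S cell to the tumor and the
    vacancy draw repeats (a single turnover can therefore seed several
    malignant cells); redraws are capped at :data:`REDRAW_CAP`.  Returns
    the updated ``(state, tumor)``; simulation time is advanced by the
    caller.
    """
    N = state.N
    v = rng.random() * N
    if v < state.X0:
        dying = 0
    elif v < state.X0 + state.X1:
        dying = 1
    else:
        dying = 2
    probs = division_distribution(state, params)
    births = 0
    daughter = -1
    for _ in range(REDRAW_CAP):
        k = _draw_outcome(probs, rng)
        if k == DivisionOutcome.TYPES_BIRTH:
            births += 1
            continue
        daughter = k
        break
    else:
        raise RuntimeError(
            f"no tissue daughter drawn within {REDRAW_CAP} redraws "
            "(muS is pathologically close to 1)")
    counts = [state.X0, state.X1, state.XS1]
    counts[dying] -= 1
    counts[daughter] += 1
    new_state = TissueState(*counts)
    new_tumor = replace(tumor, XS=tumor.XS + births) if births else tumor
    return new_state, new_tumor


def deterministic_growth_time(rS: float, dS: float, N: int,
                              threshold: float) -> float:
    """Time for deterministic growth from 2N malignant cells to threshold.

    Net exponential growth at rate ``rS - dS`` gives
    ``ln(threshold / (2N)) / (rS - dS)``.
    """
    if rS <= dS:
        raise ValueError("deterministic growth requires rS > dS")
    if threshold < 2 * N:
        raise ValueError("threshold must be at least 2N")
    return math.log(threshold / (2.0 * N)) / (rS - dS)


def apply_surgery(tumor: TumorState) -> TumorState:
    """Resect the tumor: every malignant cell is removed, the clock and
    the tissue (tracked separately) are untouched."""
    return replace(tumor, XS=0.0)


# ---------------------------------------------------------------------------
# whole runs (compiled kernels)


def _kernel_seed(rng: RngLike) -> int:
    """Derive a 31-bit kernel seed from an int / Generator / None."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2 ** 31)
    return int(rng.integers(2 ** 31))


_STATUS_ERRORS = {
    _kernels.FROZEN: FrozenTissueError(
        "all event rates are zero; the system is frozen"),
    _kernels.REDRAW_EXCEEDED: RuntimeError(
        f"no tissue daughter drawn within {REDRAW_CAP} redraws"),
}


def _run_phase(params: ModelParameters, state: TissueState,
               XS: float, seed: int):
    status, t_end, X0, X1, XS1, XS_end = _kernels.well_mixed_phase(
        seed, params.N, params.d, params.r0, params.r1, params.rS1,
        params.rS, params.dS, params.mu1, params.muS1, params.muS,
        float(params.detection_threshold), float(params.switch_count),
        float(params.max_time),
        int(state.X0), int(state.X1), int(state.XS1), float(XS))
    if status in _STATUS_ERRORS:
        raise _STATUS_ERRORS[status]
    return status == _kernels.OK, t_end, TissueState(int(X0), int(X1), int(XS1))


def simulate_to_detection(params: ModelParameters,
                          initial: Optional[TissueState] = None,
                          rng: RngLike = None) -> DetectionResult:
    """Simulate from a (default all-Type 0) tissue until first detection.

    Returns a :class:`DetectionResult`; a run whose malignant count
    never reaches the detection threshold within ``max_time`` is
    censored (``detected=False`` with ``t_detect = max_time``).
    """
    if initial is None:
        initial = TissueState.all_type0(params.N)
    if initial.N != params.N:
        raise ValueError("initial tissue size does not match params.N")
    seed = _kernel_seed(rng)
    detected, t_end, comp = _run_phase(params, initial, 0.0, seed)
    return DetectionResult(detected, t_end, comp)


def run_full(params: ModelParameters, rng: RngLike = None,
             initial: Optional[TissueState] = None) -> SimulationOutcome:
    """One full run: initiation to detection, surgery, then recurrence.

    Surgery removes every malignant cell but preserves the tissue
    composition (the cancerized field); the recurrence clock measures
    the time from surgery until the malignant count re-reaches the
    detection threshold.  Both phases are censored at ``max_time``.
    """
    if initial is None:
        initial = TissueState.all_type0(params.N)
    seed = _kernel_seed(rng)
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    detected, t_detect, comp = _run_phase(params, initial, 0.0, s1)
    if not detected:
        return SimulationOutcome(False, params.max_time, None,
                                 False, params.max_time, seed)
    # surgery: malignant cells discarded, tissue preserved
    recurred, t_recur, _ = _run_phase(params, comp, 0.0, s2)
    if not recurred:
        t_recur = params.max_time
    return SimulationOutcome(True, t_detect, comp, recurred, t_recur, seed)


def birth_death_passage_time(x0: int, rS: float, dS: float, target: float,
                             rng: RngLike = None):
    """First-passage time of a linear birth-death clone from x0 to target.

    Fully stochastic (no deterministic shortcut); used to justify the
    hybrid switch.  Returns ``(reached, t)`` where ``reached`` is False
    when the clone went extinct first.
    """
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    reached, t = _kernels.birth_death_passage(
        _kernel_seed(rng), int(x0), rS, dS, float(target))
    return bool(reached), float(t)


def proportion_bin(composition: TissueState, N: Optional[int] = None) -> str:
    """Bin the Type S-1 count: 'small' (<= 0.1N), 'intermediate'
    (0.1N < XS1 <= 0.9N) or 'large' (> 0.9N)."""
    if N is None:
        N = composition.N
    x = composition.XS1
    if x <= 0.1 * N:
        return "small"
    if x <= 0.9 * N:
        return "intermediate"
    return "large"
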