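"""2D-lattice refinement of the Moran tissue.

Cells occupy an I x J grid with wall boundaries (no wraparound).  The
event algebra is identical to the well-mixed model except for the choice
of the dividing cell: when the cell at <i, j> dies, only its von Neumann
neighbours (up to 4) compete to fill the vacancy, weighted by fitness.
Malignant Type S cells disrupt the lattice and are kept as an off-lattice
count, exactly as in the well-mixed engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .model_core import (DetectionResult, ModelParameters,
                         SimulationOutcome, TissueState, TumorState,
                         DivisionOutcome, RngLike, REDRAW_CAP, _kernel_seed,
                         _STATUS_ERRORS)

__all__ = [
    "LatticeTissue",
    "neighbors",
    "local_division_distribution",
    "spatial_turnover_step",
    "simulate_spatial_to_detection",
    "simulate_spatial",
    "square_dims",
]

# cell-type codes on the grid
TYPE0, TYPE1, TYPES1 = 0, 1, 2


def square_dims(N: int) -> Tuple[int, int]:
    """Default square geometry I = J = ceil(sqrt(N)); requires I*J == N."""
    side = math.isqrt(N)
    if side * side != N:
        raise ValueError(
            f"N={N} is not a perfect square; pass explicit dims (I, J)")
    return side, side


@dataclass
class LatticeTissue:
    """An I x J grid of tissue cell-type codes {0, 1, 2} (2 is Type S-1)."""

    grid: np.ndarray  # shape (I, J), int8

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2:
            raise ValueError("grid must be two-dimensional")
        if not np.isin(self.grid, (TYPE0, TYPE1, TYPES1)).all():
            raise ValueError("grid entries must be cell-type codes 0, 1 or 2")

    @property
    def dims(self) -> Tuple[int, int]:
        return self.grid.shape

    @property
    def N(self) -> int:
        return self.grid.size

    @classmethod
    def all_type0(cls, I: int, J: int) -> "LatticeTissue":
        return cls(np.zeros((I, J), dtype=np.int8))

    def composition(self) -> TissueState:
        flat = self.grid.ravel()
        return TissueState(int((flat == TYPE0).sum()),
                           int((flat == TYPE1).sum()),
                           int((flat == TYPES1).sum()))

    def copy(self) -> "LatticeTissue":
        return LatticeTissue(self.grid.copy())


def neighbors(pos: Tuple[int, int], dims: Tuple[int, int]) -> List[Tuple[int, int]]:
    """In-bounds von Neumann neighbours of ``pos`` under wall boundaries.

    Corners have 2 neighbours, edges 3, interior sites 4.
    """
    i, j = pos
    I, J = dims
    if not (0 <= i < I and 0 <= j < J):
        raise ValueError(f"position {pos} outside lattice {dims}")
    out = []
    if i > 0:
        out.append((i - 1, j))
    if i < I - 1:
        out.append((i + 1, j))
    if j > 0:
        out.append((i, j - 1))
    if j < J - 1:
        out.append((i, j + 1))
    return out


def _neighbor_counts(lattice: LatticeTissue, pos) -> TissueState:
    n = [0, 0, 0]
    for q in neighbors(pos, lattice.dims):
        n[lattice.grid[q]] += 1
    return TissueState(*n)


def local_division_distribution(lattice: LatticeTissue,
                                dead_pos: Tuple[int, int],
                                params: ModelParameters) -> np.ndarray:
    """Division-outcome distribution restricted to the dead cell's
    neighbourhood.

    Identical in form to the well-mixed distribution with the global
    counts replaced by neighbour-type counts and the scaling factor by
    the fitness-weighted sum over the neighbours.
    """
    from .model_core import division_distribution

    counts = _neighbor_counts(lattice, dead_pos)
    return division_distribution(counts, params)


def spatial_turnover_step(lattice: LatticeTissue, tumor: TumorState,
                          params: ModelParameters,
                          rng: np.random.Generator):
    """One lattice turnover: uniform death site, local fitness-weighted
    refill; malignant births go to the off-lattice count with the same
    redraw rule as the well-mixed engine.

    Mutates and returns ``lattice`` (grids persist across surgery);
    returns a fresh ``tumor``.
    """
    from dataclasses import replace

    from .model_core import _draw_outcome

    I, J = lattice.dims
    idx = int(rng.integers(I * J))
    pos = (idx // J, idx % J)
    probs = local_division_distribution(lattice, pos, params)
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
            f"no tissue daughter drawn within {REDRAW_CAP} redraws")
    lattice.grid[pos] = daughter
    new_tumor = replace(tumor, XS=tumor.XS + births) if births else tumor
    return lattice, new_tumor


def _run_spatial_phase(params: ModelParameters, lattice: LatticeTissue,
                       XS: float, seed: int):
    I, J = lattice.dims
    flat = lattice.grid.ravel()  # view; kernel updates the grid in place
    status, t_end, XS_end = _kernels.spatial_phase(
        seed, flat, I, J, params.d, params.r0, params.r1, params.rS1,
        params.rS, params.dS, params.mu1, params.muS1, params.muS,
        float(params.detection_threshold), float(params.switch_count),
        float(params.max_time), float(XS))
    if status in _STATUS_ERRORS:
        raise _STATUS_ERRORS[status]
    return status == _kernels.OK, t_end


def simulate_spatial_to_detection(params: ModelParameters,
                                  dims: Optional[Tuple[int, int]] = None,
                                  initial: Optional[LatticeTissue] = None,
                                  rng: RngLike = None) -> DetectionResult:
    """Lattice analogue of well-mixed detection simulation."""
    lattice = _initial_lattice(params, dims, initial)
    seed = _kernel_seed(rng)
    detected, t_end = _run_spatial_phase(params, lattice, 0.0, seed)
    return DetectionResult(detected, t_end, lattice.composition())


def _initial_lattice(params, dims, initial) -> LatticeTissue:
    if initial is not None:
        lattice = initial.copy()
    else:
        if dims is None:
            dims = square_dims(params.N)
        lattice = LatticeTissue.all_type0(*dims)
    if lattice.N != params.N:
        raise ValueError(
            f"lattice size {lattice.dims} does not match N={params.N}")
    return lattice


def simulate_spatial(params: ModelParameters,
                     dims: Optional[Tuple[int, int]] = None,
                     initial: Optional[LatticeTissue] = None,
                     rng: RngLike = None) -> SimulationOutcome:
    """Full lattice run: initiation, surgery, recurrence.

    Same contract as :func:`fieldsim.model_core.run_full`; the lattice
    (with its spatial arrangement of premalignant clones) persists
    through surgery.
    """
    lattice = _initial_lattice(params, dims, initial)
    seed = _kernel_seed(rng)
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    detected, t_detect = _run_spatial_phase(params, lattice, 0.0, s1)
    if not detected:
        return SimulationOutcome(False, params.max_time, None,
                                 False, params.max_time, seed)
    comp = lattice.composition()
    recurred, t_recur = _run_spatial_phase(params, lattice, 0.0, s2)
    if not recurred:
        t_recur = params.max_time
    return SimulationOutcome(True, t_detect, comp, recurred, t_recur, seed)
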