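"""Dominance / co-dominance classification of tissue composition at detection.

A detected run is labelled by the make-up of its premalignant field:
a single cell type above 90% is "dominance"; two types each above 40%
or all three above 30% are "co-dominance".  All thresholds are strict,
and dominance takes precedence over pairwise co-dominance, which takes
precedence over triple co-dominance; compositions matching no rule are
labelled OTHER, and censored runs (no detection) NO_CANCER.
"""

from __future__ import annotations

import dataclasses
import itertools
from enum import Enum
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import ModelParameters, TissueState, simulate_to_detection
from .spatial import simulate_spatial_to_detection, square_dims

__all__ = [
    "PatternLabel",
    "classify",
    "grid_scan",
    "FIG_GRID",
    "figure_grid_base",
]


class PatternLabel(str, Enum):
    DOM_0 = "DOM_0"
    DOM_1 = "DOM_1"
    DOM_S1 = "DOM_S1"
    CODOM_0_1 = "CODOM_0_1"
    CODOM_0_S1 = "CODOM_0_S1"
    CODOM_1_S1 = "CODOM_1_S1"
    CODOM_0_1_S1 = "CODOM_0_1_S1"
    OTHER = "OTHER"
    NO_CANCER = "NO_CANCER"


_DOM = (PatternLabel.DOM_0, PatternLabel.DOM_1, PatternLabel.DOM_S1)
_PAIR = {
    (0, 1): PatternLabel.CODOM_0_1,
    (0, 2): PatternLabel.CODOM_0_S1,
    (1, 2): PatternLabel.CODOM_1_S1,
}


def classify(composition: TissueState, N: Optional[int] = None) -> PatternLabel:
    """Label a tissue composition at cancer detection.

    Thresholds are strict (>90%, >40%, >30%); a composition sitting
    exactly on a boundary falls through to the next rule.
    """
    if N is None:
        N = composition.N
    f = composition.counts() / N
    for i in range(3):
        if f[i] > 0.9:
            return _DOM[i]
    big = [i for i in range(3) if f[i] > 0.4]
    if len(big) >= 2:
        return _PAIR[tuple(big[:2])]
    if (f > 0.3).all():
        return PatternLabel.CODOM_0_1_S1
    return PatternLabel.OTHER


# parameter grid of the initiation-pattern scans: r1 and rS1 span low /
# neutral / high fitness, muS1 spans five decades (a low value stands in
# for extra intermediate mutational steps), muS two decades.
FIG_GRID: Dict[str, Sequence[float]] = {
    "r1": (0.75, 1.00, 1.25),
    "rS1": (0.75, 1.00, 1.25),
    "muS1": (1e-6, 1e-5, 1e-4, 1e-3, 1e-2),
    "muS": (1e-3, 1e-2),
}


def figure_grid_base(N: int, **overrides) -> ModelParameters:
    """Baseline parameters of the initiation-pattern scans at tissue size N:
    d = dS = 1, r0 = 1, rS = 1.5, mu1 = 0.001."""
    kw = dict(N=N, d=1.0, r0=1.0, rS=1.5, dS=1.0, mu1=1e-3,
              muS1=1e-3, muS=1e-3)
    kw.update(overrides)
    return ModelParameters(**kw)


def grid_scan(engine: str,
              grid: Dict[str, Sequence[float]],
              replicates: int,
              rng,
              base: ModelParameters,
              dims: Optional[Tuple[int, int]] = None) -> pd.DataFrame:
    """Simulate every grid point to detection and classify the tissue.

    Parameters
    ----------
    engine : {"well_mixed", "spatial"}
    grid : mapping of ModelParameters field name to the values to scan.
    replicates : runs per parameter combination (>= 1).
    rng : seed or numpy Generator; per-run seeds are derived from it.
    base : parameters holding every non-scanned value.
    dims : lattice shape for the spatial engine (default square).

    Returns a DataFrame with one row per (combination, replicate):
    the scanned values, replicate id, run seed, detection flag and time,
    and the composition at detection.  Censored runs are labelled
    NO_CANCER.
    """
    if engine not in ("well_mixed", "spatial"):
        raise ValueError(f"unknown engine {engine!r}")
    if not grid:
        raise ValueError("grid must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if engine == "spatial" and dims is None:
        dims = square_dims(base.N)

    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in names)):
        params = dataclasses.replace(base, **dict(zip(names, values)))
        for rep in range(replicates):
            seed = int(rng.integers(2 ** 31))
            if engine == "well_mixed":
                res = simulate_to_detection(params, rng=seed)
            else:
                res = simulate_spatial_to_detection(params, dims=dims,
                                                    rng=seed)
            label = (classify(res.composition) if res.detected
                     else PatternLabel.NO_CANCER)
            row = dict(zip(names, values))
            row.update(replicate=rep, seed=seed, detected=res.detected,
                       t_detect=res.t_detect, label=label.value,
                       X0=res.composition.X0, X1=res.composition.X1,
                       XS1=res.composition.XS1)
            rows.append(row)
    return pd.DataFrame(rows)
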