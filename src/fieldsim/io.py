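"""Readers and writers for every external format, plus packaged fixtures.

Tabular formats are tab-separated UTF-8 text with a header row and "."
as the decimal separator.  Clinical disease-free-survival tables follow
the cBioPortal export dialect: PATIENT_ID, DFS_MONTHS, DFS_STATUS with
status strings like "0:DiseaseFree" / "1:Recurred/Progressed" (bare 0/1
also accepted).
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .fitting import CancerProfile
from .model_core import ModelParameters, SimulationOutcome
from .survival import SurvivalSample

__all__ = [
    "read_dfs_table",
    "write_dfs_table",
    "load_profiles",
    "read_config",
    "params_from_config",
    "write_outcomes",
    "write_lattice",
    "read_lattice",
]

logger = logging.getLogger("fieldsim")

_PROFILE_FIXTURE = "carcinogenic_profiles.tsv"
_PROFILE_SHA256 = (
    "9e4f8c092ed5e492c1c2c53007fbe7978c7e3284c722b5c336f85e4037d8c25c")

_STATUS_MAP = {
    "0:DiseaseFree": False,
    "1:Recurred/Progressed": True,
    "0": False,
    "1": True,
}


def read_dfs_table(path: Union[str, Path]) -> SurvivalSample:
    """Parse a disease-free-survival TSV into a :class:`SurvivalSample`.

    Rows with a missing time or status are dropped (with a logged
    count); an unrecognised status string is an error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["PATIENT_ID", "DFS_MONTHS", "DFS_STATUS"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    blank = df["DFS_MONTHS"].isna() | (df["DFS_MONTHS"].str.strip() == "") \
        | df["DFS_STATUS"].isna() | (df["DFS_STATUS"].str.strip() == "")
    if blank.any():
        logger.info("dropped %d row(s) with missing DFS time or status",
                    int(blank.sum()))
        df = df[~blank]
    events = []
    for row, status in zip(df.index, df["DFS_STATUS"].str.strip()):
        if status not in _STATUS_MAP:
            raise ValueError(
                f"unparseable DFS_STATUS {status!r} at row {row + 2}")
        events.append(_STATUS_MAP[status])
    times = df["DFS_MONTHS"].astype(float).to_numpy()
    return SurvivalSample(times, np.array(events, dtype=bool),
                          patient_ids=df["PATIENT_ID"].to_numpy())


def write_dfs_table(sample: SurvivalSample, path: Union[str, Path]) -> None:
    sample.to_frame().to_csv(path, sep="\t", index=False)


def load_profiles() -> List[CancerProfile]:
    """Load the 27 bundled tumor-specific carcinogenic profiles.

    The fixture is integrity-checked by SHA-256 before parsing.
    """
    data = (resources.files("fieldsim") / "data" / _PROFILE_FIXTURE).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _PROFILE_SHA256:
        raise RuntimeError(
            f"profile fixture checksum mismatch ({digest}); "
            "the packaged data file is corrupted")
    df = pd.read_csv(pd.io.common.BytesIO(data), sep="\t")
    profiles = [CancerProfile(**row) for row in df.to_dict("records")]
    codes = [p.code for p in profiles]
    if len(set(codes)) != len(codes):
        raise RuntimeError("duplicate cancer codes in profile fixture")
    return profiles


_PARAM_KEYS = {"N", "d", "r0", "r1", "rS1", "rS", "dS", "mu1", "muS1", "muS",
               "detection_threshold", "hybrid_switch", "max_time"}
_EXTRA_KEYS = {"seed", "I", "J", "engine"}


def read_config(path: Union[str, Path]) -> Dict:
    """Read a flat key: value run configuration (YAML syntax)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat mapping of key: value pairs")
    unknown = set(cfg) - _PARAM_KEYS - _EXTRA_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return cfg


def params_from_config(cfg: Dict) -> ModelParameters:
    """Build :class:`ModelParameters` from a parsed config mapping."""
    kwargs = {k: v for k, v in cfg.items() if k in _PARAM_KEYS}
    if "N" not in kwargs:
        if "I" in cfg and "J" in cfg:
            kwargs["N"] = int(cfg["I"]) * int(cfg["J"])
        else:
            raise ValueError("config must define N (or lattice dims I and J)")
    kwargs["N"] = int(kwargs["N"])
    return ModelParameters(**kwargs)


_OUTCOME_COLS = ["run_id", "seed", "t_detect", "X0", "X1", "XS1",
                 "t_recur", "detected", "recurred"]


def write_outcomes(outcomes: Sequence[SimulationOutcome],
                   path: Union[str, Path]) -> None:
    """Write a batch of run outcomes as a TSV."""
    rows = []
    for k, o in enumerate(outcomes):
        comp = o.composition_at_surgery
        rows.append({
            "run_id": k, "seed": o.rng_seed, "t_detect": o.t_detect,
            "X0": comp.X0 if comp else "", "X1": comp.X1 if comp else "",
            "XS1": comp.XS1 if comp else "",
            "t_recur": o.t_recur,
            "detected": int(o.detected), "recurred": int(o.recurred),
        })
    pd.DataFrame(rows, columns=_OUTCOME_COLS).to_csv(path, sep="\t",
                                                     index=False)


def write_lattice(grid: np.ndarray, path: Union[str, Path]) -> None:
    """Write a lattice snapshot as a plain-text integer grid, one row of
    space-separated cell-type codes per line."""
    np.savetxt(path, np.asarray(grid, dtype=int), fmt="%d")


def read_lattice(path: Union[str, Path]) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8, ndmin=2)
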