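"""File formats: JSON parameter sets, CSV trajectories and datasets.

CSV dialect is comma-separated with a mandatory header and '.' decimals;
floats are serialised with ``repr`` (shortest round-trip representation),
so write -> read is bit-lossless.  Machine-readable results are JSON with a
provenance block (package version, seed, input hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BinarySwitchParams, Trajectory

__all__ = [
    "read_params",
    "write_params",
    "write_trajectory",
    "read_trajectory",
    "write_json",
    "provenance",
]


def read_params(path) -> BinarySwitchParams:
    """Load a parameter set from a JSON object ``{r, R, alpha, beta, M}``."""
    with open(path) as fh:
        d = json.load(fh)
    return BinarySwitchParams.from_dict(d)


def write_params(params: BinarySwitchParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def write_trajectory(traj, path) -> None:
    """Write a time course as CSV with header ``t,density``."""
    df = pd.DataFrame({"t": np.asarray(traj.times, dtype=float),
                       "density": np.asarray(traj.densities, dtype=float)})
    df.to_csv(path, index=False, float_format=None)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"t", "density"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns t,density")
    return df


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(payload), indent=2,
                                     sort_keys=True) + "\n")


def provenance(seed=None, config_text: str | None = None) -> dict:
    """Provenance block recorded in every result file."""
    from . import __version__

    block = {"package": "binaryswitch", "version": __version__, "seed": seed}
    if config_text is not None:
        block["config_sha256"] = hashlib.sha256(
            config_text.encode()).hexdigest()
    return block
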