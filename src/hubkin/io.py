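"""File-format contracts: TIFF stacks, track CSVs, JSON sidecars.

Movies are multi-page TIFF in TZYX order (two-colour data as separate
files). Track tables are CSV with header ``track_id,frame,x_um,y_um,
intensity``. Ground truth and reports are JSON. All writers are
deterministic so identically seeded runs produce byte-identical artefacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import TRACK_COLUMNS

__all__ = ["save_stack", "load_stack", "save_tracks", "load_tracks",
           "save_json", "load_json"]


def save_stack(path, stack: np.ndarray, axes: str = "TZYX") -> None:
    """Write a stack as multi-page TIFF (no datetime tag, reproducible)."""
    tifffile.imwrite(str(path), np.asarray(stack), metadata={"axes": axes})


def load_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_tracks(path, tracks: pd.DataFrame) -> None:
    missing = set(TRACK_COLUMNS) - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")
    tracks[TRACK_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def load_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: track CSV missing columns {sorted(missing)}")
    return df


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())
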