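"""Reading and writing threshold maps, plans, and fits.

The canonical threshold-map CSV has one row per electrode:

    electrode_id,row,col,active,threshold_uA,censored

with an empty threshold on inactive electrodes.  The JSON form carries the
same per-electrode fields plus the stimulus metadata (pulse width,
frequency, label) and the amplitude-ladder definition.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import AmplitudeLadder, ElectrodeGrid, ThresholdMap

__all__ = [
    "threshold_map_to_frame",
    "write_map_csv",
    "read_map_csv",
    "write_map_json",
    "read_map_json",
]

CSV_COLUMNS = ["electrode_id", "row", "col", "active", "threshold_uA", "censored"]


def threshold_map_to_frame(tmap: ThresholdMap) -> pd.DataFrame:
    grid = tmap.grid
    ids = grid.electrode_ids
    rows, cols = np.divmod(ids, grid.n_cols)
    return pd.DataFrame(
        {
            "electrode_id": ids,
            "row": rows,
            "col": cols,
            "active": grid.active_mask.astype(int),
            "threshold_uA": tmap.thresholds_uA,
            "censored": tmap.censored.astype(int),
        }
    )


def write_map_csv(tmap: ThresholdMap, path: str | Path) -> None:
    threshold_map_to_frame(tmap).to_csv(path, index=False, float_format="%.10g")


def _frame_to_map(df: pd.DataFrame, **metadata) -> ThresholdMap:
    df = df.sort_values("electrode_id").reset_index(drop=True)
    n = len(df)
    n_cols = int(df["col"].max()) + 1
    n_rows = int(df["row"].max()) + 1
    if n_rows * n_cols != n:
        raise ValueError("electrode rows/cols do not form a full rectangle")
    if not np.array_equal(df["electrode_id"].to_numpy(), np.arange(n)):
        raise ValueError("electrode_id must run 0..n-1")
    grid = ElectrodeGrid(
        n_rows, n_cols, active_mask=df["active"].to_numpy().astype(bool)
    )
    return ThresholdMap(
        grid=grid,
        thresholds_uA=df["threshold_uA"].to_numpy(dtype=float),
        censored=df["censored"].to_numpy().astype(bool),
        **metadata,
    )


def read_map_csv(path: str | Path) -> ThresholdMap:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"threshold-map CSV missing columns: {sorted(missing)}")
    return _frame_to_map(df, label=Path(path).stem)


def write_map_json(tmap: ThresholdMap, path: str | Path) -> None:
    df = threshold_map_to_frame(tmap)
    payload = {
        "pulse_width_ms": tmap.pulse_width_ms,
        "frequency_hz": tmap.frequency_hz,
        "label": tmap.label,
        "ladder": {
            "minimum": tmap.ladder.minimum,
            "maximum": tmap.ladder.maximum,
            "n_steps": tmap.ladder.n_steps,
        },
        "electrodes": df.replace({np.nan: None}).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_map_json(path: str | Path) -> ThresholdMap:
    d = json.loads(Path(path).read_text())
    df = pd.DataFrame(d["electrodes"])
    ladder = AmplitudeLadder(**d.get("ladder", {}))
    return _frame_to_map(
        df,
        pulse_width_ms=d.get("pulse_width_ms", 0.45),
        frequency_hz=d.get("frequency_hz", 20.0),
        label=d.get("label", Path(path).stem),
        ladder=ladder,
    )
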