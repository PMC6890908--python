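"""File interchange: panel CSV round trip, config loading, report writing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import PANEL_COLUMNS, SIDE_COLUMNS, IndexPanel, frame_to_panels, panels_to_frame


def write_panels(panels: list[IndexPanel], csv_path: str | Path) -> None:
    """Panels to CSV at 12 significant digits (lossless for these magnitudes)."""
    df = panels_to_frame(panels)
    df.to_csv(csv_path, index=False, float_format="%.12g")


def read_panels(csv_path: str | Path) -> list[IndexPanel]:
    df = pd.read_csv(csv_path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"panel CSV {csv_path} is missing required column(s): {', '.join(missing)}"
        )
    numeric = [c for c in PANEL_COLUMNS + SIDE_COLUMNS if c not in ("subject_id", "label")]
    for col in numeric:
        if col in df.columns and not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"panel CSV column {col!r} contains non-numeric values")
    return frame_to_panels(df)


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
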