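"""The six-index panel: one subject's quantitative DAT-SPECT profile.

A panel holds the three intensity/shape/asymmetry index pairs computed under
the two VOI schemes: SBR-Q, PCR-Q, AI-Q (fitted striatal VOIs, occipital
reference) and SBR-V, FD-V, AI-V (pentagonal large-VOI scheme, whole-brain
reference).  Per-side SBRs are retained because the asymmetry indices are
derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

INDEX_COLUMNS = ["sbr_q", "pcr_q", "ai_q", "sbr_v", "fd_v", "ai_v"]
SIDE_COLUMNS = ["sbr_q_left", "sbr_q_right", "sbr_v_left", "sbr_v_right"]
PANEL_COLUMNS = ["subject_id", "label"] + INDEX_COLUMNS
Q_FEATURES = ["sbr_q", "pcr_q", "ai_q"]
V_FEATURES = ["sbr_v", "fd_v", "ai_v"]
LABELS = ("NPS", "PS")  # PS is the positive (disease) class


@dataclass
class IndexPanel:
    subject_id: str
    sbr_q: float
    pcr_q: float
    ai_q: float
    sbr_v: float
    fd_v: float
    ai_v: float
    sbr_q_left: float = np.nan
    sbr_q_right: float = np.nan
    sbr_v_left: float = np.nan
    sbr_v_right: float = np.nan
    label: str | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def features(self, scheme: str) -> np.ndarray:
        names = Q_FEATURES if scheme == "q" else V_FEATURES
        return np.array([getattr(self, n) for n in names], dtype=float)


def panels_to_frame(panels: list[IndexPanel]) -> pd.DataFrame:
    rows = [asdict(p) for p in panels]
    df = pd.DataFrame(rows)
    return df[PANEL_COLUMNS + SIDE_COLUMNS]


def frame_to_panels(df: pd.DataFrame) -> list[IndexPanel]:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel table is missing required column(s): {', '.join(missing)}")
    panels = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in PANEL_COLUMNS}
        for c in SIDE_COLUMNS:
            if c in df.columns:
                kwargs[c] = row[c]
        label = kwargs["label"]
        if label is None or (isinstance(label, float) and np.isnan(label)):
            kwargs["label"] = None
        panels.append(IndexPanel(**kwargs))
    return panels
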