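"""Core record type shared across the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SignalRecord", "METADATA_COLUMNS"]

# canonical metadata schema; extra columns are preserved on read
METADATA_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "region",
    "hemisphere",
    "channel_id",
    "fs_hz",
]


@dataclass
class SignalRecord:
    """One channel's voltage series plus its patient/placement metadata."""

    channel_id: str
    patient_id: str
    sex: str  # "F" or "M"
    age: float
    region: str
    hemisphere: str  # "L" or "R"
    fs: float
    data: np.ndarray

    @property
    def duration_s(self) -> float:
        return len(self.data) / self.fs
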