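"""Shared domain types for the telemetry / multistate-model pipeline.

Observation codes and latent states follow the four-state convention used
throughout the package: a bird is at STOPOVER until it departs; the departure
night it is either on an OFFSHORE flight (sea crossing) or an ONSHORE flight
(coastal detour); afterwards it has DEPARTED the study area for good.  The
receiver network observes flights imperfectly, so the observation alphabet
adds a NOT_SEEN code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TAG_TYPES = ("ACT", "NTQB")

DEFAULT_N_OCCASIONS = 36


class Code(IntEnum):
    """Observation codes of an encounter history (1-based, as written to disk)."""

    STOPOVER = 1
    OFFSHORE = 2
    ONSHORE = 3
    NOT_SEEN = 4


class State(IntEnum):
    """Latent states of the multistate model (1-based)."""

    STOPOVER = 1
    OFFSHORE = 2
    ONSHORE = 3
    DEPARTED = 4


@dataclass(frozen=True)
class DetectionRecord:
    """One receiver hit of one tag."""

    tag_id: str
    timestamp: pd.Timestamp
    receiver_id: str
    receiver_lat: float
    receiver_lon: float
    antenna_id: str
    signal_strength: float

    def __post_init__(self):
        if not -90.0 <= self.receiver_lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.receiver_lat}")
        if not -180.0 <= self.receiver_lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.receiver_lon}")


@dataclass
class Flight:
    """A continuous movement identified from the detection data."""

    tag_id: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    start_lon: float
    start_lat: float
    final_lat: float
    final_lon: float
    receiver_sequence: tuple
    distance_km: float
    route: str = "unset"  # {"offshore", "onshore", "unset"}
    species: Optional[str] = None

    def __post_init__(self):
        if self.end_time <= self.start_time:
            raise ValueError("flight end_time must be after start_time")
        if len(self.receiver_sequence) == 0:
            raise ValueError("flight needs a non-empty receiver sequence")


@dataclass
class EncounterHistory:
    """Per-individual sequence of observation codes over daily occasions.

    Valid histories start at STOPOVER and have one of two shapes: all
    STOPOVER (right-censored, the bird never departed within the study
    window) or STOPOVER up to some occasion d-1 followed by exactly one of
    {OFFSHORE, ONSHORE, NOT_SEEN} at occasion d and NOT_SEEN thereafter.
    """

    tag_id: str
    species: str
    tag_type: str
    codes: np.ndarray

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        if self.tag_type not in TAG_TYPES:
            raise ValueError(f"unknown tag type {self.tag_type!r}")
        if codes.ndim != 1 or len(codes) < 2:
            raise ValueError("codes must be a 1-d sequence of length >= 2")
        if not np.isin(codes, [1, 2, 3, 4]).all():
            raise ValueError("codes must be in {1, 2, 3, 4}")
        if codes[0] != Code.STOPOVER:
            raise ValueError("every history starts at STOPOVER")
        non_stop = np.nonzero(codes != Code.STOPOVER)[0]
        if non_stop.size:
            d = non_stop[0]
            if (codes[:d] != Code.STOPOVER).any():
                raise ValueError("STOPOVER codes must precede the departure")
            if (codes[d + 1:] != Code.NOT_SEEN).any():
                raise ValueError("codes after the departure occasion must be NOT_SEEN")

    @property
    def n_occasions(self) -> int:
        return len(self.codes)

    @property
    def departure_occasion(self) -> Optional[int]:
        """1-based occasion of the first non-STOPOVER code; None if censored."""
        non_stop = np.nonzero(self.codes != Code.STOPOVER)[0]
        if non_stop.size == 0:
            return None
        return int(non_stop[0]) + 1

    @property
    def outcome(self) -> Optional[Code]:
        """Observation code at the departure occasion; None if censored."""
        d = self.departure_occasion
        if d is None:
            return None
        return Code(self.codes[d - 1])


def histories_to_frame(histories: Sequence[EncounterHistory]) -> pd.DataFrame:
    """Serialize histories to a flat table (one row per individual)."""
    rows = []
    for h in histories:
        row = {"tag_id": h.tag_id, "species": h.species, "tag_type": h.tag_type}
        row.update({f"occ{t + 1}": int(c) for t, c in enumerate(h.codes)})
        rows.append(row)
    return pd.DataFrame(rows)


def histories_from_frame(frame: pd.DataFrame) -> list:
    occ_cols = sorted(
        (c for c in frame.columns if c.startswith("occ")), key=lambda c: int(c[3:])
    )
    out = []
    for _, row in frame.iterrows():
        out.append(
            EncounterHistory(
                tag_id=str(row["tag_id"]),
                species=str(row["species"]),
                tag_type=str(row["tag_type"]),
                codes=row[occ_cols].to_numpy(dtype=int),
            )
        )
    return out
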