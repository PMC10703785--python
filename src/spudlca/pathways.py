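"""Household storage-and-processing pathway identifiers.

A pathway couples one processing method — raw/uncooked (RW), boiled (BL),
baked (BK) or fried (FR) — with one storage condition — unstored (US),
refrigerator (FG), ideal chamber (ID) or cupboard (CP) — and a storage
duration in weeks (0, 2 or 5; the nominal "2 week" and "5 week" conditions
correspond to 17 and 33 days of storage).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["Processing", "Storage", "PathwayID", "DURATION_DAYS"]


class Processing(str, enum.Enum):
    RW = "RW"  # raw / uncooked
    BL = "BL"  # boiled
    BK = "BK"  # baked
    FR = "FR"  # fried


class Storage(str, enum.Enum):
    US = "US"  # unstored (processed at purchase)
    FG = "FG"  # refrigerator
    ID = "ID"  # ideal chamber (high humidity, ~8.9 C)
    CP = "CP"  # cupboard


#: calendar days behind each nominal duration label
DURATION_DAYS = {0: 0, 2: 17, 5: 33}


@dataclass(frozen=True, order=True)
class PathwayID:
    """One storage-and-processing pathway, e.g. ``BL-CP`` at 2 weeks."""

    processing: Processing
    storage: Storage
    duration_weeks: int = 0

    def __post_init__(self) -> None:
        proc = Processing(self.processing)
        stor = Storage(self.storage)
        object.__setattr__(self, "processing", proc)
        object.__setattr__(self, "storage", stor)
        if self.duration_weeks not in DURATION_DAYS:
            raise ValueError(
                f"duration_weeks must be one of {sorted(DURATION_DAYS)}, "
                f"got {self.duration_weeks}"
            )
        unstored = stor is Storage.US
        if unstored != (self.duration_weeks == 0):
            raise ValueError(
                "storage US requires duration 0 weeks and vice versa: "
                f"got {stor.value} at {self.duration_weeks} weeks"
            )

    @property
    def label(self) -> str:
        """Short label in the conventional form, e.g. ``"BL-CP"``."""
        return f"{self.processing.value}-{self.storage.value}"

    @property
    def storage_days(self) -> int:
        return DURATION_DAYS[self.duration_weeks]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def parse(cls, label: str, duration_weeks: int = 0) -> "PathwayID":
        """Build a pathway from its ``"<processing>-<storage>"`` label."""
        try:
            proc, stor = label.strip().split("-")
        except ValueError as exc:
            raise ValueError(f"malformed pathway label {label!r}") from exc
        return cls(Processing(proc), Storage(stor), duration_weeks)


def default_pathways(duration_weeks: int = 2) -> list[PathwayID]:
    """The ten pathways of one study arm: {RW,BL,BK,FR} x {US,FG,ID,CP}
    with US fixed at duration 0 and the stored conditions at
    ``duration_weeks``. Order is processing-major, matching the tables.
    """
    out: list[PathwayID] = []
    for proc in Processing:
        out.append(PathwayID(proc, Storage.US, 0))
        for stor in (Storage.FG, Storage.ID, Storage.CP):
            out.append(PathwayID(proc, stor, duration_weeks))
    return out
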