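"""Per-member brain-structure volume tables (TSV)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: The 15 subcortical segments plus the cerebellum.
STRUCTURES: tuple[str, ...] = (
    "left-thalamus",
    "left-caudate",
    "left-putamen",
    "left-pallidum",
    "left-hippocampus",
    "left-amygdala",
    "left-accumbens-area",
    "brain-stem",
    "right-thalamus-proper",
    "right-caudate",
    "right-putamen",
    "right-pallidum",
    "right-hippocampus",
    "right-amygdala",
    "right-accumbens-area",
    "cerebellum",
)


@dataclass
class VolumeTable:
    """member_id -> structure -> volume (mm^3); volumes must be positive."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, structs in self.rows.items():
            for name, vol in structs.items():
                if name not in STRUCTURES:
                    raise ValueError(f"unknown structure {name!r} for {mid}")
                if not vol > 0:
                    raise ValueError(f"non-positive volume {vol} for {mid}/{name}")

    @property
    def member_ids(self) -> list[str]:
        return list(self.rows)

    def structure_values(self, structure: str, member_ids=None) -> dict[str, float]:
        """Volumes of one structure for the given members (missing skipped)."""
        ids = self.rows.keys() if member_ids is None else member_ids
        out = {}
        for mid in ids:
            vol = self.rows.get(mid, {}).get(structure)
            if vol is not None:
                out[mid] = vol
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.rows, orient="index").rename_axis(
            "member_id"
        )


def read_volumes(path: str | Path) -> VolumeTable:
    df = pd.read_csv(path, sep="\t", index_col="member_id")
    rows = {
        str(mid): {k: float(v) for k, v in row.items() if pd.notna(v)}
        for mid, row in df.iterrows()
    }
    logger.info("read volumes for %d members from %s", len(rows), path)
    return VolumeTable(rows=rows)


def write_volumes(table: VolumeTable, path: str | Path) -> None:
    df = table.to_frame()
    df = df.reindex(columns=[s for s in STRUCTURES if s in df.columns])
    df.to_csv(path, sep="\t", float_format="%.2f")
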