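"""Copy-number-variant calls and BED-like TSV I/O.

Intervals are held 1-based inclusive internally (matching the variant
coordinate convention) and converted to 0-based half-open at the file
boundary, BED style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DELETION = "deletion"
DUPLICATION = "duplication"


@dataclass(frozen=True)
class CNVCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    copy_state: str
    caller: str
    member_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"CNV start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.copy_state not in (DELETION, DUPLICATION):
            raise ValueError(f"invalid copy state {self.copy_state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_cnv_calls(path: str | Path) -> list[CNVCall]:
    """Read CNV calls from a BED-like TSV (0-based half-open in file)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "start", "end", "copy_state", "caller", "member_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CNV table missing columns: {sorted(missing)}")
    calls = [
        CNVCall(
            chrom=row.chrom,
            start=int(row.start) + 1,
            end=int(row.end),
            copy_state=row.copy_state,
            caller=row.caller,
            member_id=row.member_id,
        )
        for row in df.itertuples(index=False)
    ]
    logger.info("read %d CNV calls from %s", len(calls), path)
    return calls


def write_cnv_calls(calls: list[CNVCall], path: str | Path) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start - 1,
            "end": c.end,
            "copy_state": c.copy_state,
            "caller": c.caller,
            "member_id": c.member_id,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "copy_state", "caller", "member_id"]
    ).to_csv(path, sep="\t", index=False)
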