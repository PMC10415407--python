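"""Structural checks on finished rDNA profiles.

These are the integrity checks one runs on a deposited or freshly built
profile: total length, the number and location of IUPAC-degenerate
(ribotypic) positions, and the variable locations between two profiles
under global alignment (each contiguous indel run counting as one
location).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .profilebuild import _parse_cigar
from .seqio import SeqRecord

__all__ = ["ProfileSummary", "profile_summary", "degenerate_positions",
           "variable_locations"]


@dataclass
class ProfileSummary:
    record_id: str
    length: int
    degenerate_positions: list[int]  # 1-based

    @property
    def n_degenerate(self) -> int:
        return len(self.degenerate_positions)


def degenerate_positions(record: SeqRecord) -> list[int]:
    """1-based positions carrying a non-ACGTN degenerate symbol."""
    return [i + 1 for i, s in enumerate(record.sequence) if s not in "ACGTN-"]


def profile_summary(record: SeqRecord) -> ProfileSummary:
    return ProfileSummary(record.id, len(record.sequence), degenerate_positions(record))


def variable_locations(a: SeqRecord, b: SeqRecord) -> list[int]:
    """Variable locations between two profiles under global alignment.

    Returns 1-based alignment-column positions: every mismatch column is one
    location, and each contiguous run of gap columns (an indel) is a single
    location at its first column.
    """
    res = edlib.align(a.sequence, b.sequence, mode="NW", task="path")
    out: list[int] = []
    col = 0
    prev_op = "="
    for n, op in _parse_cigar(res["cigar"]):
        if op == "X":
            out.extend(range(col + 1, col + n + 1))
        elif op in "ID":
            # one location per contiguous indel run, merging adjacent I/D
            if prev_op not in "ID":
                out.append(col + 1)
        col += n
        prev_op = op
    return out
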