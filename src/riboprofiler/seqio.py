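"""Sequence I/O and nucleotide-alphabet utilities.

Conventions used across the package:

* coordinates are 1-based and inclusive;
* ``U`` is normalized to ``T`` and lowercase to uppercase on input;
* per-base qualities are stored as error *probabilities* in ``(0, 1]``,
  converted from Phred+33 on FASTQ input (``p = 10^(-Q/10)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "MultipleAlignment",
    "VariantRecord",
    "ParseError",
    "IUPAC_CODES",
    "iupac_code",
    "iupac_expand",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "trim_to_common_length",
    "read_vcf",
    "write_vcf",
    "reverse_complement",
    "phred_to_error",
    "error_to_phred",
]

# 15 non-empty subsets of {A, C, G, T}
IUPAC_CODES: dict[frozenset, str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
_IUPAC_EXPAND = {v: set(k) for k, v in IUPAC_CODES.items()}
_VALID_SYMBOLS = set(_IUPAC_EXPAND) | {"-"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


def phred_to_error(q: float | np.ndarray) -> np.ndarray:
    """Convert Phred quality to error probability, ``10^(-Q/10)``."""
    return np.power(10.0, -np.asarray(q, dtype=float) / 10.0)


def error_to_phred(p: float | np.ndarray) -> np.ndarray:
    """Inverse of :func:`phred_to_error` (exact on integer Phred values)."""
    return -10.0 * np.log10(np.asarray(p, dtype=float))


def _normalize(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID_SYMBOLS
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)!r}")
    return seq


@dataclass
class SeqRecord:
    """A named nucleotide sequence with optional per-base error probabilities."""

    id: str
    sequence: str
    qualities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = _normalize(self.sequence)
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=float)
            if len(self.qualities) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: {len(self.qualities)} qualities for "
                    f"{len(self.sequence)} bases"
                )
            if np.any(self.qualities <= 0) or np.any(self.qualities > 1):
                raise ValueError(f"record {self.id!r}: error probabilities must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_error(self) -> float:
        """Mean per-base error probability (0.5 when qualities are absent)."""
        if self.qualities is None:
            return 0.5
        return float(np.mean(self.qualities))

    def reverse_complement(self) -> "SeqRecord":
        q = None if self.qualities is None else self.qualities[::-1].copy()
        return SeqRecord(self.id, reverse_complement(self.sequence), q)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MultipleAlignment:
    """Equal-length gapped records; columns are numbered 1-based."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        widths = {len(r.sequence) for r in self.records}
        if len(widths) != 1:
            raise ValueError(f"unequal gapped lengths: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class VariantRecord:
    """A biallelic variant on a named reference; 1-based position."""

    chrom: str
    position: int
    ref_allele: str
    alt_allele: str
    frequency: float
    p_value: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency outside [0, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# IUPAC utilities


def iupac_code(bases: Iterable[str]) -> str:
    """Degenerate symbol for a non-empty subset of {A, C, G, T}.

    ``iupac_code({'A', 'T'}) == 'W'``; singletons map to themselves.
    """
    key = frozenset(b.upper() for b in bases)
    if not key:
        raise ValueError("empty base set")
    try:
        return IUPAC_CODES[key]
    except KeyError:
        raise ValueError(f"not a subset of ACGT: {sorted(key)}") from None


def iupac_expand(symbol: str) -> set[str]:
    """Set of canonical bases denoted by one IUPAC symbol (N -> {A,C,G,T})."""
    try:
        return set(_IUPAC_EXPAND[symbol.upper()])
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide symbol: {symbol!r}") from None


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read Phred+33 FASTQ; qualities become error probabilities."""
    records: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            q = phred_to_error(np.array(rec.letter_annotations["phred_quality"]))
            records.append(SeqRecord(rec.id, str(rec.seq), q))
    except ValueError as exc:
        at = records[-1].id if records else "(first record)"
        raise ParseError(f"malformed FASTQ near record after {at!r}: {exc}") from exc
    return records


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> None:
    if not records:
        raise ValueError("refusing to write an empty FASTQ")
    bio = []
    for r in records:
        if r.qualities is None:
            raise ValueError(f"record {r.id!r} has no qualities")
        phred = np.clip(np.rint(error_to_phred(r.qualities)), 0, 93).astype(int)
        b = _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        b.letter_annotations["phred_quality"] = phred.tolist()
        bio.append(b)
    SeqIO.write(bio, str(path), "fastq")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    out = [SeqRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    if not records:
        raise ValueError("refusing to write an empty FASTA")
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Alignment trimming


def trim_to_common_length(alignment: MultipleAlignment, length: int) -> MultipleAlignment:
    """Trim an alignment to ``length`` columns.

    The maximal window covered by every record (no leading/trailing gaps) is
    located first; excess columns are then removed symmetrically, the left end
    taking the extra column when the excess is odd.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if length > alignment.width:
        raise ValueError(f"length {length} exceeds alignment width {alignment.width}")
    lo = max(len(r.sequence) - len(r.sequence.lstrip("-")) for r in alignment.records)
    hi = min(len(r.sequence.rstrip("-")) for r in alignment.records)
    covered = hi - lo
    if length > covered:
        raise ValueError(
            f"length {length} exceeds the common covered region ({covered} columns)"
        )
    excess = covered - length
    left = lo + (excess + 1) // 2
    right = left + length
    return MultipleAlignment(
        [SeqRecord(r.id, r.sequence[left:right]) for r in alignment.records]
    )


# ---------------------------------------------------------------------------
# Minimal VCF v4.2 subset (CHROM, POS, REF, ALT, INFO AF= and PV=)


def write_vcf(variants: Sequence[VariantRecord], path: str | Path) -> None:
    """Serialize variants as a minimal VCF v4.2; one ALT per line.

    Gap alleles ('-') are written verbatim; this subset is an interchange
    format between pipeline stages, not a normalized VCF for external tools.
    """
    if not variants:
        raise ValueError("refusing to write an empty VCF")
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele frequency">',
        '##INFO=<ID=PV,Number=1,Type=Float,Description="Corrected p-value">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        lines.append(
            f"{v.chrom}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t"
            f"AF={v.frequency:.6f};PV={v.p_value:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(f"short VCF line: {line!r}")
        info = dict(kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv)
        out.append(
            VariantRecord(
                chrom=fields[0],
                position=int(fields[1]),
                ref_allele=fields[3],
                alt_allele=fields[4],
                frequency=float(info.get("AF", "0")),
                p_value=float(info.get("PV", "1")),
            )
        )
    if not out:
        raise ParseError(f"no variant lines in {path}")
    return out
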