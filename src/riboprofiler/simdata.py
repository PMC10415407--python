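"""Synthetic data generators for every pipeline stage.

Three generators emulate the study conditions end to end:

* :func:`make_repeat_family` — a tandem 45S repeat family (ETS–18S–ITS1–5.8S–
  ITS2–28S) whose copies carry biallelic ribotypic loci at set minor-allele
  frequencies;
* :func:`simulate_reads` — indel-rich long reads with elevated error inside
  G homopolymers (runs of >= 3 G) and an off-target length fraction;
* :func:`simulate_plate` — triplex qPCR plates whose sigmoid curves cross a
  fixed RFU threshold at a Cq linear in log10(concentration).

All generators are pure functions of (spec, seed): the same spec and seed
always reproduce the same output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import SeqRecord, error_to_phred

__all__ = [
    "RepeatFamilySpec",
    "ReadSimSpec",
    "ChannelModel",
    "PlateSimSpec",
    "RIBOSOMAL_REGIONS",
    "default_unit_template",
    "make_repeat_family",
    "simulate_reads",
    "simulate_plate",
    "default_plate_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}

# Region lengths for a ~6.5 kb lepidopteran-like 45S cassette (18S 5' end to
# 28S 3' end as amplified by rDNA-spanning primers).
RIBOSOMAL_REGIONS: dict[str, int] = {
    "ETS": 650,
    "18S": 1900,
    "ITS1": 560,
    "5.8S": 160,
    "ITS2": 380,
    "28S": 2850,
}


def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _codes_to_seq(codes: np.ndarray) -> str:
    return codes.tobytes().decode()


@dataclass
class RepeatFamilySpec:
    """A tandem-repeat family with biallelic ribotypic loci.

    ``ribotypic_loci`` entries are ``(position, major, minor, minor_freq)``
    with 1-based positions; the major allele must equal the template base and
    minor frequencies lie in (0, 0.5].
    """

    unit_template: SeqRecord
    regions: dict[str, int]
    ribotypic_loci: list[tuple[int, str, str, float]]
    copy_number: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.regions.values()) != len(self.unit_template.sequence):
            raise ValueError("region lengths must sum to the template length")
        seen = set()
        for pos, major, minor, freq in self.ribotypic_loci:
            if not 1 <= pos <= len(self.unit_template.sequence):
                raise ValueError(f"locus position {pos} outside template")
            if pos in seen:
                raise ValueError(f"duplicate locus position {pos}")
            seen.add(pos)
            base = self.unit_template.sequence[pos - 1]
            if major != base:
                raise ValueError(f"major allele {major} != template base {base} at {pos}")
            if minor == base:
                raise ValueError(f"minor allele equals template base at {pos}")
            if not 0.0 < freq <= 0.5:
                raise ValueError("minor-allele frequency must be in (0, 0.5]")


@dataclass
class ReadSimSpec:
    """ONT-like read corruption model (at most one event per template base)."""

    substitution_rate: float = 0.03
    insertion_rate: float = 0.02
    deletion_rate: float = 0.03
    g_homopolymer_multiplier: float = 3.0
    n_reads: int = 1000
    offtarget_fraction: float = 0.0
    reverse_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if self.g_homopolymer_multiplier < 1.0:
            raise ValueError("g_homopolymer_multiplier must be >= 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.offtarget_fraction < 1.0:
            raise ValueError("offtarget_fraction must be in [0, 1)")
        if not 0.0 <= self.reverse_fraction <= 1.0:
            raise ValueError("reverse_fraction must be in [0, 1]")


def default_unit_template(seed: int = 0, regions: dict[str, int] | None = None) -> SeqRecord:
    """A random repeat-unit template with named region lengths.

    Coding regions (18S/5.8S/28S) are GC-richer than the spacers, and the
    sequence naturally contains G homopolymers that exercise the elevated
    homopolymer error model.
    """
    regions = dict(regions or RIBOSOMAL_REGIONS)
    rng = np.random.default_rng(seed)
    parts = []
    for name, length in regions.items():
        gc = 0.55 if name in ("18S", "5.8S", "28S") else 0.45
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        parts.append(rng.choice(4, size=length, p=p))
    codes = _BASES[np.concatenate(parts)]
    return SeqRecord("unit_template", _codes_to_seq(codes))


_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}


def choose_ribotypic_loci(template: SeqRecord, k: int, seed: int = 0,
                          minor_frequency: float = 0.5,
                          min_spacing: int = 200, edge_margin: int = 200
                          ) -> list[tuple[int, str, str, float]]:
    """Pick ``k`` ribotypic loci at alignment-identifiable sites.

    Sites inside or adjacent to homopolymer runs are avoided, and minor
    alleles that would extend a neighboring run are not used: homopolymer
    variation is indistinguishable from basecalling error in this kind of
    data and is classified as sequencing error downstream, so it cannot
    carry a ribotype.  Minor alleles are transversions of the template base.
    """
    rng = np.random.default_rng(seed)
    seq = template.sequence
    L = len(seq)
    candidates = []
    for p in range(edge_margin + 1, L - edge_margin):
        window = seq[p - 4:p + 3]
        if any(window[i] == window[i + 1] == window[i + 2] for i in range(len(window) - 2)):
            continue  # a run of >= 3 anywhere near the site
        base = seq[p - 1]
        minor = _COMPLEMENT_BASE[base]  # transversion for every base
        if minor in (seq[p - 2], seq[p]):
            continue  # minor allele would create a new dinucleotide run
        candidates.append((p, base, minor))
    rng.shuffle(candidates)
    chosen: list[tuple[int, str, str, float]] = []
    for p, base, minor in candidates:
        if all(abs(p - q) >= min_spacing for q, *_ in chosen):
            chosen.append((p, base, minor, minor_frequency))
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise ValueError(f"could not place {k} loci with spacing {min_spacing}")
    return sorted(chosen)


def make_repeat_family(spec: RepeatFamilySpec) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Realize repeat-unit copies and the per-locus truth table.

    Each copy equals the template except for independent Bernoulli(minor_freq)
    substitution at each ribotypic locus.  The truth table records the
    *realized* minor-allele counts, which are the recovery target downstream.
    """
    rng = np.random.default_rng(spec.seed)
    template = _seq_to_codes(spec.unit_template.sequence)
    n = spec.copy_number
    units_codes = np.tile(template, (n, 1))
    rows = []
    for pos, major, minor, freq in spec.ribotypic_loci:
        mask = rng.random(n) < freq
        units_codes[mask, pos - 1] = ord(minor)
        rows.append(
            {
                "position": pos,
                "major_allele": major,
                "minor_allele": minor,
                "nominal_frequency": freq,
                "minor_count": int(mask.sum()),
                "realized_frequency": float(mask.mean()),
            }
        )
    units = [
        SeqRecord(f"unit_{i:05d}", _codes_to_seq(units_codes[i])) for i in range(n)
    ]
    truth = pd.DataFrame(
        rows,
        columns=[
            "position",
            "major_allele",
            "minor_allele",
            "nominal_frequency",
            "minor_count",
            "realized_frequency",
        ],
    )
    return units, truth


def _g_run_mask(codes: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside runs of >= min_run consecutive G."""
    is_g = codes == ord("G")
    if not is_g.any():
        return np.zeros_like(is_g)
    # run-length encode
    edges = np.flatnonzero(np.diff(np.concatenate(([0], is_g.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    mask = np.zeros_like(is_g)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def _corrupt_read(codes: np.ndarray, spec: ReadSimSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-base sub/ins/del events; return (read codes, error probs)."""
    L = len(codes)
    total = spec.substitution_rate + spec.insertion_rate + spec.deletion_rate
    mult = np.where(_g_run_mask(codes), spec.g_homopolymer_multiplier, 1.0)
    eff = np.minimum(total * mult, 0.999)  # effective per-base event prob
    u = rng.random(L)
    event = np.full(L, 0, dtype=np.int8)  # 0 none, 1 sub, 2 ins, 3 del
    if total > 0:
        frac = eff / total
        event[u < spec.substitution_rate * frac] = 1
        lo = spec.substitution_rate * frac
        event[(u >= lo) & (u < lo + spec.insertion_rate * frac)] = 2
        lo = lo + spec.insertion_rate * frac
        event[(u >= lo) & (u < lo + spec.deletion_rate * frac)] = 3
    out = codes.copy()
    sub_idx = np.flatnonzero(event == 1)
    if len(sub_idx):
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=len(sub_idx))
        cur = np.searchsorted(_BASES, out[sub_idx])  # codes are sorted ACGT
        out[sub_idx] = _BASES[(cur + shift) % 4]
    keep = event != 3
    ins_after = event == 2
    # build with insertions: each kept base emits itself (+ random base if ins)
    n_ins = int(ins_after.sum())
    counts = keep.astype(np.int64) + ins_after
    positions = np.repeat(np.arange(L), counts)
    read = out[positions]
    errs = eff[positions]
    if n_ins:
        # the second emission of an insertion-carrying base is the random base
        first_of = np.concatenate(([0], np.cumsum(counts)[:-1]))
        ins_slots = first_of[ins_after] + keep[ins_after].astype(np.int64)
        read = read.copy()
        read[ins_slots] = _BASES[rng.integers(0, 4, size=n_ins)]
        errs[ins_slots] = min(total, 0.999) if total > 0 else 1e-4
    if len(read) == 0:
        read = np.array([codes[0]], dtype=np.uint8)
        errs = np.array([min(max(total, 1e-4), 0.999)])
    errs = np.clip(errs, 1e-6, 0.999)
    return read, errs


def simulate_reads(units: list[SeqRecord], spec: ReadSimSpec
                   ) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate noisy long reads from repeat-unit copies.

    Returns the reads and a truth table (read_id, source_unit, is_offtarget,
    is_reverse).  Off-target reads are random sequences with lengths outside
    the amplicon window, drawn uniformly from [200, 3000] or [9000, 12000].
    """
    if not units:
        raise ValueError("units must be non-empty")
    if spec.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(spec.seed)
    unit_codes = [_seq_to_codes(u.sequence) for u in units]
    reads: list[SeqRecord] = []
    rows = []
    is_off = rng.random(spec.n_reads) < spec.offtarget_fraction
    src = rng.integers(0, len(units), size=spec.n_reads)
    is_rev = rng.random(spec.n_reads) < spec.reverse_fraction
    base_err = spec.substitution_rate + spec.insertion_rate + spec.deletion_rate
    for i in range(spec.n_reads):
        rid = f"read_{i:06d}"
        if is_off[i]:
            if rng.random() < 0.5:
                length = int(rng.integers(200, 3001))
            else:
                length = int(rng.integers(9000, 12001))
            codes = _BASES[rng.integers(0, 4, size=length)]
            errs = np.full(length, max(base_err, 1e-3))
            rows.append({"read_id": rid, "source_unit": -1,
                         "is_offtarget": True, "is_reverse": False})
        else:
            codes, errs = _corrupt_read(unit_codes[src[i]], spec, rng)
            if is_rev[i]:
                codes = _seq_to_codes(
                    SeqRecord("t", _codes_to_seq(codes)).reverse_complement().sequence
                )
                errs = errs[::-1]
            rows.append({"read_id": rid, "source_unit": int(src[i]),
                         "is_offtarget": False, "is_reverse": bool(is_rev[i])})
        reads.append(SeqRecord(rid, _codes_to_seq(codes), errs))
    truth = pd.DataFrame(rows)
    return reads, truth


def evaluate_recovered_ribotypes(profile_sequence: str, template: SeqRecord,
                                 loci: list[tuple[int, str, str, float]],
                                 tolerance: int = 5) -> tuple[int, int]:
    """Score a recovered profile against planted ribotypic loci.

    Aligns the profile to the template (better orientation wins), then
    matches each degenerate site to a planted locus within ``tolerance``
    template positions, requiring the expanded alleles to equal the locus
    alleles (complemented for reverse-orientation profiles).  Returns
    ``(n_loci_recovered, n_spurious_sites)``.
    """
    import edlib

    from .profilebuild import map_positions
    from .seqio import iupac_expand

    prof = SeqRecord("profile", profile_sequence)
    fwd = edlib.align(prof.sequence, template.sequence, mode="NW")["editDistance"]
    rev = edlib.align(prof.reverse_complement().sequence, template.sequence,
                      mode="NW")["editDistance"]
    reverse = rev < fwd
    pm = map_positions(prof, template, try_reverse=True)
    # map_positions keys are original profile coordinates in either
    # orientation; only the symbol needs complementing for reverse matches
    sites = [(i + 1, _COMPLEMENT_IUPAC.get(s, s) if reverse else s)
             for i, s in enumerate(prof.sequence) if s not in "ACGTN-"]
    matched: set[int] = set()
    spurious = 0
    for p, s in sites:
        tpos = pm.get(p)
        if tpos is None:
            for d in range(1, tolerance + 1):
                if pm.get(p - d):
                    tpos = pm[p - d] + d
                    break
                if pm.get(p + d):
                    tpos = pm[p + d] - d
                    break
        hit = None
        for lp, major, minor, _ in loci:
            if tpos is not None and abs(tpos - lp) <= tolerance \
                    and iupac_expand(s) == {major, minor} and lp not in matched:
                hit = lp
                break
        if hit is None:
            spurious += 1
        else:
            matched.add(hit)
    return len(matched), spurious


_COMPLEMENT_IUPAC = {
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


# ---------------------------------------------------------------------------
# qPCR plate simulation


@dataclass
class ChannelModel:
    """Sigmoid amplification model for one fluorophore channel.

    The threshold crossing of a detectable well lands at
    ``Cq = cq_intercept + cq_slope * log10(concentration)``; wells below
    ``lod_ng_per_ul`` never amplify (detection floor).
    """

    name: str
    baseline_rfu: float = 100.0
    plateau_rfu: float = 4000.0
    slope: float = 0.6  # sigmoid steepness per cycle
    cq_intercept: float = 20.0
    cq_slope: float = -3.32
    lod_ng_per_ul: float = 1e-4

    def __post_init__(self) -> None:
        if self.plateau_rfu <= self.baseline_rfu:
            raise ValueError("plateau must exceed baseline")


# which true classes each channel responds to
_CHANNEL_TARGETS = {
    "FAM": {"includens"},
    "HEX": {"chalcites_or_eriosoma"},
    "Q670_control": {"includens", "chalcites_or_eriosoma", "nontarget"},
}
TRUE_CLASSES = ("includens", "chalcites_or_eriosoma", "nontarget", "blank")


@dataclass
class PlateSimSpec:
    """A plate of wells with true classes and DNA concentrations."""

    wells: list[tuple[str, str, float]]  # (sample, true class, ng/uL)
    channels: list[ChannelModel] = field(default_factory=lambda: [
        ChannelModel("FAM", cq_intercept=19.1, lod_ng_per_ul=1e-3),
        ChannelModel("HEX", cq_intercept=20.15, lod_ng_per_ul=1e-4),
        ChannelModel("Q670_control", cq_intercept=21.2, lod_ng_per_ul=1e-4),
    ])
    threshold_rfu: float = 1000.0
    noise_sd: float = 20.0
    cycles: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        for _, cls, _ in self.wells:
            if cls not in TRUE_CLASSES:
                raise ValueError(f"unknown class {cls!r}")


def default_plate_spec(seed: int = 0) -> PlateSimSpec:
    """A 32-well demonstration plate: 10+10 targets, 10 non-targets, 2 blanks."""
    wells = (
        [(f"inc_{i:02d}", "includens", 5.0) for i in range(10)]
        + [(f"cha_{i:02d}", "chalcites_or_eriosoma", 5.0) for i in range(10)]
        + [(f"non_{i:02d}", "nontarget", 5.0) for i in range(10)]
        + [("blank_00", "blank", 0.0), ("blank_01", "blank", 0.0)]
    )
    return PlateSimSpec(wells=wells, seed=seed)


def simulate_plate(spec: PlateSimSpec) -> pd.DataFrame:
    """Per-well, per-channel RFU-by-cycle table (columns: well, sample,
    channel, cycle, rfu)."""
    rng = np.random.default_rng(spec.seed)
    cycles = np.arange(1, spec.cycles + 1, dtype=float)
    frames = []
    for w, (sample, cls, conc) in enumerate(spec.wells):
        well = f"W{w + 1:03d}"
        for ch in spec.channels:
            detect = (
                cls in _CHANNEL_TARGETS[ch.name]
                and conc >= ch.lod_ng_per_ul
                and conc > 0
            )
            if detect:
                cq = ch.cq_intercept + ch.cq_slope * math.log10(conc)
                amp = ch.plateau_rfu - ch.baseline_rfu
                # place the sigmoid midpoint so the curve crosses the RFU
                # threshold exactly at the intended Cq
                mid = cq + math.log(amp / (spec.threshold_rfu - ch.baseline_rfu) - 1.0) / ch.slope
                rfu = ch.baseline_rfu + amp / (1.0 + np.exp(-ch.slope * (cycles - mid)))
            else:
                rfu = np.full_like(cycles, ch.baseline_rfu)
            rfu = rfu + rng.normal(0.0, spec.noise_sd, size=len(cycles))
            frames.append(
                pd.DataFrame(
                    {
                        "well": well,
                        "sample": sample,
                        "channel": ch.name,
                        "cycle": cycles.astype(int),
                        "rfu": rfu,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
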