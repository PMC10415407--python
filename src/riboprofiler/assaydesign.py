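"""Ribotype-aware real-time PCR oligo design.

Diagnostic windows are regions where a target profile differs from every
contrast profile while containing no intragenomic ribotypic (IUPAC
degenerate) position in *any* input profile — probe/primer binding over a
ribotypic site would split the template population and degrade the assay.

Melting temperatures come in two flavours used side by side at the bench:

* :func:`tm_nearest_neighbor` — duplex nearest-neighbor thermodynamics
  (unified 1998 parameter set) with entropy salt correction
  ``0.368 (N-1) ln[Na+]`` and divalent cations folded into an effective
  monovalent concentration ``Na+ + 120 sqrt(Mg2+ - dNTP)`` (all mM);
* :func:`tm_salt_adjusted` — the composition-only salt-adjusted formula
  ``100.5 + 41 (G+C)/N - 820/N + 16.6 log10[Na+]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import SeqRecord, reverse_complement

__all__ = [
    "TmParams",
    "DiagnosticWindow",
    "OligoCandidate",
    "OligoConstraints",
    "SpecificityHit",
    "scan_windows",
    "tm_nearest_neighbor",
    "tm_salt_adjusted",
    "generate_oligos",
    "screen_specificity",
    "gc_fraction",
]

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/mol/K),
# 5'->3' top strand stacks; complementary stacks share the same values.
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# terminal initiation terms
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)


@dataclass
class TmParams:
    """Reaction conditions for nearest-neighbor Tm (all concentrations as
    stated on the instrument protocol: mM for salts, nM for the oligo)."""

    monovalent_mM: float = 50.0
    divalent_mM: float = 3.8
    dNTP_mM: float = 0.8
    oligo_nM: float = 50.0

    def __post_init__(self) -> None:
        if min(self.monovalent_mM, self.divalent_mM, self.dNTP_mM, self.oligo_nM) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.divalent_mM < self.dNTP_mM:
            raise ValueError("divalent_mM must be >= dNTP_mM (dNTPs chelate Mg2+)")

    @property
    def effective_monovalent_mM(self) -> float:
        return self.monovalent_mM + 120.0 * math.sqrt(self.divalent_mM - self.dNTP_mM)


@dataclass
class DiagnosticWindow:
    region: str
    start: int  # 1-based inclusive on the shared profile frame
    end: int
    difference_count: int
    contains_ribotype: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")


@dataclass
class OligoCandidate:
    role: str  # forward | reverse | probe
    sequence: str
    position: int  # 1-based start on the profile frame
    strand: str  # + | -
    tm_nn: float
    tm_salt_adjusted: float
    gc_fraction: float
    dye: str | None = None  # metadata only (FAM/ZEN, HEX, Quasar 670 ...)


@dataclass
class OligoConstraints:
    min_length: int = 18
    max_length: int = 26
    tm_range: tuple[float, float] = (55.0, 65.0)
    gc_range: tuple[float, float] = (0.30, 0.70)
    target_tm: float = 60.0
    probe_no_5prime_g: bool = True
    max_amplicon: int = 400
    min_amplicon: int = 50


@dataclass
class SpecificityHit:
    nontarget_id: str
    strand: str
    amplicon_start: int  # 0-based on the non-target sequence
    amplicon_end: int
    mismatches: tuple[int, int, int]  # forward, probe, reverse


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _check_canonical(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"degenerate or non-canonical bases not allowed: {sorted(bad)}")


def tm_nearest_neighbor(sequence: str, params: TmParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in degrees C.

    ``Tm = 1000 dH / (dS + 0.368 (N-1) ln[Na+_eff] + R ln(C_T / 4)) - 273.15``
    with dH in kcal/mol, dS in cal/mol/K, Na+_eff in M and C_T the oligo
    concentration.
    """
    params = params or TmParams()
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError("sequence too short for nearest-neighbor Tm (need >= 6)")
    _check_canonical(seq)
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    na_eff = params.effective_monovalent_mM / 1000.0
    ds_corr = ds + 0.368 * (len(seq) - 1) * math.log(na_eff)
    ct = params.oligo_nM * 1e-9
    return 1000.0 * dh / (ds_corr + R_GAS * math.log(ct / 4.0)) - 273.15


def tm_salt_adjusted(sequence: str, monovalent_M: float = 0.05) -> float:
    """Composition-only salt-adjusted Tm in degrees C (length >= 8)."""
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError("sequence too short (need >= 8)")
    _check_canonical(seq)
    n = len(seq)
    gc = seq.count("G") + seq.count("C")
    return 100.5 + 41.0 * gc / n - 820.0 / n + 16.6 * math.log10(monovalent_M)


# ---------------------------------------------------------------------------
# Window scanning


def _degenerate_positions(profiles: list[SeqRecord]) -> set[int]:
    out: set[int] = set()
    for p in profiles:
        for i, s in enumerate(p.sequence):
            if s not in "ACGTN-":
                out.add(i + 1)
    return out


def scan_windows(target_profile: SeqRecord, contrast_profiles: list[SeqRecord],
                 window_len: int, min_diffs: int = 1,
                 regions: dict[str, tuple[int, int]] | None = None
                 ) -> list[DiagnosticWindow]:
    """Sliding diagnostic windows ranked by between-group difference count.

    Profiles must share a common frame.  A column counts as a difference
    when the target symbol differs from *every* contrast profile's symbol.
    Windows overlapping a degenerate (ribotypic) position in any profile are
    excluded; ties rank leftmost first.
    """
    L = len(target_profile.sequence)
    if window_len > L:
        raise ValueError("window_len exceeds profile length")
    for c in contrast_profiles:
        if len(c.sequence) != L:
            raise ValueError("profiles are not on a common frame")
    degen = _degenerate_positions([target_profile] + contrast_profiles)
    is_diff = np.ones(L, dtype=bool)
    tarr = np.frombuffer(target_profile.sequence.encode(), dtype=np.uint8)
    for c in contrast_profiles:
        carr = np.frombuffer(c.sequence.encode(), dtype=np.uint8)
        is_diff &= tarr != carr
    diff_cum = np.concatenate(([0], np.cumsum(is_diff)))
    degen_mask = np.zeros(L, dtype=bool)
    for p in degen:
        degen_mask[p - 1] = True
    degen_cum = np.concatenate(([0], np.cumsum(degen_mask)))
    windows = []
    for start in range(L - window_len + 1):
        end = start + window_len
        n_degen = degen_cum[end] - degen_cum[start]
        n_diff = int(diff_cum[end] - diff_cum[start])
        if n_diff < min_diffs:
            continue
        if n_degen > 0:
            continue
        name = _region_of(start + window_len // 2 + 1, regions)
        windows.append(DiagnosticWindow(name, start + 1, end, n_diff, False))
    windows.sort(key=lambda w: (-w.difference_count, w.start))
    return windows


def _region_of(position: int, regions: dict[str, tuple[int, int]] | None) -> str:
    if regions:
        for name, (s, e) in regions.items():
            if s <= position <= e:
                return name
    return "unassigned"


# ---------------------------------------------------------------------------
# Oligo generation


def generate_oligos(window: DiagnosticWindow, profile: SeqRecord,
                    constraints: OligoConstraints | None = None,
                    params: TmParams | None = None) -> list[OligoCandidate]:
    """Enumerate primer/probe candidates inside a diagnostic window.

    Forward candidates start in the left third of the window, reverse
    candidates end in the right third (reverse-complemented), probes sit
    anywhere; all satisfy the length / Tm / GC constraints (and no 5' G for
    probes).  Candidates are sorted by |Tm - target Tm|.  An empty result
    means no oligo satisfied the constraints.
    """
    constraints = constraints or OligoConstraints()
    params = params or TmParams()
    if window.contains_ribotype:
        raise ValueError("window overlaps a ribotypic site")
    wseq = profile.sequence[window.start - 1:window.end]
    span = len(wseq)
    if span < constraints.min_amplicon:
        return []
    third = max(span // 3, constraints.min_length)
    out: list[OligoCandidate] = []
    for length in range(constraints.min_length, constraints.max_length + 1):
        for off in range(0, span - length + 1):
            sub = wseq[off:off + length]
            if set(sub) - set("ACGT"):
                continue
            gc = gc_fraction(sub)
            if not constraints.gc_range[0] <= gc <= constraints.gc_range[1]:
                continue
            tm = tm_nearest_neighbor(sub, params)
            if not constraints.tm_range[0] <= tm <= constraints.tm_range[1]:
                continue
            tsa = tm_salt_adjusted(sub, params.monovalent_mM / 1000.0)
            pos = window.start + off
            if off + length <= third:
                out.append(OligoCandidate("forward", sub, pos, "+", tm, tsa, gc))
            if off >= span - third:
                rc = reverse_complement(sub)
                out.append(OligoCandidate(
                    "reverse", rc, pos, "-", tm_nearest_neighbor(rc, params),
                    tm_salt_adjusted(rc, params.monovalent_mM / 1000.0),
                    gc_fraction(rc)))
            probe_ok = sub[0] != "G" if constraints.probe_no_5prime_g else True
            if probe_ok:
                out.append(OligoCandidate("probe", sub, pos, "+", tm, tsa, gc))
    out.sort(key=lambda c: (abs(c.tm_nn - constraints.target_tm), c.position, c.role))
    return out


# ---------------------------------------------------------------------------
# Specificity screening


def _mismatch_profile(oligo: str, target: str) -> np.ndarray:
    """Mismatch count of the oligo at every start position of the target."""
    L, n = len(target), len(oligo)
    if L < n:
        return np.empty(0, dtype=np.int64)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    o = np.frombuffer(oligo.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, n)
    return (windows != o).sum(axis=1)


def screen_specificity(oligo_set: tuple[str, str, str],
                       nontargets: list[SeqRecord],
                       max_mismatches: int = 2,
                       max_amplicon: int = 400) -> list[SpecificityHit]:
    """Predict cross-reactions of a (forward, probe, reverse) oligo set.

    A non-target is flagged when all three oligos bind with at most
    ``max_mismatches`` mismatches in amplifiable orientation and spacing
    (forward then reverse-complement site downstream, amplicon <=
    ``max_amplicon``; probe annealing to either strand inside the
    amplicon).  An empty result is a clean screen.
    """
    if not nontargets:
        raise ValueError("non-target set must be non-empty")
    fwd, probe, rev = (s.upper() for s in oligo_set)
    hits: list[SpecificityHit] = []
    for rec in nontargets:
        for strand, seq in (("+", rec.sequence), ("-", reverse_complement(rec.sequence))):
            f_mm = _mismatch_profile(fwd, seq)
            r_site = reverse_complement(rev)
            r_mm = _mismatch_profile(r_site, seq)
            p_mm_top = _mismatch_profile(probe, seq)
            p_mm_bot = _mismatch_profile(reverse_complement(probe), seq)
            f_pos = np.flatnonzero(f_mm <= max_mismatches)
            r_pos = np.flatnonzero(r_mm <= max_mismatches)
            if not len(f_pos) or not len(r_pos):
                continue
            p_pos = np.flatnonzero(
                np.minimum.reduce([
                    p_mm_top if len(p_mm_top) else np.full(1, 99),
                    p_mm_bot if len(p_mm_bot) else np.full(1, 99),
                ]) <= max_mismatches
            ) if len(p_mm_top) and len(p_mm_bot) else np.empty(0, dtype=int)
            for fp in f_pos:
                for rp in r_pos:
                    amp_start, amp_end = int(fp), int(rp) + len(rev)
                    if amp_end <= amp_start:
                        continue
                    if amp_end - amp_start > max_amplicon:
                        continue
                    inside = p_pos[(p_pos >= amp_start) & (p_pos + len(probe) <= amp_end)]
                    if not len(inside):
                        continue
                    pi = int(inside[0])
                    hits.append(SpecificityHit(
                        nontarget_id=rec.id,
                        strand=strand,
                        amplicon_start=amp_start,
                        amplicon_end=amp_end,
                        mismatches=(int(f_mm[fp]),
                                    int(min(p_mm_top[pi] if pi < len(p_mm_top) else 99,
                                            p_mm_bot[pi] if pi < len(p_mm_bot) else 99)),
                                    int(r_mm[rp])),
                    ))
                    break
    return hits
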