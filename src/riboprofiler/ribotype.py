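"""Statistical confirmation and classification of intragenomic rDNA variants.

The caller tests, at every sufficiently covered reference position, the null
hypothesis that all non-major observations are sequencing errors.  The
p-value is the exact Poisson-binomial tail probability of observing at least
``k`` minor-allele reads given each read's own per-base error probability,
with Bonferroni correction across tested positions.  Confirmed variants are
classified as sequencing error (gap/N alleles), transient (below the fixed
threshold), or fixed ribotypes (canonical biallelic, minor frequency >= 0.25),
and fixed ribotypes are written into the profile as IUPAC degenerate bases.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .profilebuild import ConsensusProfile, PairwiseAlignment, SYMBOLS, _SYM_INDEX, _parse_cigar
from .seqio import SeqRecord, VariantRecord, iupac_code, iupac_expand

__all__ = [
    "Pileup",
    "RibotypeCall",
    "RibotypeProfile",
    "ClassificationRules",
    "build_pileup",
    "poisson_binomial_tail",
    "call_variants",
    "classify_call",
    "classify_calls",
    "flag_for_verification",
    "apply_ribotypes",
    "enumerate_combinations",
]

logger = logging.getLogger(__name__)

_GAP = 4


@dataclass
class Pileup:
    """Per-position read observations in CSR-like layout.

    ``offsets[i]:offsets[i+1]`` slices ``base_codes``/``error_probs`` for
    reference position ``i`` (0-based internally).  ``counts`` tallies
    symbols per position.  Insertions relative to the reference are excluded
    from positional tallies and reported in ``insertion_count``.
    """

    reference_id: str
    length: int
    counts: np.ndarray  # (L, 6)
    offsets: np.ndarray  # (L + 1,)
    base_codes: np.ndarray  # int8 per observation
    error_probs: np.ndarray  # float per observation
    insertion_count: int = 0

    def depth(self, position: int) -> int:
        """Depth at a 1-based position."""
        i = position - 1
        return int(self.offsets[i + 1] - self.offsets[i])

    def observations(self, position: int) -> tuple[np.ndarray, np.ndarray]:
        """(base codes, error probs) at a 1-based position."""
        i = position - 1
        sl = slice(self.offsets[i], self.offsets[i + 1])
        return self.base_codes[sl], self.error_probs[sl]


@dataclass
class RibotypeCall:
    position: int  # 1-based
    major_allele: str
    minor_allele: str
    minor_frequency: float
    p_value: float
    classification: str  # sequencing_error | transient | fixed_ribotype
    flagged_for_verification: bool = False


@dataclass
class RibotypeProfile:
    """A consensus profile whose degenerate symbols are exactly the fixed
    ribotype calls."""

    profile: ConsensusProfile
    calls: list[RibotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_fixed = sum(c.classification == "fixed_ribotype" for c in self.calls)
        n_degenerate = sum(s not in "ACGTN-" for s in self.profile.sequence)
        if n_fixed != n_degenerate:
            raise ValueError(
                f"{n_degenerate} degenerate symbols for {n_fixed} fixed ribotype calls"
            )

    @property
    def sequence(self) -> str:
        return self.profile.sequence


@dataclass
class ClassificationRules:
    min_fixed_frequency: float = 0.25
    verification_threshold: float = 0.5


def build_pileup(alignments: list[PairwiseAlignment], reference: SeqRecord) -> Pileup:
    """Tally every aligned read base (and gap) onto reference positions.

    Gap observations carry the read's mean error probability (a deleted base
    has no base quality of its own).
    """
    L = len(reference.sequence)
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    err_chunks: list[np.ndarray] = []
    n_insertions = 0
    for aln in alignments:
        ra = np.frombuffer(aln.aligned_read.encode(), dtype=np.uint8)
        rr = np.frombuffer(aln.aligned_ref.encode(), dtype=np.uint8)
        n_read_bases = int((ra != ord("-")).sum())
        q = aln.read_qualities
        if q is None:
            q = np.full(n_read_bases, 0.5)
        q = np.asarray(q, dtype=np.float64)
        mean_err = float(np.mean(q)) if len(q) else 0.5
        # quantize to the integer-Phred grid so grouped convolution stays fast
        mean_err = float(10.0 ** (-round(-10.0 * np.log10(mean_err)) / 10.0))
        ref_cols = rr != ord("-")
        n_insertions += int((~ref_cols).sum())
        ra_ref = ra[ref_cols]
        codes = _BASE_LOOKUP[ra_ref]
        # per-column error prob: the read base's own quality, or the read
        # mean for deletion (gap) observations
        read_index = np.cumsum(ra != ord("-")) - 1
        errs_cols = np.where(ra_ref == ord("-"), mean_err,
                             q[np.clip(read_index[ref_cols], 0, max(n_read_bases - 1, 0))])
        pos_chunks.append(np.arange(int(ref_cols.sum()), dtype=np.int64))
        code_chunks.append(codes)
        err_chunks.append(errs_cols)
    if pos_chunks:
        positions = np.concatenate(pos_chunks)
        codes = np.concatenate(code_chunks)
        errs = np.concatenate(err_chunks)
    else:
        positions = np.empty(0, dtype=np.int64)
        codes = np.empty(0, dtype=np.int64)
        errs = np.empty(0, dtype=np.float64)
    order = np.argsort(positions, kind="stable")
    positions, codes, errs = positions[order], codes[order], errs[order]
    counts = np.zeros((L, len(SYMBOLS)), dtype=np.int64)
    np.add.at(counts, (positions, codes), 1)
    offsets = np.zeros(L + 1, dtype=np.int64)
    np.cumsum(np.bincount(positions, minlength=L), out=offsets[1:])
    return Pileup(
        reference_id=reference.id,
        length=L,
        counts=counts,
        offsets=offsets,
        base_codes=codes.astype(np.int8),
        error_probs=errs,
        insertion_count=n_insertions,
    )


_BASE_LOOKUP = np.zeros(256, dtype=np.int64)
for _s, _i in _SYM_INDEX.items():
    _BASE_LOOKUP[ord(_s)] = _i


def poisson_binomial_tail(error_probs: np.ndarray, k: int) -> float:
    """Exact ``P(X >= k)`` for ``X = sum of independent Bernoulli(p_i)``.

    Computed as ``1 - P(X <= k-1)`` via a truncated convolution: reads with
    identical error probability are grouped (Phred values are discrete) and
    the group binomial PMFs are convolved keeping only counts ``< k`` — the
    dynamic-programming convolution of the Poisson-binomial distribution,
    evaluated exactly.
    """
    if k <= 0:
        return 1.0
    p = np.asarray(error_probs, dtype=float)
    if k > len(p):
        return 0.0
    vals, cnts = np.unique(np.round(p, 12), return_counts=True)
    pmf = np.zeros(k)
    pmf[0] = 1.0
    support = np.arange(k)
    for v, c in zip(vals, cnts):
        g = stats.binom.pmf(support, c, v)
        pmf = np.convolve(pmf, g)[:k]
    return float(max(0.0, min(1.0, 1.0 - pmf.sum())))


def call_variants(pileup: Pileup, alpha: float = 0.05,
                  min_frequency: float = 0.005, min_depth: int = 10
                  ) -> list[VariantRecord]:
    """Confirm minor alleles against the all-errors null.

    Positions with depth below ``min_depth`` are skipped (and logged).  The
    Bonferroni correction count is the number of tested (depth-qualified)
    positions.  Emitted records have corrected ``p <= alpha`` and minor
    frequency >= ``min_frequency``; each minor allele is a separate record.
    """
    depths = pileup.offsets[1:] - pileup.offsets[:-1]
    tested = np.flatnonzero(depths >= min_depth)
    n_skipped = pileup.length - len(tested)
    if n_skipped:
        logger.info("skipping %d positions with depth < %d", n_skipped, min_depth)
    m = len(tested)
    out: list[VariantRecord] = []
    for i in tested:
        row = pileup.counts[i, :5]
        depth = int(row.sum())
        major = int(np.argmax(row))
        codes, errs = pileup.observations(i + 1)
        for allele in range(5):
            if allele == major:
                continue
            k = int(row[allele])
            if k == 0:
                continue
            freq = k / depth
            if freq < min_frequency:
                continue
            p_raw = poisson_binomial_tail(errs, k)
            p_corr = min(1.0, p_raw * m)
            if p_corr <= alpha:
                out.append(
                    VariantRecord(
                        chrom=pileup.reference_id,
                        position=int(i) + 1,
                        ref_allele=SYMBOLS[major],
                        alt_allele=SYMBOLS[allele],
                        frequency=freq,
                        p_value=p_corr,
                    )
                )
    return out


def classify_call(variant: VariantRecord,
                  rules: ClassificationRules | None = None) -> RibotypeCall:
    """Classify one confirmed variant.

    fixed_ribotype: both alleles canonical and minor frequency >= 0.25;
    sequencing_error: gap or N allele (indel ambiguity is treated as error);
    transient: everything else.
    """
    rules = rules or ClassificationRules()
    major, minor = variant.ref_allele, variant.alt_allele
    canonical = major in "ACGT" and minor in "ACGT"
    if not canonical:
        cls = "sequencing_error"
    elif variant.frequency >= rules.min_fixed_frequency:
        cls = "fixed_ribotype"
    else:
        cls = "transient"
    return RibotypeCall(
        position=variant.position,
        major_allele=major,
        minor_allele=minor,
        minor_frequency=variant.frequency,
        p_value=variant.p_value,
        classification=cls,
    )


def _touches_homopolymer(reference: str, position: int, alleles: set[str],
                         min_run: int = 3) -> bool:
    """True when an allele matches a homopolymer run (>= min_run) that the
    site overlaps or borders.

    Apparent base splits at run boundaries are alignment-path artifacts of
    elevated in-run error (the G-string basecalling problem): when a run is
    mis-sized, reads divide between a mismatch column and an indel path,
    manufacturing a ~50/50 canonical split that no Sanger trace would
    confirm.
    """
    i = position - 1
    lo, hi = max(i - min_run - 1, 0), min(i + min_run + 2, len(reference))
    seg = reference[lo:hi]
    run_start = 0
    for k in range(1, len(seg) + 1):
        if k == len(seg) or seg[k] != seg[run_start]:
            run_len = k - run_start
            base = seg[run_start]
            if run_len >= min_run and base in alleles:
                a, b = lo + run_start, lo + k - 1  # run span, 0-based
                if a - 1 <= i <= b + 1:
                    return True
            run_start = k
    return False


def classify_calls(variants: list[VariantRecord],
                   rules: ClassificationRules | None = None,
                   reference: SeqRecord | None = None) -> list[RibotypeCall]:
    """Classify variants with the biallelic constraint enforced per site.

    A site with more than two canonical alleles above the caller's frequency
    floor is demoted to transient with a warning.  When the reference is
    supplied, canonical splits touching a homopolymer run of the same base
    are demoted to sequencing error (run-boundary alignment artifacts).
    """
    rules = rules or ClassificationRules()
    calls = [classify_call(v, rules) for v in variants]
    by_pos: dict[int, list[RibotypeCall]] = {}
    for c in calls:
        by_pos.setdefault(c.position, []).append(c)
    for pos, group in by_pos.items():
        alleles = {g.major_allele for g in group} | {g.minor_allele for g in group}
        if len(alleles & set("ACGT")) > 2:
            warnings.warn(
                f"position {pos}: more than two canonical alleles; demoted to transient",
                stacklevel=2,
            )
            for g in group:
                if g.classification == "fixed_ribotype":
                    g.classification = "transient"
    if reference is not None:
        for c in calls:
            if c.classification == "fixed_ribotype" and _touches_homopolymer(
                    reference.sequence, c.position,
                    {c.major_allele, c.minor_allele}):
                c.classification = "sequencing_error"
    # adjacent fixed calls are one site torn across two alignment columns:
    # keep the strongest, demote the rest
    fixed_sorted = sorted((c for c in calls if c.classification == "fixed_ribotype"),
                          key=lambda c: c.position)
    cluster: list[RibotypeCall] = []
    for c in fixed_sorted + [None]:  # type: ignore[list-item]
        if c is not None and (not cluster or c.position - cluster[-1].position <= 1):
            cluster.append(c)
            continue
        if len(cluster) > 1:
            keep = max(cluster, key=lambda x: x.minor_frequency)
            for other in cluster:
                if other is not keep:
                    other.classification = "sequencing_error"
            warnings.warn(
                f"adjacent fixed calls near position {keep.position} collapsed "
                "to the strongest (alignment tearing)", stacklevel=2)
        cluster = [c] if c is not None else []
    return calls


def flag_for_verification(calls: list[RibotypeCall],
                          threshold: float = 0.5) -> list[RibotypeCall]:
    """Flag calls whose variant (non-reference) frequency reaches the Sanger
    verification threshold; order is preserved."""
    for c in calls:
        c.flagged_for_verification = c.minor_frequency >= threshold
    return calls


def apply_ribotypes(profile: ConsensusProfile, calls: list[RibotypeCall],
                    confirmed_mask: list[bool] | None = None) -> RibotypeProfile:
    """Write IUPAC degenerate symbols at fixed-ribotype positions.

    ``confirmed_mask`` optionally restricts the fixed calls to those confirmed
    externally (e.g. by Sanger electropherograms); unconfirmed fixed calls are
    demoted to transient in the returned profile.
    """
    fixed = [c for c in calls if c.classification == "fixed_ribotype"]
    if confirmed_mask is not None:
        if len(confirmed_mask) != len(fixed):
            raise ValueError("confirmed_mask length must equal number of fixed calls")
        demoted = {id(c) for c, ok in zip(fixed, confirmed_mask) if not ok}
    else:
        demoted = set()
    seq = list(profile.sequence)
    kept_calls: list[RibotypeCall] = []
    confirmed_positions: set[int] = set()
    for c in calls:
        if c.classification == "fixed_ribotype" and id(c) not in demoted:
            if not 1 <= c.position <= len(seq):
                raise ValueError(f"call position {c.position} outside profile")
            pair_code = iupac_code({c.major_allele, c.minor_allele})
            base = seq[c.position - 1]
            if base not in (c.major_allele, c.minor_allele, pair_code):
                raise ValueError(
                    f"frame mismatch at {c.position}: consensus {base}, "
                    f"alleles {c.major_allele}/{c.minor_allele}"
                )
            seq[c.position - 1] = pair_code
            confirmed_positions.add(c.position)
            kept_calls.append(c)
        else:
            kept_calls.append(
                RibotypeCall(
                    c.position, c.major_allele, c.minor_allele, c.minor_frequency,
                    c.p_value,
                    "transient" if id(c) in demoted else c.classification,
                    c.flagged_for_verification,
                )
            )
    # candidate (merge-stage) degenerate symbols that were not confirmed as
    # fixed ribotypes resolve back to the majority canonical base
    for i, s in enumerate(seq):
        if s not in "ACGTN-" and (i + 1) not in confirmed_positions:
            row = profile.counts[i, :4]
            seq[i] = "ACGT"[int(np.argmax(row))] if row.sum() else "N"
    new_profile = ConsensusProfile(
        "".join(seq), profile.counts.copy(), provenance=list(profile.provenance),
        candidate_ribotype_positions=list(profile.candidate_ribotype_positions),
        unresolved_positions=list(profile.unresolved_positions),
    )
    return RibotypeProfile(new_profile, kept_calls)


def enumerate_combinations(profile: RibotypeProfile | ConsensusProfile | SeqRecord
                           ) -> list[SeqRecord]:
    """Fully resolved sequences from a profile with k biallelic ribotype
    sites: exactly 2^k records, lexicographic in the per-site allele choice."""
    if isinstance(profile, RibotypeProfile):
        seq = profile.profile.sequence
    elif isinstance(profile, ConsensusProfile):
        seq = profile.sequence
    else:
        seq = profile.sequence
    sites = [(i, s) for i, s in enumerate(seq) if s not in "ACGTN-"]
    expansions = []
    for i, s in sites:
        alleles = sorted(iupac_expand(s))
        if len(alleles) != 2:
            raise ValueError(
                f"position {i + 1}: symbol {s} expands to {len(alleles)} bases; "
                "only biallelic ribotype sites are supported"
            )
        expansions.append(alleles)
    out: list[SeqRecord] = []
    base = list(seq)
    for j, combo in enumerate(itertools.product(*expansions)):
        resolved = base[:]
        for (i, _), allele in zip(sites, combo):
            resolved[i] = allele
        out.append(SeqRecord(f"combination_{j:02d}", "".join(resolved)))
    return out
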