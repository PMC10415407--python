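"""From raw long reads to a per-species 45S consensus profile.

The stages mirror a benchtop long-read amplicon workflow:

1. :func:`partition_pools` — split pass reads into fixed-size pools;
2. :func:`select_by_size` — keep reads inside the expected amplicon window;
3. :func:`seed_consensus` — progressive alignment of the highest-quality
   reads into an initial reference;
4. :func:`map_to_reference` — banded global alignment of every read against
   the reference, both orientations, rejecting reads above 15% divergence;
5. :func:`pool_consensus` — per-pool column-majority consensus;
6. :func:`merge_pool_consensuses` — cross-pool merge with the ambiguity
   classification rule: gap/N disagreements are sequencing error, a roughly
   even split between two canonical bases is a candidate ribotype (IUPAC
   code), three-way splits are flagged as N.

Pairwise alignment uses unit-cost banded global edit distance (edlib);
divergence gating operates on alignment identity, which does not depend on
an affine scoring scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqio import SeqRecord, iupac_code

__all__ = [
    "PoolSet",
    "SizeWindow",
    "SizeSelectionReport",
    "PairwiseAlignment",
    "ConsensusProfile",
    "partition_pools",
    "select_by_size",
    "default_size_window",
    "seed_consensus",
    "map_to_reference",
    "pool_consensus",
    "merge_pool_consensuses",
]

# column symbol order used in count tables
SYMBOLS = ("A", "C", "G", "T", "-", "N")
_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}


@dataclass
class PoolSet:
    pools: list[list[SeqRecord]]
    pool_size: int

    def __len__(self) -> int:
        return len(self.pools)


@dataclass
class SizeWindow:
    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.min_bp < self.max_bp:
            raise ValueError("require 0 < min_bp < max_bp")

    def __contains__(self, length: int) -> bool:
        return self.min_bp <= length <= self.max_bp


@dataclass
class SizeSelectionReport:
    n_input: int
    n_kept: int

    @property
    def retained_fraction(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 0.0


@dataclass
class PairwiseAlignment:
    """A read aligned globally to a reference, with gapped strings."""

    read_id: str
    reference_id: str
    aligned_read: str
    aligned_ref: str
    identity: float
    orientation: str  # "forward" | "reverse"
    edit_distance: int
    cigar: str
    read_qualities: np.ndarray | None = None  # per *read base*, orientation-applied

    def __post_init__(self) -> None:
        if len(self.aligned_read) != len(self.aligned_ref):
            raise ValueError("aligned strings differ in length")


@dataclass
class ConsensusProfile:
    """IUPAC consensus with per-position base counts and coverage."""

    sequence: str
    counts: np.ndarray  # (L, 6) over SYMBOLS
    provenance: list[str] = field(default_factory=list)
    candidate_ribotype_positions: list[int] = field(default_factory=list)  # 1-based
    unresolved_positions: list[int] = field(default_factory=list)  # 1-based, three-way

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.sequence), len(SYMBOLS)):
            raise ValueError("count table shape does not match sequence length")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def ungapped_sequence(self) -> str:
        return self.sequence.replace("-", "")


def partition_pools(reads: list[SeqRecord], pool_size: int = 4000) -> PoolSet:
    """Split reads into ceil(n / pool_size) pools in input order (lossless)."""
    if not reads:
        raise ValueError("no reads to partition")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    pools = [reads[i:i + pool_size] for i in range(0, len(reads), pool_size)]
    return PoolSet(pools=pools, pool_size=pool_size)


def default_size_window(expected_bp: int, tolerance: float = 0.05) -> SizeWindow:
    """Expected amplicon length ± 5%, the gel-derived selection window."""
    return SizeWindow(int(expected_bp * (1 - tolerance)), int(round(expected_bp * (1 + tolerance))))


def select_by_size(reads: list[SeqRecord], window: SizeWindow
                   ) -> tuple[list[SeqRecord], SizeSelectionReport]:
    kept = [r for r in reads if len(r) in window]
    return kept, SizeSelectionReport(n_input=len(reads), n_kept=len(kept))


# ---------------------------------------------------------------------------
# Progressive seed consensus


def _rank_key(read: SeqRecord, index: int) -> tuple:
    # lowest mean error first; ties -> longer read, then input order
    return (read.mean_error, -len(read), index)


def seed_consensus(reads: list[SeqRecord], n_seeds: int = 12) -> SeqRecord:
    """Column-majority consensus of the ``n_seeds`` highest-quality reads.

    Reads are ranked by mean per-base error probability and merged
    progressively (best first) into a growing column profile; majority-gap
    columns are removed from the returned consensus.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    if len(reads) < n_seeds:
        raise ValueError(f"need at least {n_seeds} reads, got {len(reads)}")
    order = sorted(range(len(reads)), key=lambda i: _rank_key(reads[i], i))
    seeds = [reads[i] for i in order[:n_seeds]]

    # columns: list of count vectors over SYMBOLS[:5]
    first = seeds[0].sequence
    columns = [_new_column(b) for b in first]
    n_merged = 1
    for read in seeds[1:]:
        consensus, keep_idx = _profile_consensus(columns, n_merged)
        # amplicon reads arrive in both orientations: keep the better one
        fwd = edlib.align(read.sequence, consensus, mode="NW", task="path")
        rc = read.reverse_complement()
        rev = edlib.align(rc.sequence, consensus, mode="NW", task="path")
        if rev["editDistance"] < fwd["editDistance"]:
            seq, res = rc.sequence, rev
        else:
            seq, res = read.sequence, fwd
        ops = _parse_cigar(res["cigar"])
        _merge_into_columns(columns, keep_idx, seq, ops, n_merged)
        n_merged += 1
    final, _ = _profile_consensus(columns, n_merged)
    return SeqRecord("seed_consensus", final)


def _new_column(base: str) -> np.ndarray:
    col = np.zeros(5, dtype=np.int32)
    idx = _SYM_INDEX.get(base, 5)
    if idx < 5:  # degenerate symbols carry no vote
        col[idx] = 1
    return col


def _profile_consensus(columns: list[np.ndarray], n: int) -> tuple[str, list[int]]:
    """Majority symbol per column; returns consensus over non-gap-majority
    columns and their indices into ``columns``."""
    out = []
    keep = []
    for i, col in enumerate(columns):
        best = int(np.argmax(col))
        if SYMBOLS[best] == "-" or col.sum() == 0:
            continue
        out.append(SYMBOLS[best])
        keep.append(i)
    return "".join(out), keep


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def _merge_into_columns(columns: list[np.ndarray], keep_idx: list[int],
                        read: str, ops: list[tuple[int, str]], n_prev: int) -> None:
    """Merge a read aligned against the reduced consensus into full columns.

    edlib cigar semantics (query=read, target=consensus): '='/'X' consume
    both; 'I' consumes read only (new column); 'D' consumes consensus only
    (gap in read).
    """
    ci = 0  # index into keep_idx (reduced consensus coordinates)
    ri = 0
    inserts: list[tuple[int, np.ndarray]] = []  # (insert position in columns, col)
    for n, op in ops:
        if op in "=X":
            for _ in range(n):
                idx = _SYM_INDEX.get(read[ri], 5)
                if idx < 5:
                    columns[keep_idx[ci]][idx] += 1
                ci += 1
                ri += 1
        elif op == "D":  # consensus base absent from read
            for _ in range(n):
                columns[keep_idx[ci]][4] += 1
                ci += 1
        elif op == "I":  # read bases absent from consensus: new columns
            at = keep_idx[ci] if ci < len(keep_idx) else len(columns)
            for k in range(n):
                col = _new_column(read[ri])
                col[4] = n_prev
                inserts.append((at, col))
                ri += 1
        else:  # pragma: no cover - edlib emits only =XID in path mode
            raise ValueError(f"unexpected cigar op {op!r}")
    # apply inserts from the right so earlier indices stay valid
    for at, col in sorted(inserts, key=lambda t: -t[0]):
        columns.insert(at, col)


def map_positions(source: SeqRecord, target: SeqRecord,
                  try_reverse: bool = True) -> dict[int, int]:
    """1-based position map from ``source`` to ``target`` coordinates.

    Built from the global alignment of the two sequences (better orientation
    wins when ``try_reverse``); positions deleted in the target are absent
    from the map.  Reverse-orientation matches map source positions onto the
    reverse-complemented target coordinate.
    """
    fwd = edlib.align(source.sequence, target.sequence, mode="NW", task="path")
    seq = source.sequence
    res = fwd
    if try_reverse:
        rc = source.reverse_complement()
        rev = edlib.align(rc.sequence, target.sequence, mode="NW", task="path")
        if rev["editDistance"] < fwd["editDistance"]:
            seq, res = rc.sequence, rev
    mapping: dict[int, int] = {}
    s_pos = t_pos = 0
    for n, op in _parse_cigar(res["cigar"]):
        if op in "=X":
            for k in range(n):
                mapping[s_pos + k + 1] = t_pos + k + 1
            s_pos += n
            t_pos += n
        elif op == "I":
            s_pos += n
        elif op == "D":
            t_pos += n
    if seq is not source.sequence:
        L = len(source.sequence)
        mapping = {L - k + 1: v for k, v in mapping.items()}
    return mapping


def polish_reference(reads: list[SeqRecord], reference: SeqRecord,
                     rounds: int = 1, max_divergence: float = 0.15,
                     subsample: int | None = None) -> SeqRecord:
    """Refine a reference by remapping reads and taking the deep majority.

    The progressive seed consensus carries residual errors where greedy
    column anchoring tears alignments (notably around homopolymers); one or
    two rounds of remap-and-majority polishing removes them.  Majority-gap
    columns are deleted; zero-coverage positions keep the reference base.
    """
    ref = reference
    pool = reads if subsample is None else reads[:subsample]
    for _ in range(rounds):
        alns = [a for a in (map_to_reference(r, ref, max_divergence) for r in pool)
                if a is not None]
        if not alns:
            raise ValueError("no reads mapped during polishing")
        prof = pool_consensus(alns, ref, "polish")
        # majority-supported insertions at inter-position junctions: bases the
        # current reference is missing entirely
        ins_events: dict[int, list[str]] = {}
        for aln in alns:
            for junction, inserted in _insertions(aln):
                ins_events.setdefault(junction, []).append(inserted)
        err_sum, err_n = _error_prob_sums(alns, len(ref.sequence))
        ref = SeqRecord(ref.id, _polished_sequence(ref.sequence, prof, ins_events,
                                                   err_sum, err_n))
    return ref


def _error_prob_sums(alns: list["PairwiseAlignment"], L: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count of read error probabilities per reference position
    (base observations only; gaps carry no quality)."""
    err_sum = np.zeros(L)
    err_n = np.zeros(L)
    for aln in alns:
        if aln.read_qualities is None:
            continue
        ra = np.frombuffer(aln.aligned_read.encode(), dtype=np.uint8)
        rr = np.frombuffer(aln.aligned_ref.encode(), dtype=np.uint8)
        ref_cols = rr != ord("-")
        read_index = np.cumsum(ra != ord("-")) - 1
        ra_ref = ra[ref_cols]
        pos = np.arange(int(ref_cols.sum()))
        has_base = ra_ref != ord("-")
        q = np.asarray(aln.read_qualities, dtype=float)
        idx = read_index[ref_cols][has_base]
        np.add.at(err_sum, pos[has_base], q[idx])
        np.add.at(err_n, pos[has_base], 1.0)
    return err_sum, err_n


_RUN_EROSION_WEIGHT = 0.75  # fraction of in-run errors that shorten the run


def _polished_sequence(ref_seq: str, prof: "ConsensusProfile",
                       ins_events: dict[int, list[str]],
                       err_sum: np.ndarray, err_n: np.ndarray) -> str:
    """One polishing round: column majority plus homopolymer run-length repair.

    Homopolymer run lengths cannot be fixed by per-column majority: when the
    reference run is one base short, roughly half the reads emit an
    insertion (erosion by elevated in-run error), which never reaches a
    strict majority.  Each run of >= 2 identical bases is instead resized to
    ``round(mean_run_bases_per_read / (1 - w * mean_error_prob))``: the mean
    observed run length (column observations plus run-base insertions at any
    junction touching the run) corrected for expected erosion, with ``w``
    the fraction of errors that shorten a run.

    Other junctions accept an insertion when more than half the covering
    reads insert there (the majority inserted string wins); run-base
    insertions at a run's boundary junctions are not double-counted by that
    rule.  When a deleted base sits next to a shared base, the two allele
    populations' insertions straddle it on different junctions, each just
    below majority: the two junctions flanking a single base are therefore
    also pooled before voting.
    """
    L = len(ref_seq)
    coverage = prof.coverage
    # maximal runs of >= 2 identical canonical bases
    runs: list[tuple[int, int, str]] = []  # [start, end) and base
    i = 0
    while i < L:
        j = i
        while j < L and ref_seq[j] == ref_seq[i]:
            j += 1
        if j - i >= 2 and ref_seq[i] in "ACGT":
            runs.append((i, j, ref_seq[i]))
        i = j
    interior = set()
    run_base_at: dict[int, set[str]] = {}
    for s, e, b in runs:
        for t in range(s + 1, e):
            interior.add(t)
        run_base_at.setdefault(s, set()).add(b)
        run_base_at.setdefault(e, set()).add(b)
    run_start = {s: (s, e, b) for s, e, b in runs}

    def considered_events(t: int) -> list[str]:
        if t in interior:
            return []
        skip = run_base_at.get(t, set())
        return [e for e in ins_events.get(t, []) if not (set(e) and set(e) <= skip)]

    def majority_string(events: list[str]) -> str:
        values, counts = np.unique(events, return_counts=True)
        return str(values[np.argmax(counts)])

    accept: dict[int, str] = {}
    for t in ins_events:
        considered = considered_events(t)
        cov = float(coverage[min(t, L - 1)])
        if considered and cov > 0 and len(considered) * 2 > cov:
            accept[t] = majority_string(considered)
    # pooled vote across the two junctions flanking a single (non-run) base
    for i in range(L):
        if i in run_start or i in interior or ref_seq[i] not in "ACGT":
            continue
        t1, t2 = i, i + 1
        if t1 in accept or t2 in accept or t2 in interior:
            continue
        combined = considered_events(t1) + considered_events(t2)
        cov = float(coverage[i])
        if combined and cov > 0 and len(combined) * 2 > cov:
            accept[t2] = majority_string(combined)

    out: list[str] = []
    i = 0
    while i <= L:
        if i in accept:
            out.append(accept[i])
        if i == L:
            break
        if i in run_start:
            s, e, b = run_start[i]
            cov = float(coverage[s:e].mean())
            if cov > 0:
                b_obs = float(prof.counts[s:e, _SYM_INDEX[b]].sum())
                b_ins = sum(ev.count(b) for t in range(s, e + 1)
                            for ev in ins_events.get(t, []))
                mean_run = (b_obs + b_ins) / cov
                n_obs = float(err_n[s:e].sum())
                mean_err = float(err_sum[s:e].sum()) / n_obs if n_obs else 0.0
                survival = max(1.0 - _RUN_EROSION_WEIGHT * mean_err, 0.5)
                est = max(int(round(mean_run / survival)), 1)
            else:
                est = e - s
            out.append(b * est)
            i = e
            continue
        s = prof.sequence[i]
        if s != "-":
            out.append(ref_seq[i] if s == "N" else s)
        i += 1
    return "".join(out)


def _insertions(aln: "PairwiseAlignment"):
    """Yield (reference junction, inserted bases) for read insertions.

    The junction index j means the bases sit between reference positions
    j-1 and j (0-based); j == 0 is before the first base.
    """
    ref_pos = 0
    read_pos = 0
    read = aln.aligned_read.replace("-", "")
    for n, op in _parse_cigar(aln.cigar):
        if op in "=X":
            ref_pos += n
            read_pos += n
        elif op == "D":
            ref_pos += n
        elif op == "I":
            yield ref_pos, read[read_pos:read_pos + n]
            read_pos += n


# ---------------------------------------------------------------------------
# Read mapping


def _alignment_strings(read: str, ref: str, ops: list[tuple[int, str]]) -> tuple[str, str]:
    a, b = [], []
    ri = ci = 0
    for n, op in ops:
        if op in "=X":
            a.append(read[ri:ri + n]); b.append(ref[ci:ci + n])
            ri += n; ci += n
        elif op == "I":
            a.append(read[ri:ri + n]); b.append("-" * n)
            ri += n
        elif op == "D":
            a.append("-" * n); b.append(ref[ci:ci + n])
            ci += n
    return "".join(a), "".join(b)


def map_to_reference(read: SeqRecord, reference: SeqRecord,
                     max_divergence: float = 0.15) -> PairwiseAlignment | None:
    """Banded global alignment of a read to the reference, both orientations.

    Returns ``None`` (rejection) when the best orientation's divergence
    ``1 - identity`` exceeds ``max_divergence`` — the mapping tolerance used
    for noisy long-read amplicon data.
    """
    if not reference.sequence:
        raise ValueError("empty reference")
    # cap the band: anything beyond this cannot pass the divergence gate
    k = int((max_divergence + 0.10) * max(len(read), len(reference))) + 10
    fwd = edlib.align(read.sequence, reference.sequence, mode="NW", task="distance", k=k)
    rc = read.reverse_complement()
    rev = edlib.align(rc.sequence, reference.sequence, mode="NW", task="distance", k=k)
    d_f = fwd["editDistance"] if fwd["editDistance"] >= 0 else np.inf
    d_r = rev["editDistance"] if rev["editDistance"] >= 0 else np.inf
    if np.isinf(d_f) and np.isinf(d_r):
        return None
    if d_f <= d_r:
        oriented, orientation = read, "forward"
    else:
        oriented, orientation = rc, "reverse"
    res = edlib.align(oriented.sequence, reference.sequence, mode="NW", task="path", k=k)
    ops = _parse_cigar(res["cigar"])
    a_read, a_ref = _alignment_strings(oriented.sequence, reference.sequence, ops)
    columns = len(a_read)
    matches = sum(n for n, op in ops if op == "=")
    identity = matches / columns if columns else 0.0
    if 1.0 - identity > max_divergence:
        return None
    return PairwiseAlignment(
        read_id=read.id,
        reference_id=reference.id,
        aligned_read=a_read,
        aligned_ref=a_ref,
        identity=identity,
        orientation=orientation,
        edit_distance=int(res["editDistance"]),
        cigar=res["cigar"],
        read_qualities=oriented.qualities,
    )


# ---------------------------------------------------------------------------
# Pool consensus and merging


def pool_consensus(alignments: list[PairwiseAlignment],
                   reference: SeqRecord,
                   pool_id: str = "pool") -> ConsensusProfile:
    """Column-majority consensus of mapped reads over the reference frame.

    The consensus symbol is the plurality of {A, C, G, T, gap} at each
    position (ties broken in that fixed order); zero-coverage positions are
    emitted as N.  Counts are retained for the ribotype stage.
    """
    if not alignments:
        raise ValueError("no accepted alignments")
    L = len(reference.sequence)
    counts = np.zeros((L, len(SYMBOLS)), dtype=np.int64)
    for aln in alignments:
        _tally_one(counts, aln)
    seq = []
    for i in range(L):
        if counts[i, :5].sum() == 0:
            seq.append("N")
        else:
            seq.append(SYMBOLS[int(np.argmax(counts[i, :5]))])
    return ConsensusProfile("".join(seq), counts, provenance=[pool_id])


def _tally_one(counts: np.ndarray, aln: PairwiseAlignment) -> None:
    # vectorized over alignment columns: every column that consumes the
    # reference contributes the read symbol ('-' for deletions)
    ra = np.frombuffer(aln.aligned_read.encode(), dtype=np.uint8)
    rr = np.frombuffer(aln.aligned_ref.encode(), dtype=np.uint8)
    ref_cols = rr != ord("-")
    codes = _BASE_LOOKUP[ra[ref_cols]]
    np.add.at(counts, (np.arange(int(ref_cols.sum())), codes), 1)


_BASE_LOOKUP = np.zeros(256, dtype=np.int64)
for _s, _i in _SYM_INDEX.items():
    _BASE_LOOKUP[ord(_s)] = _i


def merge_pool_consensuses(profiles: list[ConsensusProfile],
                           split_fraction: float = 0.25) -> ConsensusProfile:
    """Merge per-pool consensuses with the ambiguity-classification rule.

    Per column: disagreements involving gap or N resolve to the majority
    canonical base (treated as sequencing error); two canonical bases each
    carried by >= ``split_fraction`` of pools become an IUPAC-coded candidate
    ribotype; a three-way canonical split is flagged N and reported.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 pool consensuses")
    L = len(profiles[0].sequence)
    if any(len(p.sequence) != L for p in profiles):
        raise ValueError("pool consensuses are not on the same reference frame")
    n_pools = len(profiles)
    seq = []
    candidates: list[int] = []
    unresolved: list[int] = []
    merged_counts = np.zeros((L, len(SYMBOLS)), dtype=np.int64)
    for p in profiles:
        merged_counts += p.counts
    for i in range(L):
        symbols = [p.sequence[i] for p in profiles]
        canon = [s for s in symbols if s in "ACGT"]
        if not canon:
            seq.append("-" if symbols.count("-") >= symbols.count("N") else "N")
            continue
        tally = {b: canon.count(b) for b in set(canon)}
        major = sorted(tally, key=lambda b: (-tally[b], b))
        frequent = [b for b in major if tally[b] / n_pools >= split_fraction]
        if len(frequent) >= 3:
            seq.append("N")
            unresolved.append(i + 1)
        elif len(frequent) == 2:
            seq.append(iupac_code(frequent))
            candidates.append(i + 1)
        else:
            seq.append(major[0])
    provenance = [pid for p in profiles for pid in p.provenance]
    return ConsensusProfile("".join(seq), merged_counts, provenance=provenance,
                            candidate_ribotype_positions=candidates,
                            unresolved_positions=unresolved)


def build_species_profile(reads: list[SeqRecord], size_window: SizeWindow,
                          pool_size: int = 500, n_seeds: int = 12,
                          polish_rounds: int = 2, polish_subsample: int = 300,
                          max_divergence: float = 0.15
                          ) -> tuple[ConsensusProfile, SeqRecord, list[PairwiseAlignment]]:
    """Full profile pipeline: size-select, seed, polish, map, pool, merge.

    Returns the merged cross-pool consensus, the polished reference it is
    framed on, and the accepted read alignments (ready for the ribotype
    caller).
    """
    kept, _ = select_by_size(reads, size_window)
    if len(kept) < n_seeds:
        raise ValueError(f"only {len(kept)} reads inside the size window")
    seed = seed_consensus(kept, n_seeds=n_seeds)
    reference = polish_reference(kept, seed, rounds=polish_rounds,
                                 max_divergence=max_divergence,
                                 subsample=polish_subsample)
    alignments = [a for a in (map_to_reference(r, reference, max_divergence)
                              for r in kept) if a is not None]
    if not alignments:
        raise ValueError("no reads mapped to the polished reference")
    pools = partition_pools(alignments, pool_size)
    profiles = [pool_consensus(p, reference, f"pool_{i}")
                for i, p in enumerate(pools.pools)]
    if len(profiles) >= 2:
        merged = merge_pool_consensuses(profiles)
    else:
        merged = profiles[0]
    return merged, reference, alignments
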