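"""Haplotype networks, distance trees, and species-delimitation statistics.

Implements the population-genetic layer of the workflow: haplotype
collapsing, TCS-style statistical-parsimony networks, Tamura–Nei (1993)
distances, neighbor joining with jackknife support, Rosenberg's reciprocal
monophyly probability P_AB, and a Monte-Carlo "random distinctiveness" test
in the spirit of Rodrigo's P(RD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from io import StringIO

import dendropy
import networkx as nx
import numpy as np

from .seqio import SeqRecord

__all__ = [
    "HaplotypeSet",
    "ParsimonyNetwork",
    "DistanceMatrix",
    "PhyloTree",
    "DelimitationResult",
    "collapse_haplotypes",
    "parsimony_connection_limit",
    "pairwise_mutation_steps",
    "tcs_network",
    "tn93_distance",
    "tn93_matrix",
    "nj_tree",
    "jackknife_support",
    "simulate_coalescent_tree",
    "rosenberg_pab",
    "rodrigo_prd",
    "clade_distances",
]


@dataclass
class HaplotypeSet:
    sequences: list[str]
    multiplicities: list[int]
    labels: list[list[str]]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class ParsimonyNetwork:
    graph: nx.Graph  # nodes: haplotype ids; 'sampled', 'multiplicity', 'labels'
    connection_limit: int

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("sampled")]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("sampled")]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("nonzero diagonal")


@dataclass
class PhyloTree:
    """An (un)rooted tree with branch lengths and optional integer-percent
    support on internal edges, backed by a dendropy tree."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        t = dendropy.Tree.get(data=newick, schema="newick",
                              suppress_internal_node_taxa=True)
        return cls(t)

    def to_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def bipartitions(self, min_length: float = 1e-12) -> set[frozenset]:
        """Non-trivial unrooted splits, each as the frozenset of the smaller
        side's leaf labels (ties: lexicographically smaller side).

        Internal edges of (near-)zero length are treated as unresolved and
        contribute no split — identical sequences produce no supported
        bipartitions rather than tie-break artifacts.
        """
        labels = frozenset(self.leaf_labels)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            if (node.edge.length or 0.0) < min_length:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = labels - side
            if len(side) < 2 or len(other) < 2:
                continue
            pick = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            out.add(pick)
        return out


@dataclass
class DelimitationResult:
    clade: str
    intra_distance: float  # mean within-group pairwise; NaN for singletons
    inter_distance: float  # nearest between-group mean
    ratio: float

    def __post_init__(self) -> None:
        if self.inter_distance < 0:
            raise ValueError("negative distance")


# ---------------------------------------------------------------------------
# Haplotypes and networks


def collapse_haplotypes(sequences: list[str], labels: list[str] | None = None
                        ) -> HaplotypeSet:
    """Merge identical equal-length sequences (ambiguity codes compared
    literally: W != A)."""
    if labels is None:
        labels = [f"seq_{i}" for i in range(len(sequences))]
    if len(labels) != len(sequences):
        raise ValueError("labels and sequences differ in length")
    widths = {len(s) for s in sequences}
    if len(widths) > 1:
        raise ValueError(f"unequal sequence lengths: {sorted(widths)}")
    seen: dict[str, int] = {}
    seqs: list[str] = []
    mult: list[int] = []
    labs: list[list[str]] = []
    for s, l in zip(sequences, labels):
        if s in seen:
            mult[seen[s]] += 1
            labs[seen[s]].append(l)
        else:
            seen[s] = len(seqs)
            seqs.append(s)
            mult.append(1)
            labs.append([l])
    return HaplotypeSet(seqs, mult, labs)


def pairwise_mutation_steps(a: str, b: str) -> int:
    """Mutational differences with each contiguous gap run counted once.

    Columns where both sequences are gapped are ignored; a run of columns
    gapped in exactly one sequence is a single indel event.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    steps = 0
    in_gap_run = False
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            in_gap_run = False
            continue
        if (x == "-") != (y == "-"):
            if not in_gap_run:
                steps += 1
                in_gap_run = True
            continue
        in_gap_run = False
        if x != y:
            steps += 1
    return steps


def parsimony_connection_limit(n_sites: int, confidence: float = 0.95,
                               max_steps: int = 100) -> int:
    """Largest step count whose parsimony probability is >= ``confidence``.

    Operationalized with a Jukes–Cantor correction: for j observed
    differences over L sites, the per-site number of substitutions is
    Poisson with mean mu solving (3/4)(1 - exp(-4 mu / 3)) = j / L, and the
    probability that one observed difference reflects exactly one
    substitution is mu * exp(-mu) / (j / L).  The parsimony probability for
    j steps is that ratio to the j-th power.
    """
    best = 1
    for j in range(1, max_steps + 1):
        q = j / n_sites
        if q >= 0.75:
            break
        mu = -0.75 * math.log(1.0 - 4.0 * q / 3.0)
        p_single = (mu * math.exp(-mu)) / q
        if p_single ** j >= confidence:
            best = j
        else:
            break
    return best


def tcs_network(haplotypes: HaplotypeSet, confidence: float = 0.95,
                limit_override: int | None = None) -> ParsimonyNetwork:
    """Statistical-parsimony network with inferred median nodes.

    Pairs differing by one step are always joined directly; longer
    connections (up to the parsimony limit) are added in increasing distance
    order only between components not yet connected, inserting unsampled
    median nodes so every edge represents a single mutation.
    """
    n = len(haplotypes)
    g = nx.Graph()
    for i in range(n):
        g.add_node(f"H{i}", sampled=True,
                   multiplicity=haplotypes.multiplicities[i],
                   labels=list(haplotypes.labels[i]),
                   sequence=haplotypes.sequences[i])
    if n == 1:
        return ParsimonyNetwork(g, connection_limit=0)
    L = len(haplotypes.sequences[0])
    limit = limit_override if limit_override is not None else \
        parsimony_connection_limit(L, confidence)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_mutation_steps(haplotypes.sequences[i], haplotypes.sequences[j])
            pairs.append((d, i, j))
    pairs.sort()
    n_median = 0
    for d, i, j in pairs:
        if d == 0 or d > limit:
            continue
        a, b = f"H{i}", f"H{j}"
        if d == 1:
            g.add_edge(a, b, steps=1)
            continue
        if nx.has_path(g, a, b):
            continue
        prev = a
        for _ in range(d - 1):
            m = f"mv{n_median}"
            n_median += 1
            g.add_node(m, sampled=False, multiplicity=0, labels=[])
            g.add_edge(prev, m, steps=1)
            prev = m
        g.add_edge(prev, b, steps=1)
    return ParsimonyNetwork(g, connection_limit=limit)


# ---------------------------------------------------------------------------
# Distances


def _comparable_columns(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    ok = np.isin(xa, _ACGT) & np.isin(xb, _ACGT)
    return xa[ok], xb[ok]


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def tn93_distance(a: str, b: str) -> float:
    """Tamura–Nei (1993) distance per site.

    Gap and ambiguous columns are excluded pairwise; base frequencies are
    estimated from the two sequences pooled over comparable columns.
    Returns ``inf`` when a logarithm argument is non-positive (saturation);
    raises on zero comparable sites.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    xa, xb = _comparable_columns(a, b)
    n = len(xa)
    if n == 0:
        raise ValueError("no comparable sites")
    pooled = np.concatenate([xa, xb])
    gA, gC, gG, gT = [(pooled == c).mean() for c in _ACGT]
    gR, gY = gA + gG, gC + gT
    diff = xa != xb
    purine = np.isin(xa, _ACGT[[0, 2]]) & np.isin(xb, _ACGT[[0, 2]])
    pyrim = np.isin(xa, _ACGT[[1, 3]]) & np.isin(xb, _ACGT[[1, 3]])
    P1 = float((diff & purine).mean())   # A<->G transitions
    P2 = float((diff & pyrim).mean())    # C<->T transitions
    Q = float((diff & ~purine & ~pyrim).mean())  # transversions
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    if gR == 0 or gY == 0:  # one base class absent but differences exist
        return math.inf
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 0.0
    w2 = 1.0 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 0.0
    w3 = 1.0 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.inf
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def tn93_matrix(records: list[SeqRecord]) -> DistanceMatrix:
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tn93_distance(records[i].sequence, records[j].sequence)
    return DistanceMatrix([r.id for r in records], d)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; ties broken by the lowest-index pair.

    Additive distance matrices are recovered exactly (negative estimated
    branch lengths are clamped to zero).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[str] = []  # newick fragments
    for lab in dm.labels:
        nodes.append(_quote(lab))
    active = list(range(n))
    next_d = d
    while len(active) > 3:
        m = len(active)
        sub = next_d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        fi, fj = np.unravel_index(np.argmin(q), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = next_d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_row = 0.5 * (next_d[i, :] + next_d[j, :] - dij)
        k = next_d.shape[0]
        next_d = np.pad(next_d, ((0, 1), (0, 1)))
        next_d[k, :k] = new_row
        next_d[:k, k] = new_row
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        active = [a for a in active if a not in (i, j)] + [k]
    # join the last three nodes at an unrooted trifurcation
    a, b, c = active
    la = 0.5 * (next_d[a, b] + next_d[a, c] - next_d[b, c])
    lb = 0.5 * (next_d[a, b] + next_d[b, c] - next_d[a, c])
    lc = 0.5 * (next_d[a, c] + next_d[b, c] - next_d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    return PhyloTree.from_newick(newick)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Jackknife support


def jackknife_support(records: list[SeqRecord], replicates: int = 1000,
                      delete_fraction: float = 0.5, seed: int = 0,
                      distance=tn93_distance) -> PhyloTree:
    """Column-deletion jackknife support for the NJ/TN93 tree.

    Each replicate deletes ``delete_fraction`` of alignment columns without
    replacement, rebuilds the tree, and support is the integer percentage of
    replicates containing each original internal bipartition.  Saturated
    (infinite) replicate distances are capped at twice the largest finite
    entry so the replicate can still be built.
    """
    width = len(records[0].sequence)
    if width < 10:
        raise ValueError("alignment too narrow to jackknife")
    rng = np.random.default_rng(seed)
    base = _matrix_with_cap(records, distance)
    tree = nj_tree(base)
    targets = tree.bipartitions()
    hits = {bp: 0 for bp in targets}
    arr = np.array([list(r.sequence) for r in records])
    n_keep = width - int(round(delete_fraction * width))
    for _ in range(replicates):
        cols = rng.choice(width, size=n_keep, replace=False)
        sub = ["".join(row) for row in arr[:, np.sort(cols)]]
        recs = [SeqRecord(r.id, s) for r, s in zip(records, sub)]
        try:
            rep_tree = nj_tree(_matrix_with_cap(recs, distance))
        except ValueError:
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                hits[bp] += 1
    # annotate internal nodes with integer percent support
    labels = frozenset(tree.leaf_labels)
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        if pick in hits:
            node.label = str(int(round(100 * hits[pick] / replicates)))
    return tree


def _matrix_with_cap(records: list[SeqRecord], distance) -> DistanceMatrix:
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = distance(records[i].sequence, records[j].sequence)
    finite = d[np.isfinite(d)]
    cap = 2.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
    d[~np.isfinite(d)] = cap
    return DistanceMatrix([r.id for r in records], d)


# ---------------------------------------------------------------------------
# Coalescent simulation and delimitation statistics


def simulate_coalescent_tree(n: int, rng: np.random.Generator,
                             labels: list[str] | None = None) -> PhyloTree:
    """A Kingman coalescent tree: exponential waiting times with rate
    C(k, 2), uniformly random pair joins; branch lengths in coalescent
    units."""
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    frags = [_quote(l) for l in labels]
    heights = [0.0] * n
    active = list(range(n))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        frag = (f"({frags[a]}:{t - heights[a]:.10g},"
                f"{frags[b]}:{t - heights[b]:.10g})")
        frags.append(frag)
        heights.append(t)
        active = [x for x in active if x not in (a, b)] + [len(frags) - 1]
    return PhyloTree.from_newick(frags[active[0]] + ";")


@lru_cache(maxsize=None)
def _recip_mono_prob(i: int, j: int) -> float:
    # P(coalescence keeps both groups pure down to one lineage each)
    if i == 1 and j == 1:
        return 1.0
    tot = (i + j) * (i + j - 1) / 2
    p = 0.0
    if i >= 2:
        p += (i * (i - 1) / 2) / tot * _recip_mono_prob(i - 1, j)
    if j >= 2:
        p += (j * (j - 1) / 2) / tot * _recip_mono_prob(i, j - 1)
    return p


def rosenberg_pab(a: int, b: int) -> float:
    """Probability that two groups of sizes a and b are reciprocally
    monophyletic on a uniformly random labeled coalescent history.

    Computed by exact recursion over the number of pure lineages remaining
    in each group; agrees with brute-force enumeration of labeled histories.
    """
    if a < 1 or b < 1:
        raise ValueError("group sizes must be >= 1")
    return _recip_mono_prob(a, b)


def _node_of_clade(tree: PhyloTree, clade: set[str]):
    target = frozenset(clade)
    for node in tree.tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leaves == target:
            return node
    raise ValueError("clade not present in tree")


def _stem_statistic(node, tree_obj: dendropy.Tree) -> float:
    stem = node.edge.length or 0.0
    lengths = [e.length for e in tree_obj.preorder_edge_iter()
               if e.length is not None]
    mean_len = float(np.mean(lengths)) if lengths else 1.0
    return stem / mean_len if mean_len > 0 else 0.0


def rodrigo_prd(tree: PhyloTree, clade: set[str], n_sim: int = 1000,
                seed: int = 0) -> float:
    """Monte-Carlo p-value for the distinctiveness of a clade.

    The statistic is the clade's stem branch length divided by the tree's
    mean edge length; the null distribution is obtained from Kingman
    coalescent trees of the same tip count, measuring a random internal
    clade of matching size (nearest available size otherwise).  Small
    p-values mean the clade is *more* distinct than random coalescence
    predicts; large p-values mean "randomly distinct".
    """
    if len(clade) < 2:
        raise ValueError("clade must contain at least 2 tips")
    node = _node_of_clade(tree, clade)
    s_obs = _stem_statistic(node, tree.tree)
    n = len(tree.leaf_labels)
    k = len(clade)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_sim):
        sim = simulate_coalescent_tree(n, rng)
        cands = []
        for nd in sim.tree.preorder_node_iter():
            if nd.parent_node is None or nd.is_leaf():
                continue
            size = sum(1 for _ in nd.leaf_iter())
            if size <= n - 1:
                cands.append((abs(size - k), nd))
        if not cands:
            continue
        best = min(c[0] for c in cands)
        pool = [nd for dd, nd in cands if dd == best]
        pick = pool[rng.integers(0, len(pool))]
        if _stem_statistic(pick, sim.tree) >= s_obs:
            exceed += 1
    return (1 + exceed) / (n_sim + 1)


def clade_distances(dm: DistanceMatrix, grouping: dict[str, str]
                    ) -> list[DelimitationResult]:
    """Mean intra-clade distance, nearest inter-clade mean, and their ratio.

    Every taxon must be assigned to exactly one group; singleton groups get
    NaN intra distance (undefined, not zero).
    """
    missing = set(dm.labels) - set(grouping)
    if missing:
        raise ValueError(f"taxa missing from grouping: {sorted(missing)}")
    groups: dict[str, list[int]] = {}
    for idx, lab in enumerate(dm.labels):
        groups.setdefault(grouping[lab], []).append(idx)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = []
    for gname, idx in groups.items():
        if len(idx) > 1:
            sub = dm.values[np.ix_(idx, idx)]
            intra = float(sub[np.triu_indices(len(idx), 1)].mean())
        else:
            intra = math.nan
        inter = math.inf
        for oname, odx in groups.items():
            if oname == gname:
                continue
            inter = min(inter, float(dm.values[np.ix_(idx, odx)].mean()))
        ratio = intra / inter if inter > 0 and not math.isnan(intra) else math.nan
        out.append(DelimitationResult(gname, intra, inter, ratio))
    return out
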