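"""Mitochondrial consensus calling, masked distances and haplotype networks.

Consensus bases are called per position from base counts with an inclusive
depth >= 4 and major-allele frequency >= 0.75 rule (ties for the major
allele give N). Pairwise distances count differing positions where both
sequences have a called base. The haplotype network collapses identical
sequences into weighted nodes and retains every edge that occurs in some
minimum spanning tree of the distance graph (a minimum spanning network),
reporting the clade separation as the smallest inter-clade edge on the
network when clade labels are supplied.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .geodist import DistMatrix
from .io import BASES

MIN_DEPTH = 4
MIN_MAJOR_FREQ = 0.75


@dataclasses.dataclass
class ConsensusSeq:
    label: str
    sequence: str
    callable_fraction: float
    n_ties: int = 0


def call_consensus(
    counts: np.ndarray,
    label: str = "",
    min_depth: int = MIN_DEPTH,
    min_major_freq: float = MIN_MAJOR_FREQ,
) -> ConsensusSeq:
    """Consensus sequence from per-position (L, 4) base counts.

    A position is called to its major allele iff depth >= ``min_depth`` and
    major count / depth >= ``min_major_freq`` (both inclusive); otherwise N.
    A tie for the major allele also gives N.
    """
    c = np.asarray(counts)
    if c.ndim != 2 or c.shape[1] != 4:
        raise ValueError("counts must have shape (L, 4)")
    depth = c.sum(axis=1)
    major = c.argmax(axis=1)
    major_count = c.max(axis=1)
    tie = (c == major_count[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore"):
        freq = np.where(depth > 0, major_count / np.maximum(depth, 1), 0.0)
    callable_ = (depth >= min_depth) & (freq >= min_major_freq) & ~tie & (depth > 0)
    seq = np.where(callable_, BASES[major], "N")
    return ConsensusSeq(
        label=label,
        sequence="".join(seq),
        callable_fraction=float(callable_.mean()),
        n_ties=int((tie & (depth >= min_depth)).sum()),
    )


def pairwise_diffs(seqs: list[ConsensusSeq] | list[str]):
    """Masked Hamming distances between consensus sequences.

    Returns ``(DistMatrix of mutation counts, comparable-site counts)``;
    positions where either base is N are excluded. A pair with zero
    comparable sites gets NaN distance (flagged missing).
    """
    labels = []
    arrs = []
    for i, s in enumerate(seqs):
        if isinstance(s, ConsensusSeq):
            labels.append(s.label or f"seq{i}")
            s = s.sequence
        else:
            labels.append(f"seq{i}")
        arrs.append(np.frombuffer(s.encode(), dtype="S1"))
    L = len(arrs[0])
    if any(len(a) != L for a in arrs):
        raise ValueError("sequences must have equal length")
    X = np.vstack(arrs)
    valid = X != b"N"
    n = len(arrs)
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp[i, j] = comp[j, i] = both.sum()
            if comp[i, j] == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = int(np.sum(X[i][both] != X[j][both]))
    return DistMatrix(labels=labels, values=d), comp


def haplotype_network(dist: DistMatrix, clade_labels=None):
    """Minimum spanning network over collapsed haplotypes.

    Identical sequences (distance 0) collapse into one node with
    multiplicity. The network keeps every edge belonging to some minimum
    spanning tree (Kruskal processed by weight class: an edge qualifies if
    its endpoints are not yet connected by strictly lighter edges). Returns
    ``(graph, clade_separation)`` where the separation is the minimum
    inter-clade edge weight on the network (NaN without labels).
    """
    n = dist.n
    # collapse identical haplotypes
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i in range(n):
        for j in range(i + 1, n):
            if dist.values[i, j] == 0:
                union(i, j)
    by_root: dict[int, list[int]] = {}
    for i in range(n):
        by_root.setdefault(find(i), []).append(i)
    # representative = lowest-index member, so node labels are predictable
    groups = {min(members): members for members in by_root.values()}
    reps = sorted(groups)
    if len(reps) < 1:
        raise ValueError("no haplotypes")

    G = nx.Graph()
    for r in reps:
        members = [dist.labels[i] for i in groups[r]]
        clades = (
            sorted({clade_labels[i] for i in groups[r]}) if clade_labels is not None else None
        )
        G.add_node(dist.labels[r], multiplicity=len(members), members=members, clades=clades)

    edges = []
    for a_i, r1 in enumerate(reps):
        for r2 in reps[a_i + 1 :]:
            w = dist.values[r1, r2]
            if not np.isnan(w):
                edges.append((w, r1, r2))
    edges.sort(key=lambda e: e[0])

    parent2 = {r: r for r in reps}

    def find2(x):
        while parent2[x] != x:
            parent2[x] = parent2[parent2[x]]
            x = parent2[x]
        return x

    i = 0
    while i < len(edges):
        j = i
        while j < len(edges) and edges[j][0] == edges[i][0]:
            j += 1
        batch = [e for e in edges[i:j] if find2(e[1]) != find2(e[2])]
        for w, u, v in batch:
            G.add_edge(dist.labels[u], dist.labels[v], weight=float(w))
        for w, u, v in batch:
            if find2(u) != find2(v):
                parent2[find2(u)] = find2(v)
        i = j

    separation = np.nan
    if clade_labels is not None:
        clade_of = {dist.labels[r]: {clade_labels[i] for i in groups[r]} for r in reps}
        inter = [
            d["weight"]
            for u, v, d in G.edges(data=True)
            if not (clade_of[u] & clade_of[v])
        ]
        if inter:
            separation = float(min(inter))
    return G, separation
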