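"""Pairwise linkage disequilibrium from genotype likelihoods.

Two-locus haplotype frequencies are estimated by EM over the four
haplotype classes (AB, Ab, aB, ab), treating each individual's two
haplotypes as independent draws (random mating) and marginalizing the
unknown genotypes through their likelihood triplets. From the converged
frequencies the usual D, D' and r2 follow. Pruning removes SNPs so that no
retained pair within a distance window exceeds an r2 threshold, via the
standard greedy max-degree node-deletion heuristic with deterministic
tie-breaking.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .io import GLMatrix

MAX_EM_ITER = 200
EM_TOL = 1e-8

# genotype pair implied by an ordered pair of haplotypes (each in 0..3 coding
# allele-at-A * 2 + allele-at-B); g_a = a1 + a2, g_b = b1 + b2
_HAP_A = np.array([0, 0, 1, 1])  # allele at locus A for haplotype class
_HAP_B = np.array([0, 1, 0, 1])  # allele at locus B


@dataclasses.dataclass
class LDRecord:
    chrom: str
    pos_a: int
    pos_b: int
    dist: int
    D: float
    Dprime: float
    r2: float
    loglik_trace: np.ndarray | None = None


def haplotype_em_r2(
    gl_a: np.ndarray,
    gl_b: np.ndarray,
    max_iter: int = MAX_EM_ITER,
    tol: float = EM_TOL,
    return_trace: bool = False,
):
    """EM over 4 haplotype frequencies for one pair of sites.

    ``gl_a``/``gl_b`` are (N, 3) likelihood triplets. Returns
    ``(h, D, Dprime, r2)`` (plus the log-likelihood trace when requested).
    Monomorphic sites give an undefined (NaN) r2.
    """
    gl_a = np.asarray(gl_a, dtype=float)
    gl_b = np.asarray(gl_b, dtype=float)
    N = gl_a.shape[0]
    if N < 2:
        raise ValueError("need at least two individuals")

    # data likelihood for each ordered haplotype pair (j, k): gl_a[g_a] * gl_b[g_b]
    ga = _HAP_A[:, None] + _HAP_A[None, :]
    gb = _HAP_B[:, None] + _HAP_B[None, :]
    lik_pair = gl_a[:, ga] * gl_b[:, gb]  # (N, 4, 4)

    h = np.full(4, 0.25)
    trace = []
    for _ in range(max_iter):
        w = lik_pair * h[None, :, None] * h[None, None, :]
        tot = w.sum(axis=(1, 2))
        if np.any(tot <= 0):
            raise ValueError("zero likelihood; invalid triplets")
        if return_trace:
            trace.append(np.log(tot).sum())
        post = w / tot[:, None, None]
        counts = post.sum(axis=(0, 2)) + post.sum(axis=(0, 1))
        h_new = counts / (2 * N)
        delta = np.max(np.abs(h_new - h))
        h = h_new
        if delta < tol:
            break
    pA = h[2] + h[3]
    pB = h[1] + h[3]
    D = h[3] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        r2 = np.nan
        dprime = np.nan
    else:
        r2 = D * D / denom
        dmax = min(pA * (1 - pB), (1 - pA) * pB) if D > 0 else min(pA * pB, (1 - pA) * (1 - pB))
        dprime = D / dmax if dmax > 0 else np.nan
    if return_trace:
        w = lik_pair * h[None, :, None] * h[None, None, :]
        trace.append(np.log(w.sum(axis=(1, 2))).sum())
        return h, D, dprime, r2, np.array(trace)
    return h, D, dprime, r2


def compute_ld(gl: GLMatrix, max_dist: int = 100_000, pairs=None) -> pd.DataFrame:
    """All within-chromosome pairwise LD records up to ``max_dist`` bp.

    Returns a DataFrame ``chrom posA posB dist D Dprime r2``. ``pairs`` may
    restrict computation to explicit (i, j) site-index pairs.
    """
    sites = gl.sites
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    if pairs is None:
        pairs = []
        order = np.lexsort((pos, chrom))
        for a_idx in range(len(order)):
            i = order[a_idx]
            for b_idx in range(a_idx + 1, len(order)):
                j = order[b_idx]
                if chrom[i] != chrom[j] or abs(pos[j] - pos[i]) > max_dist:
                    break
                pairs.append((i, j))
    rows = []
    for i, j in pairs:
        _, D, dprime, r2 = haplotype_em_r2(gl.gl[i], gl.gl[j])
        rows.append(
            (chrom[i], int(pos[i]), int(pos[j]), int(abs(pos[j] - pos[i])), D, dprime, r2)
        )
    return pd.DataFrame(rows, columns=["chrom", "posA", "posB", "dist", "D", "Dprime", "r2"])


def ld_decay(records: pd.DataFrame, bins) -> pd.DataFrame:
    """Mean r2 by physical-distance bin.

    ``bins`` are edges as for numpy.histogram; empty bins are reported with
    count 0 and NaN mean.
    """
    if len(records) == 0:
        raise ValueError("no LD records")
    bins = np.asarray(bins)
    idx = np.digitize(records["dist"], bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = records["r2"][idx == b]
        rows.append((bins[b], bins[b + 1], len(sel), sel.mean() if len(sel) else np.nan))
    return pd.DataFrame(rows, columns=["dist_low", "dist_high", "n", "mean_r2"])


def prune_graph(records: pd.DataFrame, r2_threshold: float = 0.5, max_dist: int = 100_000):
    """Greedy LD pruning: return positions of kept sites.

    Build a graph with an edge between sites whose r2 exceeds the threshold
    (within ``max_dist``); repeatedly delete the node of highest degree
    (ties broken by larger r2-weighted degree, then by larger position)
    until no edges remain. Sites are identified by (chrom, pos); returns a
    DataFrame of kept sites in positional order.
    """
    rec = records[(records["dist"] <= max_dist) & (records["r2"] > r2_threshold)]
    nodes = set()
    for df in (records[["chrom", "posA"]].rename(columns={"posA": "pos"}),
               records[["chrom", "posB"]].rename(columns={"posB": "pos"})):
        nodes.update(map(tuple, df.to_numpy()))
    adj: dict = {n: {} for n in nodes}
    for row in rec.itertuples(index=False):
        a = (row.chrom, row.posA)
        b = (row.chrom, row.posB)
        adj[a][b] = row.r2
        adj[b][a] = row.r2
    removed = set()
    while True:
        best = None
        for n, nb in adj.items():
            if n in removed:
                continue
            deg = sum(1 for m in nb if m not in removed)
            if deg == 0:
                continue
            wdeg = sum(w for m, w in nb.items() if m not in removed)
            key = (deg, wdeg, n[1], n[0])
            if best is None or key > best[0]:
                best = (key, n)
        if best is None:
            break
        removed.add(best[1])
    kept = sorted(nodes - removed)
    return pd.DataFrame(kept, columns=["chrom", "pos"])


def ld_matrix(gl: GLMatrix, site_idx=None) -> np.ndarray:
    """Square r2 matrix over the given site indices (heatmap input)."""
    idx = np.arange(gl.n_sites) if site_idx is None else np.asarray(site_idx)
    n = len(idx)
    out = np.eye(n)
    for a, b in itertools.combinations(range(n), 2):
        _, _, _, r2 = haplotype_em_r2(gl.gl[idx[a]], gl.gl[idx[b]])
        out[a, b] = out[b, a] = r2
    return out
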