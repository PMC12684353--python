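"""Local-PCA scanning for megabase structural variants and their genotyping.

The scan computes PCA in consecutive windows of a fixed number of SNPs,
measures how different each window's individual-score geometry is from
every other window's (one minus the mean squared canonical correlation
between the retained score subspaces), embeds the windows by classical
MDS, and flags runs of windows whose coordinates are extreme relative to a
robust (median/MAD) spread as candidate non-recombining blocks.

Candidate regions are genotyped from the three-cluster geometry a
polymorphic inversion produces on PC1: the two flanking clusters are the
arrangement homozygotes, the middle one the heterozygotes, and the alpha
(more diverse) arrangement is the homozygote cluster with the larger PC2
spread. Per-deme genotype counts feed exact Hardy-Weinberg tests, Nei's
FST from arrangement frequencies, and between-homozygote dxy contrasts.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .geodist import DistMatrix
from .io import GLMatrix
from .structure import covariance_pca


@dataclasses.dataclass
class WindowPCA:
    window_id: int
    chrom: str
    first_pos: int
    last_pos: int
    n_snps: int
    scores: np.ndarray  # (N, k)
    short: bool = False


@dataclasses.dataclass
class SVRegion:
    id: str
    chrom: str
    start: int
    stop: int
    n_snps: int
    mds_axis: int
    windows: list[int]

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")


@dataclasses.dataclass
class SVGenotypes:
    genotypes: np.ndarray  # (N,) in {0,1,2} copies of alpha
    pc1: np.ndarray
    pc2: np.ndarray
    counts_by_deme: pd.DataFrame  # deme, n_aa, n_ab, n_bb, f_alpha
    alpha_cluster_sign: int  # +1 if alpha homozygotes sit at high PC1


def region_length_mbp(region: SVRegion | tuple) -> float:
    """Region length in Mbp, rounded to one decimal."""
    if isinstance(region, SVRegion):
        start, stop = region.start, region.stop
    else:
        start, stop = region
    return round((stop - start) / 1e6, 1)


def window_pca(gl: GLMatrix, snps_per_window: int, k: int = 2) -> list[WindowPCA]:
    """Covariance PCA in consecutive windows of ``snps_per_window`` SNPs.

    Windows are laid per chromosome in positional order; a trailing window
    shorter than the configured size is flagged. Chromosomes without any
    SNPs are skipped.
    """
    if snps_per_window < 10:
        raise ValueError("snps_per_window must be >= 10")
    out = []
    wid = 0
    chroms = pd.unique(gl.sites["chrom"])
    for c in chroms:
        idx = np.flatnonzero((gl.sites["chrom"] == c).to_numpy())
        idx = idx[np.argsort(gl.sites["pos"].to_numpy()[idx], kind="stable")]
        for lo in range(0, len(idx), snps_per_window):
            members = idx[lo : lo + snps_per_window]
            sub = gl.subset_sites(members)
            pca = covariance_pca(sub, n_axes=k)
            out.append(
                WindowPCA(
                    window_id=wid,
                    chrom=str(c),
                    first_pos=int(sub.sites["pos"].min()),
                    last_pos=int(sub.sites["pos"].max()),
                    n_snps=len(members),
                    scores=pca.scores[:, :k],
                    short=len(members) < snps_per_window,
                )
            )
            wid += 1
    return out


def _subspace_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """1 - mean squared canonical correlation between two score maps.

    Depends only on the spanned subspaces, so it is symmetric and invariant
    to sign flips and rotations of the window PCs.
    """
    q1, _ = np.linalg.qr(s1 - s1.mean(axis=0))
    q2, _ = np.linalg.qr(s2 - s2.mean(axis=0))
    sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
    k = min(s1.shape[1], s2.shape[1])
    return float(1 - np.sum(np.clip(sv, 0, 1) ** 2) / k)


def window_distance_mds(windows: list[WindowPCA], n_axes: int = 5):
    """Classical MDS of pairwise window dissimilarities.

    Returns ``(coords, dist)`` with ``coords`` (n_windows, n_axes).
    Identical windows give zero distances and zero coordinates.
    """
    W = len(windows)
    if W < 3:
        raise ValueError("need at least 3 windows")
    D = np.zeros((W, W))
    for i in range(W):
        for j in range(i + 1, W):
            D[i, j] = D[j, i] = _subspace_distance(windows[i].scores, windows[j].scores)
    J = np.eye(W) - np.ones((W, W)) / W
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    n_axes = min(n_axes, W)
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    return coords, D


def outlier_regions(
    coords: np.ndarray,
    windows: list[WindowPCA],
    z_cut: float = 4.0,
    min_run: int = 3,
) -> list[SVRegion]:
    """Merge runs of MDS-outlier windows into candidate SV regions.

    Per axis, a window is an outlier when |coord - median| exceeds
    ``z_cut`` robust standard deviations (1.4826 x MAD); runs of at least
    ``min_run`` consecutive outlier windows on the same chromosome and the
    same side of the median become one region spanning the first window's
    first SNP to the last window's last SNP.
    """
    coords = np.asarray(coords)
    regions = []
    order = np.argsort([w.window_id for w in windows])
    ws = [windows[i] for i in order]
    for axis in range(coords.shape[1]):
        x = coords[order, axis]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        scale = 1.4826 * mad
        if scale == 0:
            scale = x.std()
        if scale == 0:
            continue
        side = np.where(x - med > z_cut * scale, 1, np.where(med - x > z_cut * scale, -1, 0))
        run = []
        for i, w in enumerate(ws):
            extend = (
                side[i] != 0
                and run
                and side[i] == side[run[-1]]
                and w.chrom == ws[run[-1]].chrom
                and w.window_id == ws[run[-1]].window_id + 1
            )
            if extend:
                run.append(i)
            else:
                if len(run) >= min_run:
                    regions.append(_make_region(ws, run, axis, len(regions)))
                run = [i] if side[i] != 0 else []
        if len(run) >= min_run:
            regions.append(_make_region(ws, run, axis, len(regions)))
    return regions


def _make_region(ws, run, axis, n) -> SVRegion:
    first = ws[run[0]]
    last = ws[run[-1]]
    return SVRegion(
        id=f"sv{n}_{first.chrom}:{first.first_pos}",
        chrom=first.chrom,
        start=first.first_pos,
        stop=last.last_pos,
        n_snps=sum(ws[i].n_snps for i in run),
        mds_axis=axis + 1,
        windows=[ws[i].window_id for i in run],
    )


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two 1-based inclusive intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def _kmeans_1d(x: np.ndarray, max_iter: int = 100):
    """Lloyd's algorithm on a line, k=3, centers seeded at min/median/max."""
    centers = np.array([x.min(), np.median(x), x.max()], dtype=float)
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        new_labels = d.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in range(3):
            if np.any(labels == k):
                centers[k] = x[labels == k].mean()
    order = np.argsort(centers)
    remap = np.empty(3, dtype=int)
    remap[order] = np.arange(3)
    return remap[labels], centers[order]


class GenotypingError(ValueError):
    """Raised when a region's PC1 geometry does not show three clusters."""


def sv_pca_genotype(gl_region: GLMatrix, demes=None) -> SVGenotypes:
    """Genotype an SV from the three-cluster PCA geometry of its SNPs.

    PC1 is clustered with 1-D k-means (k=3, centers initialized at
    min/median/max); clusters ordered by center, the middle cluster is the
    heterozygote, and the alpha arrangement is the homozygote cluster with
    the larger within-cluster variance along PC2. Returns per-individual
    genotypes (copies of alpha) and per-deme counts and frequencies.
    Refuses with :class:`GenotypingError` when PC1 does not separate three
    clusters.
    """
    pca = covariance_pca(gl_region, n_axes=2)
    pc1 = pca.scores[:, 0]
    pc2 = pca.scores[:, 1]
    if len(np.unique(np.round(pc1, 10))) < 3:
        raise GenotypingError("fewer than 3 distinct PC1 values; no SV signal")
    labels, centers = _kmeans_1d(pc1)
    sizes = np.bincount(labels, minlength=3)
    if np.any(sizes == 0):
        raise GenotypingError(
            f"PC1 clustering degenerate (cluster sizes {sizes.tolist()}); "
            "region may be monomorphic for the arrangement"
        )
    # require an empty margin between consecutive clusters: a unimodal cloud
    # split by k-means has near-touching point sets at the boundaries
    rng_pc1 = np.ptp(pc1)
    for lo, hi in ((0, 1), (1, 2)):
        margin = pc1[labels == hi].min() - pc1[labels == lo].max()
        if margin < 0.15 * rng_pc1:
            raise GenotypingError(
                "PC1 clusters not separated; no three-cluster geometry"
            )
    var_pc2 = [np.var(pc2[labels == k]) for k in (0, 2)]
    alpha_high = var_pc2[1] > var_pc2[0]
    # genotype = copies of alpha: 2 for the alpha homozygote cluster, 1 het
    if alpha_high:
        geno = np.where(labels == 2, 2, np.where(labels == 1, 1, 0))
    else:
        geno = np.where(labels == 0, 2, np.where(labels == 1, 1, 0))
    demes = gl_region.demes if demes is None else np.asarray(demes)
    if demes is None:
        demes = np.zeros(gl_region.n_ind, dtype=int)
    rows = []
    for d in pd.unique(demes):
        g = geno[demes == d]
        n_aa = int(np.sum(g == 2))
        n_ab = int(np.sum(g == 1))
        n_bb = int(np.sum(g == 0))
        n = n_aa + n_ab + n_bb
        rows.append((d, n_aa, n_ab, n_bb, (2 * n_aa + n_ab) / (2 * n)))
    counts = pd.DataFrame(rows, columns=["deme", "n_aa", "n_ab", "n_bb", "f_alpha"])
    return SVGenotypes(
        genotypes=geno,
        pc1=pc1,
        pc2=pc2,
        counts_by_deme=counts,
        alpha_cluster_sign=1 if alpha_high else -1,
    )


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums, over heterozygote counts h compatible with the observed allele
    totals, the probabilities P(h) <= P(observed), where
    P(h | n, n_minor) = n! / (n_AA! h! n_aa!) * 2^h * n_minor! n_major! / (2n)!.
    Monomorphic samples give p = 1.
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one individual")
    n_a = 2 * n_aa + n_ab  # minor-allele copies (either labelling works)
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    def logp(h):
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        return (
            math.lgamma(n + 1)
            - math.lgamma(naa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(nbb + 1)
            + h * math.log(2)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([logp(int(h)) for h in hs])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[hs == n_ab][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def nei_fst(f_alpha, labels=None) -> DistMatrix:
    """Pairwise Nei FST = (HT - HS) / HT from per-deme allele frequencies.

    HS is the mean of the two demes' expected heterozygosities 2f(1-f);
    HT uses the unweighted mean frequency. HT = 0 gives FST = 0.
    """
    f = np.asarray(f_alpha, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    n = len(f)
    labels = [str(i) for i in range(n)] if labels is None else list(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            hs = (2 * f[i] * (1 - f[i]) + 2 * f[j] * (1 - f[j])) / 2
            fbar = (f[i] + f[j]) / 2
            ht = 2 * fbar * (1 - fbar)
            fst = (ht - hs) / ht if ht > 0 else 0.0
            out[i, j] = out[j, i] = fst
    return DistMatrix(labels=labels, values=out)


def dxy_contrast(p_a: np.ndarray, p_b: np.ndarray, inside_mask: np.ndarray) -> pd.DataFrame:
    """Per-SNP dxy between two groups, averaged inside vs outside a region.

    dxy_s = p_A (1 - p_B) + p_B (1 - p_A); groups are typically the alpha/
    alpha and beta/beta individuals.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    inside = np.asarray(inside_mask, dtype=bool)
    dxy = p_a * (1 - p_b) + p_b * (1 - p_a)
    return pd.DataFrame(
        {
            "where": ["inside", "outside"],
            "n_snps": [int(inside.sum()), int((~inside).sum())],
            "mean_dxy": [
                dxy[inside].mean() if inside.any() else np.nan,
                dxy[~inside].mean() if (~inside).any() else np.nan,
            ],
        }
    )
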