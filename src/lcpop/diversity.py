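"""Site-frequency-spectrum machinery and diversity statistics.

The site-allele-frequency (SAF) likelihood of a deme of n diploids is the
probability of the deme's read data given that j of its 2n allele copies
are the minor allele, computed by a dynamic-programming convolution of the
individual likelihood triplets with binomial configuration weights. The
SFS is estimated from SAF likelihoods by EM (1-D, or 2-D for a pair of
demes); Watterson's theta, pi and Tajima's D follow from the spectrum with
the standard constants. Weighted FST uses the Hudson/Bhatia per-site
components ratio-of-sums estimator, genome-wide and in fixed windows.
Pairwise relatedness is a three-state IBD-proportion EM with
r = k2 + k1 / 2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genolik import estimate_maf_em_many
from .io import GLMatrix

MAX_SFS_ITER = 500
SFS_TOL = 1e-8


def saf_likelihoods(gl_arr: np.ndarray, normalize: bool = True) -> np.ndarray:
    """SAF likelihood vectors for one deme, shape (S, 2n+1).

    Convolves the likelihood triplets over individuals: the polynomial
    product prod_i [L_i(0) + 2 L_i(1) x + L_i(2) x^2] gives, for each total
    count j, the sum over genotype configurations weighted by the number of
    ways to realize them; dividing by C(2n, j) yields P(data | j minor
    copies). Missing individuals (flat triplets) contribute a flat factor.
    """
    gl_arr = np.asarray(gl_arr, dtype=float)
    S, n, _ = gl_arr.shape
    if n < 1:
        raise ValueError("deme must have at least one individual")
    # work in linear space with per-site rescaling for stability
    poly = np.zeros((S, 2 * n + 1))
    poly[:, 0] = 1.0
    width = 1
    for i in range(n):
        c0 = gl_arr[:, i, 0][:, None]
        c1 = 2 * gl_arr[:, i, 1][:, None]
        c2 = gl_arr[:, i, 2][:, None]
        new = np.zeros_like(poly)
        new[:, :width] += poly[:, :width] * c0
        new[:, 1 : width + 1] += poly[:, :width] * c1
        new[:, 2 : width + 2] += poly[:, :width] * c2
        poly = new
        width += 2
        m = poly.max(axis=1, keepdims=True)
        m[m == 0] = 1
        poly /= m
    j = np.arange(2 * n + 1)
    log_binom = gammaln(2 * n + 1) - gammaln(j + 1) - gammaln(2 * n - j + 1)
    saf = poly / np.exp(log_binom)[None, :]
    if normalize:
        m = saf.max(axis=1, keepdims=True)
        m[m == 0] = 1
        saf = saf / m
    return saf


def sfs_em(
    saf: np.ndarray,
    saf2: np.ndarray | None = None,
    max_iter: int = MAX_SFS_ITER,
    tol: float = SFS_TOL,
    return_trace: bool = False,
):
    """EM estimate of the (1-D or 2-D) site frequency spectrum.

    Maximizes sum_sites log sum_j phi_j SAF_sj over the probability vector
    phi (outer product of bins for the 2-D case); returns expected *site
    counts* (phi times the number of sites). Convergence when the max
    absolute change of normalized phi is below ``tol``.
    """
    saf = np.asarray(saf, dtype=float)
    S = saf.shape[0]
    if S == 0:
        raise ValueError("no sites")
    if saf2 is not None:
        saf2 = np.asarray(saf2, dtype=float)
        A = saf[:, :, None] * saf2[:, None, :]
        A = A.reshape(S, -1)
        shape = (saf.shape[1], saf2.shape[1])
    else:
        A = saf
        shape = (saf.shape[1],)
    if np.any(A.sum(axis=1) <= 0):
        raise ValueError("site with all-zero SAF likelihood")
    if np.all(np.ptp(A, axis=1) <= 1e-9 * A.max(axis=1)):
        raise ValueError("degenerate input: every site's SAF is flat (all data missing)")
    B = A.shape[1]
    phi = np.full(B, 1.0 / B)
    trace = []
    for _ in range(max_iter):
        w = A * phi[None, :]
        tot = w.sum(axis=1)
        if return_trace:
            trace.append(np.log(tot).sum())
        phi_new = (w / tot[:, None]).sum(axis=0) / S
        delta = np.max(np.abs(phi_new - phi))
        phi = phi_new
        if delta < tol:
            break
    if return_trace:
        trace.append(np.log((A * phi[None, :]).sum(axis=1)).sum())
        return (phi * S).reshape(shape), np.array(trace)
    return (phi * S).reshape(shape)


@dataclasses.dataclass
class ThetaStats:
    theta_w: float  # total over sites
    pi: float
    tajima_d: float
    theta_w_per_site: float
    pi_per_site: float
    n_sites: float
    segregating: float


def theta_stats(sfs: np.ndarray, n_diploids: int | None = None) -> ThetaStats:
    """Watterson's theta, pi and Tajima's D from an SFS of expected counts.

    The spectrum may be folded or unfolded over bins 0..2n: both the
    segregating-site count and the pairwise-diversity weights i(2n - i) are
    symmetric under folding. ``n_diploids`` defaults to (len(sfs)-1)/2.
    For a single diploid theta_w and pi are still defined but Tajima's D
    has zero variance constants and is flagged NaN.
    """
    sfs = np.asarray(sfs, dtype=float)
    n2 = len(sfs) - 1
    if n_diploids is not None and 2 * n_diploids != n2:
        raise ValueError("sfs length inconsistent with n_diploids")
    if n2 < 2:
        raise ValueError("spectrum must cover at least one diploid (3 bins)")
    nseq = n2  # number of sequences
    i = np.arange(1, nseq)
    S_seg = sfs[1:nseq].sum()
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    theta_w = S_seg / a1
    pi = (i * (nseq - i) * sfs[1:nseq]).sum() / (nseq * (nseq - 1) / 2)
    b1 = (nseq + 1) / (3 * (nseq - 1))
    b2 = 2 * (nseq**2 + nseq + 3) / (9 * nseq * (nseq - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (nseq + 2) / (a1 * nseq) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S_seg + e2 * S_seg * (S_seg - 1)
    d = (pi - theta_w) / np.sqrt(var) if var > 0 else np.nan
    total = sfs.sum()
    return ThetaStats(
        theta_w=theta_w,
        pi=pi,
        tajima_d=d,
        theta_w_per_site=theta_w / total if total else np.nan,
        pi_per_site=pi / total if total else np.nan,
        n_sites=total,
        segregating=S_seg,
    )


def individual_heterozygosity(ind_sfs: np.ndarray) -> float:
    """Percent heterozygous sites from an individual's (hom, het, hom) SFS."""
    ind_sfs = np.asarray(ind_sfs, dtype=float)
    if ind_sfs.shape != (3,):
        raise ValueError("individual SFS must have 3 bins")
    total = ind_sfs.sum()
    if total <= 0:
        raise ValueError("no sites with information")
    return 100.0 * ind_sfs[1] / total


def heterozygosity_from_gl(gl: GLMatrix, individual: int) -> float:
    """Estimate one individual's heterozygosity via its 3-bin SFS EM."""
    saf = saf_likelihoods(gl.gl[:, [individual], :])
    sfs = sfs_em(saf)
    return individual_heterozygosity(sfs)


def hudson_components(p1, p2, n1_alleles, n2_alleles):
    """Per-site Hudson/Bhatia alpha and beta from sample allele frequencies.

    ``n*_alleles`` are haploid sample sizes (2 x diploids). alpha estimates
    the numerator (p1 - p2)^2 minus finite-sample corrections; beta is
    p1 (1 - p2) + p2 (1 - p1).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    alpha = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1_alleles - 1)
        - p2 * (1 - p2) / (n2_alleles - 1)
    )
    beta = p1 * (1 - p2) + p2 * (1 - p1)
    return alpha, beta


@dataclasses.dataclass
class FstResult:
    fst: float
    alpha_sum: float
    beta_sum: float
    windows: pd.DataFrame | None = None


def fst_weighted(
    gl1: GLMatrix | None = None,
    gl2: GLMatrix | None = None,
    freqs1=None,
    freqs2=None,
    n1_diploids: int | None = None,
    n2_diploids: int | None = None,
    positions=None,
    chrom=None,
    window_bp: int | None = None,
    sfs2d: np.ndarray | None = None,
    saf1: np.ndarray | None = None,
    saf2: np.ndarray | None = None,
) -> FstResult:
    """Weighted (ratio-of-sums) Hudson FST between two demes.

    Fast mode: supply per-deme GLMatrix panels (frequencies estimated by
    EM) or plug-in frequencies. Posterior mode: supply SAF likelihood
    arrays plus the 2-D SFS prior; per-site frequencies are posterior
    means of allele counts. Windows (fixed, non-overlapping, anchored at
    position 1, 1-based inclusive) are emitted when ``window_bp`` is set;
    windows without SNPs get NaN.
    """
    if saf1 is not None:
        if sfs2d is None or saf2 is None:
            raise ValueError("posterior mode needs saf1, saf2 and sfs2d")
        prior = sfs2d / sfs2d.sum()
        n1b = saf1.shape[1] - 1
        n2b = saf2.shape[1] - 1
        post = saf1[:, :, None] * saf2[:, None, :] * prior[None, :, :]
        post /= post.sum(axis=(1, 2), keepdims=True)
        p1 = (post.sum(axis=2) * np.arange(n1b + 1)[None, :]).sum(axis=1) / n1b
        p2 = (post.sum(axis=1) * np.arange(n2b + 1)[None, :]).sum(axis=1) / n2b
        n1a, n2a = n1b, n2b
    else:
        if gl1 is not None:
            freqs1 = estimate_maf_em_many(gl1.gl)
            n1_diploids = gl1.n_ind
            positions = gl1.sites["pos"].to_numpy() if positions is None else positions
            chrom = gl1.sites["chrom"].to_numpy() if chrom is None else chrom
        if gl2 is not None:
            freqs2 = estimate_maf_em_many(gl2.gl)
            n2_diploids = gl2.n_ind
        if n1_diploids < 2 or n2_diploids < 2:
            raise ValueError("both demes need at least two diploids")
        p1, p2 = np.asarray(freqs1), np.asarray(freqs2)
        n1a, n2a = 2 * n1_diploids, 2 * n2_diploids
    alpha, beta = hudson_components(p1, p2, n1a, n2a)
    fst = alpha.sum() / beta.sum() if beta.sum() > 0 else np.nan

    windows = None
    if window_bp is not None:
        if positions is None:
            raise ValueError("window output needs site positions")
        pos = np.asarray(positions)
        ch = np.asarray(chrom) if chrom is not None else np.full(len(pos), "chr1")
        rows = []
        for c in pd.unique(ch):
            m = ch == c
            last = pos[m].max()
            n_win = int(np.ceil(last / window_bp))
            widx = (pos[m] - 1) // window_bp
            for w in range(n_win):
                sel = widx == w
                a = alpha[m][sel].sum()
                b = beta[m][sel].sum()
                rows.append(
                    (
                        c,
                        w * window_bp + 1,
                        (w + 1) * window_bp,
                        int(sel.sum()),
                        a / b if sel.sum() and b > 0 else np.nan,
                    )
                )
        windows = pd.DataFrame(rows, columns=["chrom", "start", "stop", "n_snps", "fst"])
    return FstResult(fst=fst, alpha_sum=alpha.sum(), beta_sum=beta.sum(), windows=windows)


# --- pairwise relatedness -------------------------------------------------

def _ibd_genotype_tables(f: np.ndarray) -> np.ndarray:
    """P(g_i, g_j | IBD state, site freq): array (S, 3 states, 3, 3).

    Allele frequency ``f`` refers to the allele counted by the genotypes.
    """
    p = np.asarray(f, dtype=float)
    q = 1 - p
    S = p.shape[0]
    hw = np.stack([q**2, 2 * p * q, p**2], axis=1)  # (S, 3)
    T = np.zeros((S, 3, 3, 3))
    # state 0: independent genotypes
    T[:, 0] = hw[:, :, None] * hw[:, None, :]
    # state 1: share exactly one allele
    T[:, 1, 0, 0] = q**3
    T[:, 1, 0, 1] = p * q**2
    T[:, 1, 1, 0] = p * q**2
    T[:, 1, 1, 1] = p * q
    T[:, 1, 1, 2] = p**2 * q
    T[:, 1, 2, 1] = p**2 * q
    T[:, 1, 2, 2] = p**3
    # state 2: identical genotypes with HWE marginal
    T[:, 2, 0, 0] = q**2
    T[:, 2, 1, 1] = 2 * p * q
    T[:, 2, 2, 2] = p**2
    return T


def relatedness_pair(
    gl_i: np.ndarray,
    gl_j: np.ndarray,
    freqs: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-7,
    return_trace: bool = False,
):
    """IBD-proportion EM for one pair of individuals.

    ``gl_i``/``gl_j`` are (S, 3) likelihood triplets, ``freqs`` the
    population frequency of the minor-coded allele per site. Returns
    ``(k0, k1, k2, r)`` with r = k2 + k1/2; the k's stay on the simplex at
    every iteration.
    """
    gl_i = np.asarray(gl_i, dtype=float)
    gl_j = np.asarray(gl_j, dtype=float)
    T = _ibd_genotype_tables(np.clip(np.asarray(freqs, dtype=float), 1e-6, 1 - 1e-6))
    # site-state likelihood: sum_{gi,gj} gl_i(gi) gl_j(gj) T[state, gi, gj]
    L = np.einsum("si,sj,smij->sm", gl_i, gl_j, T)
    k = np.array([1 / 3, 1 / 3, 1 / 3])
    trace = []
    for _ in range(max_iter):
        w = L * k[None, :]
        tot = w.sum(axis=1)
        if return_trace:
            trace.append(np.log(tot).sum())
        k_new = (w / tot[:, None]).mean(axis=0)
        k_new /= k_new.sum()
        delta = np.max(np.abs(k_new - k))
        k = k_new
        if delta < tol:
            break
    r = k[2] + k[1] / 2
    if return_trace:
        trace.append(np.log((L * k[None, :]).sum(axis=1)).sum())
        return k[0], k[1], k[2], r, np.array(trace)
    return k[0], k[1], k[2], r


def relatedness_all_pairs(gl: GLMatrix, freqs=None) -> pd.DataFrame:
    """Relatedness table ``indA indB k0 k1 k2 r`` over all pairs."""
    f = estimate_maf_em_many(gl.gl) if freqs is None else np.asarray(freqs)
    rows = []
    for i in range(gl.n_ind):
        for j in range(i + 1, gl.n_ind):
            k0, k1, k2, r = relatedness_pair(gl.gl[:, i], gl.gl[:, j], f)
            rows.append((gl.individuals[i], gl.individuals[j], k0, k1, k2, r))
    return pd.DataFrame(rows, columns=["indA", "indB", "k0", "k1", "k2", "r"])
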