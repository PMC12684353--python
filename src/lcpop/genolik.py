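"""Genotype likelihoods, allele-frequency EM, SNP discovery and filtering.

The likelihood model is the classic per-read error model for a diploid at a
biallelic site: a read base ``b`` has probability ``1 - eps`` of matching a
homozygote's allele and ``eps/3`` of being any specific other base; under a
heterozygote the two alleles each contribute with weight 1/2. The likelihood
of a genotype is the product over reads, so only the per-base counts matter.

Allele frequencies are estimated per site by an EM iteration under a
Hardy-Weinberg prior, and SNPs are discovered with a likelihood-ratio test
of ``f = f_hat`` against ``f = 0`` referred to a chi-square with 1 df.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import GLMatrix, PileupCounts, BASES, _allele_codes

MAX_EM_ITER = 200
EM_TOL = 1e-8


def _xlogy(x, y):
    """x * log(y) with the convention 0 * log(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x * np.log(y)
    return np.where(x == 0, 0.0, out)


def genotype_likelihoods(
    counts: PileupCounts,
    eps: float,
    major,
    minor,
    demes=None,
) -> GLMatrix:
    """Compute normalized genotype-likelihood triplets from base counts.

    Parameters
    ----------
    counts
        Per-site, per-individual A/C/G/T counts.
    eps
        Per-base error rate, in [0, 0.25).
    major, minor
        Per-site allele pair, as base letters or 0..3 codes.

    Reads of bases other than the two alleles contribute the same factor
    ``eps/3`` to all three genotypes and therefore cancel after
    normalization; they are included so unnormalized likelihoods match the
    direct product over reads. Zero-depth site-individuals get (1, 1, 1).
    """
    if not 0 <= eps < 0.25:
        raise ValueError("error rate must lie in [0, 0.25)")
    a1 = _allele_codes(major)
    a2 = _allele_codes(minor)
    if np.any(a1 == a2):
        raise ValueError("major and minor alleles must differ")
    c = counts.counts
    S, N, _ = c.shape
    n1 = np.take_along_axis(c, a1[:, None, None].repeat(N, 1), axis=2)[:, :, 0]
    n2 = np.take_along_axis(c, a2[:, None, None].repeat(N, 1), axis=2)[:, :, 0]
    no = c.sum(axis=2) - n1 - n2

    p_match = 1.0 - eps
    p_mis = eps / 3.0
    p_het = 0.5 * p_match + 0.5 * p_mis

    ll = np.empty((S, N, 3))
    ll[:, :, 0] = _xlogy(n1, p_match) + _xlogy(n2 + no, p_mis)
    ll[:, :, 1] = _xlogy(n1 + n2, p_het) + _xlogy(no, p_mis)
    ll[:, :, 2] = _xlogy(n2, p_match) + _xlogy(n1 + no, p_mis)

    ll -= ll.max(axis=2, keepdims=True)
    gl = np.exp(ll)
    sites = pd.DataFrame(
        {
            "chrom": counts.chrom,
            "pos": counts.pos,
            "major": BASES[a1],
            "minor": BASES[a2],
        }
    )
    return GLMatrix(sites=sites, individuals=list(counts.individuals), gl=gl, demes=demes)


def _hwe_prior(f: np.ndarray) -> np.ndarray:
    """Stack of HWE genotype priors ((1-f)^2, 2f(1-f), f^2); f is (S,)."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def site_loglik(gl: np.ndarray, f) -> np.ndarray:
    """Marginal log-likelihood of per-site allele frequencies f under HWE.

    ``gl`` is (S, N, 3); returns (S,). Constant per-triplet scalings cancel
    in all downstream likelihood ratios.
    """
    prior = _hwe_prior(np.broadcast_to(np.asarray(f, dtype=float), (gl.shape[0],)))
    persite = (gl * prior[:, None, :]).sum(axis=2)
    with np.errstate(divide="ignore"):
        return np.log(persite).sum(axis=1)


def estimate_maf_em_many(
    gl: np.ndarray,
    max_iter: int = MAX_EM_ITER,
    tol: float = EM_TOL,
    return_trace: bool = False,
):
    """Allele-frequency EM for every site of a (S, N, 3) likelihood array.

    Iterates f <- (1/2N) * sum_i E[g_i | gl_i, f] under the HWE prior until
    max |delta f| < tol or ``max_iter`` iterations. Returns the frequency of
    the allele coded as "minor" in the triplet orientation (which may exceed
    0.5; see :func:`discover_snps` for re-orientation). Sites where every
    individual is missing are flagged NaN. With ``return_trace=True`` also
    returns the per-iteration total log-likelihood (non-decreasing).
    """
    gl = np.asarray(gl, dtype=float)
    S, N, _ = gl.shape
    if N < 1:
        raise ValueError("need at least one individual")
    tot = gl.sum(axis=2)
    if np.any(tot == 0):
        raise ValueError("invalid likelihood triplet summing to zero")
    # moment-style initialization from normalized triplets
    f = ((0.5 * gl[:, :, 1] + gl[:, :, 2]) / tot).mean(axis=1)
    f = np.clip(f, 1e-6, 1 - 1e-6)
    trace = []
    for _ in range(max_iter):
        prior = _hwe_prior(f)
        w = gl * prior[:, None, :]
        wsum = w.sum(axis=2)
        if return_trace:
            with np.errstate(divide="ignore"):
                trace.append(np.log(wsum).sum())
        eg = (w[:, :, 1] + 2 * w[:, :, 2]) / wsum
        f_new = eg.sum(axis=1) / (2 * N)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    flat = (np.abs(gl[:, :, 0] - gl[:, :, 1]) < 1e-12) & (
        np.abs(gl[:, :, 1] - gl[:, :, 2]) < 1e-12
    )
    f = np.where(flat.all(axis=1), np.nan, f)
    if return_trace:
        trace.append(site_loglik(gl, np.nan_to_num(f, nan=0.5)).sum())
        return f, np.array(trace)
    return f


def estimate_maf_em(gl_site: np.ndarray, **kwargs):
    """Single-site convenience wrapper around :func:`estimate_maf_em_many`."""
    gl_site = np.asarray(gl_site, dtype=float)
    out = estimate_maf_em_many(gl_site[None], **kwargs)
    if isinstance(out, tuple):
        return out[0][0], out[1]
    return out[0]


def snp_lrt_many(gl: np.ndarray, f_hat: np.ndarray):
    """Likelihood-ratio SNP test per site.

    Lambda = 2 [l(f_hat) - l(f=0)], clipped at 0; p from the chi-square
    (1 df) upper tail. Monomorphic certain data gives Lambda = 0, p = 1.
    """
    l1 = site_loglik(gl, f_hat)
    l0 = site_loglik(gl, np.zeros(gl.shape[0]))
    lam = np.clip(2 * (l1 - l0), 0, None)
    return lam, stats.chi2.sf(lam, df=1)


def snp_lrt(gl_site: np.ndarray, f_hat: float | None = None):
    """Single-site SNP likelihood-ratio test; estimates f if not supplied."""
    gl_site = np.asarray(gl_site, dtype=float)
    if f_hat is None:
        f_hat = estimate_maf_em(gl_site)
    lam, p = snp_lrt_many(gl_site[None], np.array([f_hat]))
    return lam[0], p[0]


def allele_freq_em4(pooled_counts: np.ndarray, eps: float, max_iter: int = MAX_EM_ITER, tol: float = EM_TOL) -> np.ndarray:
    """Four-allele frequency EM from pooled per-site read counts (S, 4).

    Reads arise from an allele a with frequency phi_a and are observed as b
    with probability (1-eps) if b == a else eps/3. Used to flag sites where
    a third allele is segregating.
    """
    n = np.asarray(pooled_counts, dtype=float)
    S = n.shape[0]
    M = np.full((4, 4), eps / 3.0)
    np.fill_diagonal(M, 1.0 - eps)
    tot = n.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        phi = np.where(tot > 0, n / tot, 0.25)
    for _ in range(max_iter):
        # r[s, a, b]: posterior that a read observed as b came from allele a
        joint = phi[:, :, None] * M[None, :, :]
        denom = joint.sum(axis=1, keepdims=True)
        r = np.where(denom > 0, joint / denom, 0.25)
        counts_a = (r * n[:, None, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            phi_new = np.where(tot > 0, counts_a / tot, 0.25)
        if np.max(np.abs(phi_new - phi)) < tol:
            phi = phi_new
            break
        phi = phi_new
    return phi


@dataclasses.dataclass
class SNPFilters:
    """Thresholds for the SNP filter stack.

    Depth bounds are absolute read totals across individuals; with N
    individuals at ~1-2x coverage, sensible defaults are min = N and
    max = 2N (set when ``None``). An individual's reads only count toward
    the total when its depth is at least ``min_ind_depth``.
    """

    min_total_depth: int | None = None
    max_total_depth: int | None = None
    min_ind_depth: int = 1
    min_maf: float = 0.05
    snp_pval: float = 1e-6
    max_third_allele: float = 0.05


def discover_snps(
    counts: PileupCounts,
    eps: float,
    major,
    minor,
    filters: SNPFilters | None = None,
    demes=None,
):
    """Apply the SNP filter stack and return the passing panel.

    A site passes iff, in order: total depth within [min, max]; minor allele
    frequency above ``min_maf``; SNP LRT p-value below ``snp_pval``; and
    estimated third-allele frequency at most ``max_third_allele``. Returns
    ``(GLMatrix, report)`` where the report counts removals per rule in the
    order applied (each site attributed to the first rule it fails).
    Likelihood triplets are re-oriented so maf <= 0.5.
    """
    filters = filters or SNPFilters()
    N = counts.n_ind
    min_d = filters.min_total_depth if filters.min_total_depth is not None else N
    max_d = filters.max_total_depth if filters.max_total_depth is not None else 2 * N
    if min_d > max_d:
        raise ValueError("min_total_depth exceeds max_total_depth")

    gl = genotype_likelihoods(counts, eps, major, minor, demes=demes)
    depth = counts.depth()
    counted = np.where(depth >= filters.min_ind_depth, depth, 0)
    total_depth = counted.sum(axis=1)

    f = estimate_maf_em_many(gl.gl)
    # orient to the minor allele: swap labels where f > 0.5
    swap = f > 0.5
    maf = np.where(swap, 1 - f, f)
    gl_arr = gl.gl.copy()
    gl_arr[swap] = gl_arr[swap][:, :, ::-1]
    sites = gl.sites.copy()
    sites.loc[swap, ["major", "minor"]] = sites.loc[swap, ["minor", "major"]].to_numpy()
    f_or = np.where(swap, 1 - f, f)
    _, pval = snp_lrt_many(gl_arr, f_or)
    sites["maf"] = maf
    sites["lrt_p"] = pval

    pooled = np.where(depth[:, :, None] >= filters.min_ind_depth, counts.counts, 0).sum(axis=1)
    phi = allele_freq_em4(pooled, eps)
    third = np.sort(phi, axis=1)[:, 1]  # third-largest of 4

    rules = [
        ("min_total_depth", total_depth < min_d),
        ("max_total_depth", total_depth > max_d),
        ("min_maf", ~(maf > filters.min_maf)),  # NaN maf (all-missing) fails
        ("snp_pval", ~(pval < filters.snp_pval)),
        ("triallelic", third > filters.max_third_allele),
    ]
    removed_by = np.full(len(sites), -1)
    for i, (_, fails) in enumerate(rules):
        newly = (removed_by == -1) & fails
        removed_by[newly] = i
    report = pd.DataFrame(
        {
            "rule": [name for name, _ in rules],
            "removed": [(removed_by == i).sum() for i in range(len(rules))],
        }
    )
    keep = removed_by == -1
    out = GLMatrix(
        sites=sites.loc[keep].reset_index(drop=True),
        individuals=list(gl.individuals),
        gl=gl_arr[keep],
        demes=demes,
    )
    return out, report


def posterior_mean_genotypes(gl: np.ndarray, f: np.ndarray) -> np.ndarray:
    """E[g | gl, HWE(f)] per site x individual; the dosage used by PCA."""
    prior = _hwe_prior(f)
    w = np.asarray(gl) * prior[:, None, :]
    return (w[:, :, 1] + 2 * w[:, :, 2]) / w.sum(axis=2)
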