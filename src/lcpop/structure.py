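"""Individual-level population structure from genotype likelihoods.

PCA is computed from a covariance matrix of standardized posterior-mean
genotypes (dosages) under a Hardy-Weinberg prior at the global allele
frequency of each site. Admixture proportions are estimated with the
standard likelihood model for K ancestral components, marginalizing hard
genotypes through the likelihood triplets, with a multi-seed convergence
rule: a run is declared converged when the best and third-best seed
log-likelihoods agree within two units. A per-site selection scan refers
N * r2 between dosages and a principal axis to a chi-square with 1 df, and
a diagnostic regression quantifies how much of each axis is explained by
per-individual missingness.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genolik import estimate_maf_em_many, posterior_mean_genotypes
from .io import GLMatrix


@dataclasses.dataclass
class PCAResult:
    covariance: np.ndarray
    scores: np.ndarray  # (N, K)
    var_explained: np.ndarray
    eigenvalues: np.ndarray
    used_sites: np.ndarray  # boolean mask of sites entering the covariance
    dosages: np.ndarray | None = None  # (S_used, N) posterior-mean genotypes
    freqs: np.ndarray | None = None


@dataclasses.dataclass
class AdmixResult:
    Q: np.ndarray  # (N, K)
    F: np.ndarray  # (S, K)
    loglik: float
    logliks_per_seed: np.ndarray
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray | None = None


def covariance_pca(gl: GLMatrix, n_axes: int | None = None, freqs=None) -> PCAResult:
    """PCA from the dosage covariance matrix.

    C_ij = (1/S) sum_s (E[g_is] - 2 f_s)(E[g_js] - 2 f_s) / (2 f_s (1 - f_s))
    with E[g] the posterior-mean genotype under HWE at the site's estimated
    global frequency. Sites with f in {0, 1} carry no information and are
    skipped with a warning. Axes are ordered by eigenvalue;
    ``var_explained`` is eigenvalue / trace.
    """
    if gl.n_ind < 2 or gl.n_sites < 1:
        raise ValueError("need >= 2 individuals and >= 1 site")
    f = estimate_maf_em_many(gl.gl) if freqs is None else np.asarray(freqs, dtype=float)
    ok = (f > 1e-6) & (f < 1 - 1e-6)
    if not ok.all():
        warnings.warn(f"skipping {np.sum(~ok)} monomorphic site(s) in PCA")
    if ok.sum() == 0:
        raise ValueError("no polymorphic sites")
    all_missing = gl.missing_mask().all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} individual(s) have no data; their "
            "dosages shrink to the prior mean and scores sit near the origin"
        )
    e = posterior_mean_genotypes(gl.gl[ok], f[ok])
    z = (e - 2 * f[ok, None]) / np.sqrt(2 * f[ok, None] * (1 - f[ok, None]))
    C = z.T @ z / ok.sum()
    C = (C + C.T) / 2
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    trace = np.clip(evals, 0, None).sum()
    var = np.clip(evals, 0, None) / trace if trace > 0 else np.zeros_like(evals)
    k = gl.n_ind if n_axes is None else min(n_axes, gl.n_ind)
    scores = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))
    return PCAResult(
        covariance=C,
        scores=scores,
        var_explained=var[:k],
        eigenvalues=evals,
        used_sites=ok,
        dosages=e,
        freqs=f,
    )


def _admix_loglik(gl_arr, Q, F):
    pi = np.clip(F @ Q.T, 1e-9, 1 - 1e-9)  # (S, N)
    lik = (
        gl_arr[:, :, 0] * (1 - pi) ** 2
        + gl_arr[:, :, 1] * 2 * pi * (1 - pi)
        + gl_arr[:, :, 2] * pi**2
    )
    return np.log(lik).sum()


def admixture_em(
    gl: GLMatrix,
    K: int,
    n_seeds: int = 3,
    max_iter: int = 2000,
    tol: float = 1e-4,
    seed: int = 0,
    return_trace: bool = False,
) -> AdmixResult:
    """Admixture-proportion EM with the multi-seed convergence rule.

    The model: individual i's allele frequency at site s is
    pi_is = sum_k q_ik f_ks; genotypes are Binomial(2, pi) under HWE and are
    marginalized through the likelihood triplets. Each seed runs EM to
    ``max_iter`` (or until the log-likelihood gain per iteration drops
    below ``tol``); ``converged`` is True when the
    top and third-ranked seed log-likelihoods differ by at most two units
    (requires n_seeds >= 3). The best seed's result is returned, with
    Q rows summing to 1 exactly.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gl.n_ind:
        raise ValueError("K cannot exceed the number of individuals")
    gl_arr = gl.gl
    S, N, _ = gl_arr.shape
    if K == 1:
        f = estimate_maf_em_many(gl_arr)
        Q = np.ones((N, 1))
        F = f[:, None]
        ll = _admix_loglik(gl_arr, Q, F)
        return AdmixResult(Q, F, ll, np.array([ll]), True, 0,
                           np.array([ll]) if return_trace else None)

    rng_master = np.random.default_rng(seed)
    best = None
    logliks = []
    gl0, gl1, gl2 = gl_arr[:, :, 0], gl_arr[:, :, 1], gl_arr[:, :, 2]
    for s in range(max(n_seeds, 1)):
        rng = np.random.default_rng(rng_master.integers(2**31))
        Q = rng.dirichlet(np.ones(K), size=N)
        F = np.clip(rng.random((S, K)), 0.05, 0.95)
        trace = []
        ll_prev = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            pi = np.clip(F @ Q.T, 1e-9, 1 - 1e-9)  # (S, N)
            l0 = gl0 * (1 - pi) ** 2
            l1 = gl1 * 2 * pi * (1 - pi)
            l2 = gl2 * pi**2
            tot = l0 + l1 + l2
            ll = np.log(tot).sum()
            trace.append(ll)
            eg = (l1 + 2 * l2) / tot  # E[genotype | data, current params]
            # expected allele copies attributed to each component: the
            # derived copies split in proportion q_ik f_ks / pi_is, the
            # ancestral in proportion q_ik (1 - f_ks) / (1 - pi_is)
            t1 = eg / pi  # (S, N)
            t2 = (2 - eg) / (1 - pi)
            der = F * (t1 @ Q)  # (S, K) expected derived copies
            anc = (1 - F) * (t2 @ Q)
            F_new = np.clip(der / np.clip(der + anc, 1e-12, None), 1e-6, 1 - 1e-6)
            q_counts = Q * (t1.T @ F + t2.T @ (1 - F))  # (N, K)
            Q_new = q_counts / q_counts.sum(axis=1, keepdims=True)
            Q, F = Q_new, F_new
            if abs(ll - ll_prev) < tol:
                break
            ll_prev = ll
        ll_final = _admix_loglik(gl_arr, Q, F)
        trace.append(ll_final)
        logliks.append(ll_final)
        if best is None or ll_final > best[0]:
            best = (ll_final, Q, F, it, np.array(trace))
    logliks = np.array(logliks)
    top3 = np.sort(logliks)[::-1][: min(3, len(logliks))]
    converged = len(logliks) >= 3 and (top3[0] - top3[-1]) <= 2.0
    ll_best, Q, F, n_iter, trace = best
    return AdmixResult(
        Q=Q,
        F=F,
        loglik=ll_best,
        logliks_per_seed=logliks,
        converged=bool(converged),
        n_iter=n_iter,
        loglik_trace=trace if return_trace else None,
    )


def align_admixture(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Resolve label switching: greedily match columns of Q to Q_ref by
    correlation and return the permuted Q."""
    K = Q.shape[1]
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            corr[a, b] = np.corrcoef(Q_ref[:, a], Q[:, b])[0, 1]
    perm = np.full(K, -1)
    used = set()
    for a in np.argsort(-np.nanmax(corr, axis=1)):
        b = max((x for x in range(K) if x not in used), key=lambda x: corr[a, x])
        perm[a] = b
        used.add(b)
    return Q[:, perm]


def selection_scan(gl: GLMatrix, pca: PCAResult, axes=(0,)) -> pd.DataFrame:
    """Per-site test for excess covariance with principal axes.

    For axis k the statistic is N * r2(standardized dosage, scores_k),
    referred to chi-square (1 df); a Benjamini-Hochberg q-value column is
    appended per axis. Monomorphic (skipped) sites get NaN. Dosages are
    recomputed from ``gl``, so the scanned panel need not be the one the
    PCA was fitted on — calibration against the chi-square null is exact
    only for sites that did not themselves shape the axis (e.g. a held-out
    half), since an axis fitted on the tested sites absorbs part of their
    noise.
    """
    if pca.scores.shape[0] != gl.n_ind:
        raise ValueError("PCA and panel disagree on individuals")
    N = gl.n_ind
    f = estimate_maf_em_many(gl.gl)
    ok = (f > 1e-6) & (f < 1 - 1e-6)
    e = posterior_mean_genotypes(gl.gl[ok], f[ok])
    z = e - e.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    rows = {}
    for k in axes:
        y = pca.scores[:, k]
        yc = y - y.mean()
        denom = sd * np.sqrt((yc**2).mean())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (z * yc[None, :]).mean(axis=1) / denom
        chi = N * r**2
        p = stats.chi2.sf(chi, df=1)
        full_chi = np.full(gl.n_sites, np.nan)
        full_p = np.full(gl.n_sites, np.nan)
        full_chi[ok] = chi
        full_p[ok] = p
        q = np.full(gl.n_sites, np.nan)
        okp = ~np.isnan(full_p)
        q[okp] = stats.false_discovery_control(full_p[okp])
        rows[f"stat_pc{k + 1}"] = full_chi
        rows[f"p_pc{k + 1}"] = full_p
        rows[f"q_pc{k + 1}"] = q
    out = gl.sites[["chrom", "pos"]].copy()
    for name, col in rows.items():
        out[name] = col
    return out


def missingness_diagnostic(gl: GLMatrix, pca: PCAResult, axes=(0, 1)) -> pd.DataFrame:
    """Regress each axis's scores on per-individual missing fraction.

    Returns per-axis R-squared and slope p-value; a constant missingness
    vector yields R2 = 0 by convention.
    """
    miss = gl.missing_mask().mean(axis=0)
    rows = []
    for k in axes:
        y = pca.scores[:, k]
        if np.ptp(miss) == 0 or np.ptp(y) == 0:
            rows.append((k + 1, miss.mean(), 0.0, np.nan, 1.0))
            continue
        res = stats.linregress(miss, y)
        rows.append((k + 1, miss.mean(), res.rvalue**2, res.slope, res.pvalue))
    return pd.DataFrame(
        rows, columns=["axis", "mean_missingness", "r_squared", "slope", "p_value"]
    )
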