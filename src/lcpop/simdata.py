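"""Synthetic low-coverage data with known truth.

The generator produces the statistical structure the downstream analyses
assume, without modelling reads against a reference:

* drift-structured demes on a 1-D lattice: per-site deme allele frequencies
  follow a Balding-Nichols beta law around a uniform ancestral frequency,
  with optional spatial autocorrelation between demes (a Gaussian copula
  with correlation exp(-distance / migration_decay)) creating isolation by
  distance while preserving the beta marginals;
* one or more megabase-scale inversion-like blocks: inside each block two
  divergent haplotype classes (alpha/beta) with no recombination between
  them replace the neutral frequencies, and each individual carries 0, 1 or
  2 copies of the alpha arrangement drawn from its deme's arrangement
  frequency;
* Poisson read depth per site-individual (target ~1.3x per individual, the
  realized coverage regime of low-coverage resequencing panels) with a
  single per-base error rate; and
* a mitochondrial alignment with two deep clades separated by a fixed
  number of mutations.

All randomness flows from ``SimConfig.seed``: identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import BASES, GLMatrix, PileupCounts
from . import genolik


@dataclasses.dataclass
class InversionSpec:
    """An inversion-like block: [start, stop] bp, haplotype-class divergence
    d in (0,1), and the per-deme frequency of the alpha arrangement."""

    start: int
    stop: int
    divergence: float
    freq_alpha: tuple[float, ...]


@dataclasses.dataclass
class SimConfig:
    n_demes: int = 2
    inds_per_deme: int = 20
    n_sites: int = 10_000
    chrom_length: int = 10_000_000
    fst_drift: float = 0.1
    migration_decay: float = 0.0
    inversion_specs: list[InversionSpec] = dataclasses.field(default_factory=list)
    mean_depth: float = 1.3
    error_rate: float = 0.01
    mito_length: int = 2_000
    mito_clade_separation: int = 96
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fst_drift < 1:
            raise ValueError("fst_drift must lie in (0, 1)")
        if self.migration_decay < 0:
            raise ValueError("migration_decay must be >= 0")
        if not 0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must lie in [0, 0.2]")
        specs = []
        for inv in self.inversion_specs:
            if not isinstance(inv, InversionSpec):
                inv = InversionSpec(*inv)
            if not (1 <= inv.start < inv.stop <= self.chrom_length):
                raise ValueError("inversion interval must lie within [1, chrom_length]")
            if not 0 < inv.divergence < 1:
                raise ValueError("inversion divergence must lie in (0, 1)")
            fa = np.atleast_1d(np.asarray(inv.freq_alpha, dtype=float))
            if fa.size == 1:
                fa = np.repeat(fa, self.n_demes)
            if fa.size != self.n_demes or np.any((fa < 0) | (fa > 1)):
                raise ValueError("freq_alpha must give one frequency in [0,1] per deme")
            specs.append(InversionSpec(inv.start, inv.stop, inv.divergence, tuple(fa)))
        for a, b in zip(specs, specs[1:]):
            if b.start <= a.stop:
                raise ValueError("inversion intervals must not overlap")
        self.inversion_specs = specs
        if self.mito_clade_separation > self.mito_length:
            raise ValueError("mito_clade_separation cannot exceed mito_length")

    @property
    def n_ind(self) -> int:
        return self.n_demes * self.inds_per_deme

    def deme_of(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_demes), self.inds_per_deme)

    def individual_labels(self) -> list[str]:
        return [f"d{d}_i{i}" for d in range(self.n_demes) for i in range(self.inds_per_deme)]


@dataclasses.dataclass
class SimTruth:
    """Ground truth for validating every analysis stage."""

    positions: np.ndarray
    deme_freqs: np.ndarray  # (S, n_demes) allele frequency of the "minor"-coded allele
    true_genotypes: np.ndarray  # (S, N) in {0,1,2}
    haplotypes: np.ndarray  # (S, N, 2) allele per chromosome copy
    inversion_genotypes: np.ndarray  # (N, n_inversions) copies of alpha
    class_freqs: list[tuple[np.ndarray, np.ndarray]]  # per inversion: (p_alpha, p_beta) at member sites
    inversion_site_masks: list[np.ndarray]
    mito_clade: np.ndarray | None = None
    mito_sequences: list[str] | None = None


def _balding_nichols_freqs(rng, p_anc, fst, n_demes, migration_decay):
    """Per-deme frequencies: Balding-Nichols marginals, optional copula IBD."""
    S = p_anc.shape[0]
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    if migration_decay <= 0 or n_demes == 1:
        return rng.beta(a[:, None], b[:, None], size=(S, n_demes))
    d = np.arange(n_demes)
    corr = np.exp(-np.abs(d[:, None] - d[None, :]) / migration_decay)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(n_demes))
    z = rng.standard_normal((S, n_demes)) @ L.T
    u = stats.norm.cdf(z)
    return stats.beta.ppf(u, a[:, None], b[:, None])


def simulate_frequencies(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw site positions, allele coding and per-deme frequencies.

    Returns ``(sites, deme_freqs, aux)`` where ``sites`` is a DataFrame with
    chrom/pos/major/minor, ``deme_freqs`` is (S, n_demes) for the
    minor-coded allele, and ``aux`` carries the inversion haplotype-class
    frequency profiles used downstream by the genotype simulator. Inside
    each inversion block, the per-deme frequency is the mixture
    f_alpha * p_alpha + (1 - f_alpha) * p_beta with |p_alpha - p_beta| = d.
    """
    rng = rng or np.random.default_rng(config.seed)
    S = config.n_sites
    pos = np.sort(rng.choice(config.chrom_length, size=S, replace=False)) + 1
    # ancestral frequencies uniform on [0.05, 0.95]: expected minor-allele mass >= 0.05
    p_anc = rng.uniform(0.05, 0.95, size=S)
    freqs = _balding_nichols_freqs(
        rng, p_anc, config.fst_drift, config.n_demes, config.migration_decay
    )

    class_freqs = []
    masks = []
    for inv in config.inversion_specs:
        mask = (pos >= inv.start) & (pos <= inv.stop)
        m = int(mask.sum())
        d = inv.divergence
        centre = rng.uniform(d / 2, 1 - d / 2, size=m)
        sign = rng.choice([-1.0, 1.0], size=m)
        p_alpha = centre + sign * d / 2
        p_beta = centre - sign * d / 2
        fa = np.asarray(inv.freq_alpha)
        freqs[mask] = p_alpha[:, None] * fa[None, :] + p_beta[:, None] * (1 - fa[None, :])
        class_freqs.append((p_alpha, p_beta))
        masks.append(mask)

    base_pairs = rng.integers(0, 4, size=(S, 2))
    clash = base_pairs[:, 0] == base_pairs[:, 1]
    base_pairs[clash, 1] = (base_pairs[clash, 0] + 1 + rng.integers(0, 3, size=clash.sum())) % 4
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "major": BASES[base_pairs[:, 0]],
            "minor": BASES[base_pairs[:, 1]],
        }
    )
    aux = {"class_freqs": class_freqs, "masks": masks}
    return sites, freqs, aux


def _reads_from_haplotypes(rng, haps, mean_depth, eps, major_code, minor_code):
    """Poisson-depth reads copying a uniformly chosen chromosome with error."""
    S, N, _ = haps.shape
    depth = rng.poisson(mean_depth, size=(S, N))
    counts = np.zeros((S, N, 4), dtype=np.int64)
    max_d = depth.max() if depth.size else 0
    allele_bases = np.stack([major_code, minor_code], axis=1)  # (S, 2)
    for r in range(max_d):
        active = depth > r
        pick = rng.integers(0, 2, size=(S, N))
        allele = np.take_along_axis(haps, pick[:, :, None], axis=2)[:, :, 0]
        base = np.take_along_axis(allele_bases, allele, axis=1)
        err = rng.random(size=(S, N)) < eps
        shift = rng.integers(1, 4, size=(S, N))
        base = np.where(err, (base + shift) % 4, base)
        flat = np.flatnonzero(active)
        s_idx, i_idx = np.unravel_index(flat, (S, N))
        np.add.at(counts, (s_idx, i_idx, base[s_idx, i_idx]), 1)
    return counts, depth


def simulate_genotypes_and_reads(config: SimConfig, sites, freqs, aux, rng=None):
    """Draw genotypes, reads and exact genotype likelihoods.

    Genotypes are binomial in the deme frequency (HWE within deme) at
    neutral sites; inside inversions each of an individual's two haplotypes
    is drawn from the class profile (alpha or beta) of the corresponding
    arrangement copy. Read bases copy a uniformly chosen chromosome with
    per-base error; genotype likelihoods are computed exactly from the
    counts. Returns ``(SimTruth, PileupCounts, GLMatrix)``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    S, N = config.n_sites, config.n_ind
    deme = config.deme_of()
    pos = sites["pos"].to_numpy()

    haps = (rng.random((S, N, 2)) < freqs[:, deme][:, :, None]).astype(np.int8)

    inv_geno = np.zeros((N, len(config.inversion_specs)), dtype=np.int8)
    for k, inv in enumerate(config.inversion_specs):
        fa = np.asarray(inv.freq_alpha)[deme]
        arr = (rng.random((N, 2)) < fa[:, None]).astype(np.int8)  # 1 = alpha copy
        inv_geno[:, k] = arr.sum(axis=1)
        p_alpha, p_beta = aux["class_freqs"][k]
        mask = aux["masks"][k]
        m = int(mask.sum())
        for copy in range(2):
            p = np.where(arr[None, :, copy] == 1, p_alpha[:, None], p_beta[:, None])
            haps[mask, :, copy] = (rng.random((m, N)) < p).astype(np.int8)

    genotypes = haps.sum(axis=2).astype(np.int8)
    major_code = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in sites["major"]])
    minor_code = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in sites["minor"]])
    counts_arr, _ = _reads_from_haplotypes(
        rng, haps, config.mean_depth, config.error_rate, major_code, minor_code
    )
    labels = config.individual_labels()
    counts = PileupCounts(
        chrom=sites["chrom"].to_numpy(),
        pos=pos,
        counts=counts_arr,
        individuals=labels,
    )
    gl = genolik.genotype_likelihoods(
        counts, config.error_rate, major_code, minor_code, demes=deme
    )
    truth = SimTruth(
        positions=pos,
        deme_freqs=freqs,
        true_genotypes=genotypes,
        haplotypes=haps,
        inversion_genotypes=inv_geno,
        class_freqs=aux["class_freqs"],
        inversion_site_masks=aux["masks"],
    )
    return truth, counts, gl


def simulate(config: SimConfig):
    """Full nuclear simulation: frequencies, genotypes, reads, likelihoods."""
    rng = np.random.default_rng(config.seed)
    sites, freqs, aux = simulate_frequencies(config, rng)
    return simulate_genotypes_and_reads(config, sites, freqs, aux, rng)


def simulate_mito(
    config: SimConfig,
    depth: float = 10.0,
    private_rate: float = 0.001,
    clade_prob: float = 0.5,
    poisson_depth: bool = False,
    rng=None,
):
    """Two-clade mitochondrial alignment plus per-position base counts.

    Two clade consensus sequences differ at exactly
    ``mito_clade_separation`` positions; individuals are assigned to clades
    and receive private mutations at ``private_rate`` per position. Counts
    place exactly ``depth`` reads per position (every position callable;
    set ``poisson_depth`` for Poisson-distributed depth instead) with the
    config's error rate. Returns ``(counts_per_individual, clade_labels,
    sequences)`` where ``counts_per_individual`` is a list of (L, 4) arrays.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    L = config.mito_length
    N = config.n_ind
    anc = rng.integers(0, 4, size=L)
    sep_pos = rng.choice(L, size=config.mito_clade_separation, replace=False)
    cladeB = anc.copy()
    cladeB[sep_pos] = (cladeB[sep_pos] + rng.integers(1, 4, size=sep_pos.size)) % 4
    clade = (rng.random(N) < clade_prob).astype(int)

    seqs = []
    counts = []
    for i in range(N):
        seq = (anc if clade[i] == 0 else cladeB).copy()
        if private_rate > 0:
            n_priv = rng.binomial(L, private_rate)
            if n_priv:
                at = rng.choice(L, size=n_priv, replace=False)
                seq[at] = (seq[at] + rng.integers(1, 4, size=n_priv)) % 4
        seqs.append(seq)
        if poisson_depth:
            d = rng.poisson(depth, size=L)
        else:
            d = np.full(L, int(round(depth)))
        c = np.zeros((L, 4), dtype=np.int64)
        for pos_i in range(L):
            k = d[pos_i]
            if k == 0:
                continue
            err = rng.random(k) < config.error_rate
            bases = np.full(k, seq[pos_i])
            if err.any():
                bases[err] = (bases[err] + rng.integers(1, 4, size=err.sum())) % 4
            np.add.at(c[pos_i], bases, 1)
        counts.append(c)
    sequences = ["".join(BASES[s]) for s in seqs]
    return counts, clade, sequences


def simulate_neutral_spectrum(
    n_diploids: int,
    n_sites: int,
    seed: int = 1,
    mean_depth: float | None = None,
    error_rate: float = 0.01,
):
    """Independent segregating sites from the constant-size neutral spectrum.

    Derived-allele counts i in 1..2n-1 are drawn with probability
    proportional to 1/i (the standard neutral expectation) and assigned to
    haplotypes at random; genotypes pair consecutive haplotypes. With
    ``mean_depth`` set, also simulates reads and genotype likelihoods.
    Returns ``(genotypes, gl_or_None)``.
    """
    rng = np.random.default_rng(seed)
    n2 = 2 * n_diploids
    i = np.arange(1, n2)
    w = (1 / i) / (1 / i).sum()
    counts = rng.choice(i, size=n_sites, p=w)
    haps = np.zeros((n_sites, n2), dtype=np.int8)
    for s in range(n_sites):
        haps[s, rng.choice(n2, size=counts[s], replace=False)] = 1
    haps = haps.reshape(n_sites, n_diploids, 2)
    genotypes = haps.sum(axis=2)
    if mean_depth is None:
        return genotypes, None
    major = np.zeros(n_sites, dtype=int)
    minor = np.ones(n_sites, dtype=int)
    counts_arr, _ = _reads_from_haplotypes(rng, haps, mean_depth, error_rate, major, minor)
    pc = PileupCounts(
        chrom=np.full(n_sites, "chr1"),
        pos=np.arange(1, n_sites + 1),
        counts=counts_arr,
        individuals=[f"i{j}" for j in range(n_diploids)],
    )
    gl = genolik.genotype_likelihoods(pc, error_rate, major, minor)
    return genotypes, gl


def simulate_reads(
    genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float = 0.01,
    seed: int = 1,
):
    """Reads and genotype likelihoods for given hard genotypes.

    Heterozygotes are split into one copy of each allele (reads pick a
    chromosome uniformly, so only the allele counts matter). Returns
    ``(PileupCounts, GLMatrix)`` with alleles coded A (major) / C (minor).
    """
    rng = np.random.default_rng(seed)
    g = np.asarray(genotypes)
    S, N = g.shape
    haps = np.zeros((S, N, 2), dtype=np.int8)
    haps[:, :, 0] = g >= 1
    haps[:, :, 1] = g == 2
    major = np.zeros(S, dtype=int)
    minor = np.ones(S, dtype=int)
    counts_arr, _ = _reads_from_haplotypes(rng, haps, mean_depth, error_rate, major, minor)
    pc = PileupCounts(
        chrom=np.full(S, "chr1"),
        pos=np.arange(1, S + 1),
        counts=counts_arr,
        individuals=[f"i{j}" for j in range(N)],
    )
    gl = genolik.genotype_likelihoods(pc, error_rate, major, minor)
    return pc, gl


def certain_gl_from_genotypes(genotypes: np.ndarray) -> np.ndarray:
    """Full-certainty likelihood triplets (S, N, 3) from genotype calls."""
    g = np.asarray(genotypes)
    gl = np.zeros(g.shape + (3,))
    for k in range(3):
        gl[:, :, k] = g == k
    return gl


def glmatrix_from_genotypes(genotypes, positions=None, chrom="chr1", demes=None) -> GLMatrix:
    """Wrap hard genotypes in a GLMatrix (certain likelihoods)."""
    g = np.asarray(genotypes)
    S, N = g.shape
    pos = np.arange(1, S + 1) if positions is None else np.asarray(positions)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "major": "A", "minor": "C"}
    )
    return GLMatrix(
        sites=sites,
        individuals=[f"i{j}" for j in range(N)],
        gl=certain_gl_from_genotypes(g),
        demes=demes,
    )
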