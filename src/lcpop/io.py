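"""Readers and writers for the flat-text formats used throughout the package.

The central exchange format is the Beagle genotype-likelihood file: one row
per site, a ``marker`` column coded ``chrom_pos``, integer-coded major and
minor alleles (0=A, 1=C, 2=G, 3=T) and three columns per individual holding
the likelihoods of the major/major, major/minor and minor/minor genotypes.
Likelihoods are stored normalized so the largest of the three equals 1;
missing data is the uninformative triplet (1, 1, 1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])
BASE_CODE = {b: i for i, b in enumerate(BASES)}

SITE_COLUMNS = ["chrom", "pos", "major", "minor"]


@dataclasses.dataclass
class PileupCounts:
    """Per-site, per-individual base counts (A, C, G, T).

    ``counts`` has shape (n_sites, n_individuals, 4); row sums per
    site-individual equal that individual's read depth at the site.
    """

    chrom: np.ndarray
    pos: np.ndarray
    counts: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (sites, individuals, 4)")
        if np.any(self.counts < 0):
            raise ValueError("base counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_ind(self) -> int:
        return self.counts.shape[1]

    def depth(self) -> np.ndarray:
        """Read depth per site x individual."""
        return self.counts.sum(axis=2)


@dataclasses.dataclass
class GLMatrix:
    """Genotype likelihoods for a panel of sites and individuals.

    ``gl`` has shape (n_sites, n_individuals, 3), one triplet of likelihoods
    per site-individual for the genotypes (major/major, major/minor,
    minor/minor), normalized to a maximum of 1. ``sites`` carries chrom,
    1-based position, major/minor bases and, once estimated, the minor
    allele frequency (``maf``) and SNP likelihood-ratio p-value (``lrt_p``).
    """

    sites: pd.DataFrame
    individuals: list[str]
    gl: np.ndarray
    demes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError("gl must have shape (sites, individuals, 3)")
        if self.gl.shape[0] != len(self.sites):
            raise ValueError("site table and gl array disagree on site count")
        if self.gl.shape[1] != len(self.individuals):
            raise ValueError("individual labels and gl array disagree")
        self.sites = self.sites.reset_index(drop=True)
        if self.demes is not None:
            self.demes = np.asarray(self.demes)

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_ind(self) -> int:
        return self.gl.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (sites x individuals): True where the triplet is uninformative."""
        g = self.gl
        return (np.abs(g[:, :, 0] - g[:, :, 1]) < 1e-12) & (
            np.abs(g[:, :, 1] - g[:, :, 2]) < 1e-12
        )

    def subset_sites(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GLMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            individuals=list(self.individuals),
            gl=self.gl[idx],
            demes=self.demes,
        )

    def subset_individuals(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GLMatrix(
            sites=self.sites.copy(),
            individuals=[self.individuals[i] for i in idx],
            gl=self.gl[:, idx, :],
            demes=None if self.demes is None else self.demes[idx],
        )


def _allele_codes(values) -> np.ndarray:
    """Map base letters or integer codes to integers 0..3."""
    arr = np.asarray(values)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    return np.array([BASE_CODE[str(v)] for v in arr], dtype=int)


def write_beagle(gl: GLMatrix, path) -> None:
    """Write a Beagle-format genotype-likelihood file (tab-separated)."""
    header = ["marker", "allele1", "allele2"]
    for ind in gl.individuals:
        header += [ind] * 3
    markers = gl.sites["chrom"].astype(str) + "_" + gl.sites["pos"].astype(str)
    a1 = _allele_codes(gl.sites["major"])
    a2 = _allele_codes(gl.sites["minor"])
    flat = gl.gl.reshape(gl.n_sites, gl.n_ind * 3)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for m, x, y, row in zip(markers, a1, a2, flat):
            fh.write(f"{m}\t{x}\t{y}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_beagle(path, demes=None) -> GLMatrix:
    """Read a Beagle genotype-likelihood file written by :func:`write_beagle`.

    Marker ids are split on the final underscore into chrom and 1-based pos.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    df = pd.read_csv(path, sep="\t", header=None, skiprows=1)
    ind_cols = header[3:]
    individuals = list(dict.fromkeys(ind_cols))
    if len(ind_cols) != 3 * len(individuals) or ind_cols != [
        c for c in individuals for _ in range(3)
    ]:
        raise ValueError("Beagle file must have 3 columns per individual")
    markers = df.iloc[:, 0].astype(str)
    chrom = markers.str.rsplit("_", n=1).str[0]
    pos = markers.str.rsplit("_", n=1).str[1].astype(int)
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "major": BASES[df.iloc[:, 1].astype(int)],
            "minor": BASES[df.iloc[:, 2].astype(int)],
        }
    )
    gl = df.iloc[:, 3:].to_numpy(dtype=float).reshape(len(df), len(individuals), 3)
    return GLMatrix(sites=sites, individuals=individuals, gl=gl, demes=demes)


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table lacks columns: {missing}")
    return df


def write_fasta(records: dict[str, str], path) -> None:
    """Write label -> sequence mappings as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(s), id=str(k), description="") for k, s in records.items()],
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


def write_matrix(labels, values, path) -> None:
    """Write a labeled square matrix as tab-separated text."""
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
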