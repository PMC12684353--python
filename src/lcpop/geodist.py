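"""Geographic distances, Rousset's FST linearization, and Mantel tests.

Isolation by distance predicts that the linearized genetic distance
FST / (1 - FST) increases with geographic separation; the association
between the two distance matrices is tested with a one-sided Mantel
permutation test (simultaneous row/column permutation of one matrix).
Geographic distances are great-circle (haversine) kilometres.
"""

from __future__ import annotations

import dataclasses

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclasses.dataclass
class DistMatrix:
    """Symmetric labeled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def haversine_matrix(labels, lat, lon) -> DistMatrix:
    """Great-circle distance matrix (km) from decimal-degree coordinates."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of range [-180, 180]")
    la = np.radians(lat)
    lo = np.radians(lon)
    dlat = la[:, None] - la[None, :]
    dlon = lo[:, None] - lo[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistMatrix(labels=list(labels), values=d)


def rousset_gd(fst: DistMatrix) -> DistMatrix:
    """Elementwise FST / (1 - FST); FST = 1 entries become NaN (flagged)."""
    v = fst.values.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        gd = np.where(v >= 1, np.nan, v / (1 - v))
    np.fill_diagonal(gd, 0.0)
    return DistMatrix(labels=list(fst.labels), values=gd)


def mantel_test(a: DistMatrix, b: DistMatrix, n_perm: int = 9999, seed: int = 0):
    """One-sided Mantel test of positive association between two matrices.

    r is the Pearson correlation of the upper triangles; the p-value is
    (1 + #{permuted r >= observed}) / (n_perm + 1) under simultaneous
    row/column permutation of ``b``. Permutations are drawn uniformly with
    the identity redrawn, so mantel(a, a) yields p = 1/(n_perm+1) exactly
    (for matrices without nontrivial symmetries).
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share labels in the same order")
    n = a.n
    if n < 3:
        raise ValueError("need at least 3 labels")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    iu = np.triu_indices(n, k=1)
    x = a.values[iu]
    rng = np.random.default_rng(seed)

    def corr(y):
        xm = x - x.mean()
        ym = y - y.mean()
        return float(xm @ ym / np.sqrt((xm @ xm) * (ym @ ym)))

    r_obs = corr(b.values[iu])
    count = 0
    ident = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        while np.array_equal(perm, ident):
            perm = rng.permutation(n)
        y = b.values[np.ix_(perm, perm)][iu]
        if corr(y) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p
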