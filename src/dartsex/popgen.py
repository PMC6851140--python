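"""Population-structure statistics: F_ST, Nei's genetic distance, PCoA.

F_ST is the Nei-style G_ST on expected heterozygosities,
(H_T - H_S) / H_T, accumulated as a ratio of averages across loci
(sum of numerators over sum of H_T), with H_T computed from the
unweighted mean of group allele frequencies and H_S as the mean
within-group expected heterozygosity.  No small-sample correction is
applied; the estimator is deliberately the simplest textbook form.

Nei's genetic distance between individuals treats each individual as a
"population" with per-locus reference-allele frequency in {0, 1/2, 1}:
D = -ln( J_xy / sqrt(J_x J_y) ) with the identity sums J accumulated
across loci *before* the ratio, which keeps a single opposite-homozygote
locus from producing an infinity.  Loci where either individual is null
are dropped pairwise.

PCoA is classical metric scaling: double-centre -D^2/2, eigendecompose,
scale eigenvectors by the square root of the (nonnegative) eigenvalues.
Negative eigenvalues are dropped and excluded from the reported variance
proportions.  The eigenvector sign convention (largest-magnitude loading
positive) makes coordinate files reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import SnpCall
from .matrices import SexRegistry, SnpMatrix

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "pairwise_fst",
    "nei_distance",
    "pcoa",
    "individual_ref_freqs",
]

NEI_SENTINEL = 50.0  # distance reported when genetic identity is exactly zero


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance/divergence matrix with labelled axes."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k, column means zero
    eigenvalues: np.ndarray  # positive eigenvalues actually retained
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"axis{i + 1}" for i in range(k)],
        )


# ---------------------------------------------------------------------------
# allele frequencies


def _genotype_counts(calls: np.ndarray, sample_mask: np.ndarray):
    """Per-locus (ref-allele count, called-allele count) over masked samples."""
    block = calls[:, sample_mask]
    hom_ref = np.count_nonzero(block == SnpCall.HOM_REF, axis=1)
    het = np.count_nonzero(block == SnpCall.HET, axis=1)
    called = np.count_nonzero(block != SnpCall.NULL, axis=1)
    return 2 * hom_ref + het, 2 * called


def individual_ref_freqs(matrix: SnpMatrix, loci=None) -> np.ndarray:
    """Per (sample, locus) reference-allele frequency in {0, 0.5, 1}; nan = null."""
    calls = matrix.calls if loci is None else matrix.subset_loci(list(loci)).calls
    freq = np.full(calls.shape, np.nan)
    freq[calls == SnpCall.HOM_REF] = 1.0
    freq[calls == SnpCall.HET] = 0.5
    freq[calls == SnpCall.HOM_ALT] = 0.0
    return freq.T  # samples x loci


# ---------------------------------------------------------------------------
# F_ST


def _fst_from_freqs(p: np.ndarray, valid: np.ndarray) -> float:
    """Ratio-of-averages G_ST from a groups x loci frequency grid.

    ``valid`` marks loci where every group has at least one called
    genotype.  Loci monomorphic in the pooled set are skipped.
    """
    p = p[:, valid]
    p_bar = p.mean(axis=0)
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    h_s = (2.0 * p * (1.0 - p)).mean(axis=0)
    poly = h_t > 0
    if not np.any(poly):
        raise ValueError("F_ST undefined: all loci monomorphic")
    return float(np.sum(h_t[poly] - h_s[poly]) / np.sum(h_t[poly]))


def pairwise_fst(
    matrix: SnpMatrix, sites: dict[str, str] | SexRegistry
) -> tuple[DistanceMatrix, float]:
    """Pairwise F_ST between sites plus the overall (all sites jointly) F_ST.

    ``sites`` maps sample id -> site label, or is a registry carrying
    site labels.  Needs at least two sites with one individual each.
    """
    if isinstance(sites, SexRegistry):
        sites = {s: sites.site_of(s) or "" for s in sites.samples}
    labels = sorted({sites.get(s) for s in matrix.sample_ids if sites.get(s)})
    if len(labels) < 2:
        raise ValueError("pairwise F_ST needs at least two sites")
    site_of = np.array([sites.get(s, "") for s in matrix.sample_ids], dtype=object)

    freqs = np.full((len(labels), matrix.n_loci), np.nan)
    has_data = np.zeros((len(labels), matrix.n_loci), dtype=bool)
    for g, label in enumerate(labels):
        ref, total = _genotype_counts(matrix.calls, site_of == label)
        ok = total > 0
        freqs[g, ok] = ref[ok] / total[ok]
        has_data[g] = ok

    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = np.array([i, j])
            out[i, j] = out[j, i] = _fst_from_freqs(
                freqs[pair], has_data[pair].all(axis=0)
            )
    overall = _fst_from_freqs(freqs, has_data.all(axis=0))
    return DistanceMatrix(labels, out), overall


# ---------------------------------------------------------------------------
# Nei's genetic distance between individuals


def nei_distance(
    matrix: SnpMatrix,
    loci,
    individuals=None,
    sentinel: float = NEI_SENTINEL,
) -> DistanceMatrix:
    """Nei's standard genetic distance between individuals over given loci.

    Identity sums run over loci before the log; pairs with zero shared
    identity (or no shared called locus) get the finite ``sentinel``
    with a warning.
    """
    loci = list(loci)
    if not loci:
        raise ValueError("nei_distance needs a non-empty locus list")
    if individuals is None:
        individuals = list(matrix.sample_ids)
    sub = matrix.subset_loci(loci)
    cols = np.array([sub.sample_index(s) for s in individuals], dtype=int)
    p = individual_ref_freqs(sub)[cols]  # individuals x loci, nan for nulls
    q = 1.0 - p
    n = len(individuals)
    out = np.zeros((n, n))
    degenerate = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(p[i]) & ~np.isnan(p[j])
            if not shared.any():
                degenerate.append((individuals[i], individuals[j]))
                out[i, j] = out[j, i] = sentinel
                continue
            j_xy = np.sum(p[i][shared] * p[j][shared] + q[i][shared] * q[j][shared])
            j_x = np.sum(p[i][shared] ** 2 + q[i][shared] ** 2)
            j_y = np.sum(p[j][shared] ** 2 + q[j][shared] ** 2)
            if j_xy == 0.0:
                degenerate.append((individuals[i], individuals[j]))
                out[i, j] = out[j, i] = sentinel
                continue
            out[i, j] = out[j, i] = max(
                0.0, float(-np.log(j_xy / np.sqrt(j_x * j_y)))
            )
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} pair(s) with zero shared identity reported "
            f"at sentinel distance {sentinel}",
            stacklevel=2,
        )
    return DistanceMatrix(list(individuals), out)


# ---------------------------------------------------------------------------
# principal coordinates analysis


def pcoa(distances: DistanceMatrix | np.ndarray, k: int = 2, ids=None) -> PcoaResult:
    """Classical metric scaling of a distance matrix onto k axes."""
    if isinstance(distances, DistanceMatrix):
        d = distances.values
        ids = list(distances.ids)
    else:
        d = np.asarray(distances, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(len(d))]
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(d)
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ (d**2) @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12 if n else 0.0
    positive = eigval > tol
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {n_pos} axes "
            f"instead of the requested {k}",
            stacklevel=2,
        )
        k = n_pos
    lam = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(lam)
    # sign convention: the largest-magnitude coordinate on each axis is positive
    for a in range(k):
        col = coords[:, a]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            coords[:, a] = -col
    total_positive = float(eigval[positive].sum()) if n_pos else 1.0
    return PcoaResult(
        sample_ids=ids,
        coordinates=coords,
        eigenvalues=lam,
        proportion_explained=lam / total_positive,
    )
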