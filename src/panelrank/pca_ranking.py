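"""Locus contribution to principal components (LC) and principal
coordinate analysis of population distance matrices.

LC follows the multivariate locus-comparison idea of Moazami-Goudarzi &
Laloe: PCA of the populations x loci allele-frequency matrix, then each
locus's average share of the leading axes' inertia.  One column per locus
(the reference-allele frequency) — for biallelic loci the alternate-allele
column is perfectly anticorrelated and would double-count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model_io import AlleleFrequencyMatrix

__all__ = ["PcaResult", "PcoaResult", "population_pca", "locus_contribution_lc", "pcoa"]

_EIG_TOL = 1e-12


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # descending, length n_axes
    scores: np.ndarray               # populations x n_axes
    loadings: np.ndarray             # n_axes x loci (unit eigenvectors)
    proportion_variance: np.ndarray  # per axis
    loci: list[str]
    populations: list[str]

    @property
    def contributions(self) -> np.ndarray:
        """Per-axis locus contributions (squared unit loadings; rows sum to 1)."""
        return self.loadings**2


def population_pca(
    freqs: AlleleFrequencyMatrix, loci: list[str] | None = None, scale: bool = False
) -> PcaResult:
    """Centered (by default unscaled) PCA of population allele frequencies.

    Requires >=3 populations, >=2 loci and no undefined frequencies in the
    subset.  Returns at most min(K-1, L) axes.  ``scale=True`` switches to a
    correlation-matrix PCA.
    """
    if loci is None:
        loci = list(freqs.loci)
    cols = [freqs.locus_index(l) for l in loci]
    X = freqs.freq[:, cols]
    K, L = X.shape
    if K < 3:
        raise ValueError("population PCA needs at least 3 populations")
    if L < 2:
        raise ValueError("population PCA needs at least 2 loci")
    if np.any(np.isnan(X)):
        raise ValueError("undefined frequencies in the requested locus subset")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    n_axes = min(K - 1, L)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (K - 1)
    eig, U, s, Vt = eig[:n_axes], U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    total = eig.sum()
    if total <= _EIG_TOL:
        warnings.warn("all populations identical: eigenvalues ~ 0", stacklevel=2)
        prop = np.zeros_like(eig)
    else:
        prop = eig / total
    return PcaResult(
        eigenvalues=eig,
        scores=U * s,
        loadings=Vt,
        proportion_variance=prop,
        loci=list(loci),
        populations=list(freqs.populations),
    )


def locus_contribution_lc(pca: PcaResult, n_components: int = 5) -> np.ndarray:
    """Per-locus LC: unweighted mean of the locus's per-axis contributions
    over the first ``n_components`` axes (zero-eigenvalue axes dropped)."""
    avail = len(pca.eigenvalues)
    if avail < n_components:
        warnings.warn(
            f"only {avail} axes available; using all of them", stacklevel=2
        )
        n_components = avail
    eig = pca.eigenvalues[:n_components]
    keep = eig > _EIG_TOL * max(pca.eigenvalues.max(), 1.0)
    if not np.all(keep):
        warnings.warn("zero-eigenvalue axes excluded from the LC average", stacklevel=2)
    if not np.any(keep):
        warnings.warn("no informative axes: LC is uniform", stacklevel=2)
        L = len(pca.loci)
        return np.full(L, 1.0 / L)
    return pca.contributions[:n_components][keep].mean(axis=0)


@dataclass
class PcoaResult:
    coordinates: np.ndarray          # objects x n_axes
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be negative)
    proportion_variance: np.ndarray  # per returned axis, of the positive-eig sum
    n_negative: int


def pcoa(distance_matrix: np.ndarray, n_axes: int = 6) -> PcoaResult:
    """Classical multidimensional scaling of a symmetric, zero-diagonal
    distance matrix.  Negative eigenvalues are reported and their axes
    dropped; variance shares are of the positive-eigenvalue sum."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > _EIG_TOL * max(abs(eigval).max(), 1.0)
    n_pos = int(pos.sum())
    m = min(n_axes, n_pos)
    coords = eigvec[:, :m] * np.sqrt(eigval[:m])
    pos_sum = eigval[pos].sum() if n_pos else 1.0
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigval,
        proportion_variance=eigval[:m] / pos_sum,
        n_negative=int((eigval < -_EIG_TOL * max(abs(eigval).max(), 1.0)).sum()),
    )
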