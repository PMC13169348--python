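"""PCA-guided K-means clustering of conformer ensembles.

Each conformer is described by the sorted eigenvalues of its interatomic
distance matrix — a descriptor invariant under rigid motion and atom
reordering, optionally restricted to heavy atoms. The eigenvalue features are
reduced by PCA and partitioned by K-means; when no cluster count is given,
every k from 10% to 80% of the ensemble size (lower bound 2) is tried and the
silhouette-score maximum wins. Each cluster is represented by its
lowest-energy member.

The cost of the discretisation is quantified by ΔE_av: the difference between
the Boltzmann-averaged energy of the full ensemble and that of the
representatives with their populations recomputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .ensemble import Ensemble, distance_matrix
from .errors import DataError
from .thermo import boltzmann_average, boltzmann_populations

__all__ = [
    "ClusterResult",
    "eigen_features",
    "pca_reduce",
    "optimize_k",
    "evaluate_clustering_loss",
]

#: K-means restarts per candidate k
N_RESTARTS = 10


@dataclass
class ClusterResult:
    """K-means outcome on the active conformers.

    labels index into the *active-conformer order*; representatives are
    positions (in that same order) of the lowest-energy member of each
    cluster. silhouette is None when clustering was skipped (fewer than three
    active conformers).
    """

    k: int
    labels: np.ndarray
    silhouette: float | None
    representatives: np.ndarray
    seed: int

    @property
    def skipped(self) -> bool:
        return self.silhouette is None and self.k == len(self.labels)


def eigen_features(ens: Ensemble, include_hydrogens: bool = True) -> np.ndarray:
    """Per-active-conformer descriptor: descending distance-matrix eigenvalues."""
    rows = []
    for c in ens.active:
        eig = np.linalg.eigvalsh(distance_matrix(c, include_hydrogens))
        rows.append(eig[::-1])
    return np.asarray(rows)


def pca_reduce(features: np.ndarray, variance_kept: float = 0.95) -> np.ndarray:
    """Mean-centered PCA scores keeping ≥ variance_kept of the total variance.

    Deterministic (full SVD) up to component sign. A constant feature matrix
    has no variance to decompose; it yields a single zero component with a
    warning so that downstream clustering degrades gracefully.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 2:
        raise DataError("PCA needs at least two conformers")
    centered = x - x.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        warnings.warn("constant feature matrix: returning a single zero component")
        return np.zeros((x.shape[0], 1))
    n_comp = min(variance_kept, 0.999999) if 0 < variance_kept < 1 else variance_kept
    pca = PCA(n_components=n_comp, svd_solver="full")
    return pca.fit_transform(x)


def _kmeans_grid(n: int) -> range:
    lo = max(2, math.ceil(0.10 * n))
    hi = max(lo, math.floor(0.80 * n))
    return range(lo, hi + 1)


def _fit_kmeans(scores: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
    return km.fit_predict(scores)


def _representatives(labels: np.ndarray, energies: np.ndarray) -> np.ndarray:
    reps = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        reps.append(members[np.argmin(energies[members])])
    return np.asarray(sorted(reps))


def optimize_k(
    scores: np.ndarray,
    energies,
    k_user: int | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster PCA scores, choosing k by silhouette unless the user fixes it.

    Automatic mode scans k ∈ [max(2, ⌈0.10·n⌉), ⌊0.80·n⌋] with seeded
    restarts and keeps the highest silhouette; ties go to the smaller k.
    With fewer than three points automatic clustering is skipped and every
    conformer forms its own cluster.
    """
    scores = np.asarray(scores, dtype=float)
    energies = np.asarray(energies, dtype=float)
    n = scores.shape[0]
    if energies.shape[0] != n:
        raise DataError("energies must align with score rows")

    if k_user is not None:
        if not 2 <= k_user <= n - 1:
            raise DataError(f"k must lie in [2, {n - 1}], got {k_user}")
        labels = _fit_kmeans(scores, k_user, seed)
        sil = float(silhouette_score(scores, labels))
        return ClusterResult(
            k=k_user,
            labels=labels,
            silhouette=sil,
            representatives=_representatives(labels, energies),
            seed=seed,
        )

    if n < 3:
        warnings.warn("fewer than 3 active conformers: clustering skipped")
        labels = np.arange(n)
        return ClusterResult(
            k=n,
            labels=labels,
            silhouette=None,
            representatives=np.arange(n),
            seed=seed,
        )

    best: tuple[float, int, np.ndarray] | None = None
    for k in _kmeans_grid(n):
        if k >= n:  # silhouette is undefined for k = n
            continue
        labels = _fit_kmeans(scores, k, seed)
        if np.unique(labels).size < 2:
            continue
        sil = float(silhouette_score(scores, labels))
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, labels)
    if best is None:
        raise DataError("no valid clustering found on the silhouette grid")
    sil, k, labels = best
    return ClusterResult(
        k=k,
        labels=labels,
        silhouette=sil,
        representatives=_representatives(labels, energies),
        seed=seed,
    )


def evaluate_clustering_loss(
    full_energies,
    full_populations,
    result: ClusterResult,
    temperature: float = 298.15,
) -> float:
    """Energy cost ΔE_av of representing the ensemble by cluster representatives.

    ΔE_av = E_av(full ensemble) − E_av(representatives), the latter with
    Boltzmann weights recomputed over the representatives alone. Zero when
    every conformer is its own cluster; grows as the discretisation coarsens.
    """
    e = np.asarray(full_energies, dtype=float)
    reps = np.asarray(result.representatives, dtype=int)
    if reps.size == 0:
        raise DataError("empty representative set")
    e_av_tot = boltzmann_average(e, full_populations)
    e_reps = e[reps]
    p_reps = boltzmann_populations(e_reps, temperature=temperature)
    e_av_clustered = boltzmann_average(e_reps, p_reps)
    return float(e_av_tot - e_av_clustered)
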