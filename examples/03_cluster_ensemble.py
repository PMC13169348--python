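"""PCA/K-means clustering with silhouette-driven cluster-count selection.

Clusters a 24-conformer synthetic ensemble on distance-matrix-eigenvalue
descriptors and reports ΔE_av, the Boltzmann-average energy lost by keeping
only the cluster representatives.
"""

import numpy as np

from enref import (
    FixtureSpec,
    boltzmann_populations,
    eigen_features,
    evaluate_clustering_loss,
    make_ensemble,
    optimize_k,
    pca_reduce,
)

ens, _ = make_ensemble(FixtureSpec(n_conformers=24, n_atoms=10, seed=4))
feats = eigen_features(ens, include_hydrogens=True)
scores = pca_reduce(feats, variance_kept=0.95)
print(f"{feats.shape[1]} eigenvalue features → {scores.shape[1]} principal components")

energies = np.array([c.e_el for c in ens.active])
result = optimize_k(scores, energies, seed=0)
print(f"silhouette scan chose k = {result.k} (silhouette = {result.silhouette:.3f}); "
      f"representatives are the lowest-energy members of each cluster")

pops = boltzmann_populations(energies)
loss = evaluate_clustering_loss(energies, pops, result)
print(f"ΔE_av = {loss:.4f} kcal/mol — the shift in the Boltzmann-averaged energy "
      f"when the ensemble is reduced from {len(energies)} to {result.k} conformers")
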