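# enref

Automated refinement of molecular conformer ensembles.

Conformer generators (CREST, GOAT, RDKit, ...) cheaply produce hundreds to
thousands of candidate structures for a flexible molecule, but every
downstream property — energies, populations, IR/VCD/UV/ECD spectra — needs
that ensemble re-evaluated at higher levels of theory, which is intractable
without aggressive, reproducible filtering. `enref` is the engine for that
refinement: it reads a multi-structure XYZ ensemble and a JSON protocol of
sequential calculation steps, drives any backend that implements a small
calculator contract (a deterministic synthetic calculator ships with the
package, so the whole pipeline runs without any quantum-chemistry code), and
applies at each step:

- **Dual-filter pruning.** Two conformers are duplicates when they agree
  simultaneously in energy, |E_i − E_j| < thrG, and in the scalar norm of the
  rotational-constant vector, |B_i − B_j| < thrB; the higher-energy one is
  discarded. No structural alignment is ever performed. A retention window
  then drops conformers more than ΔG_max above the minimum (6.0 kcal/mol for
  single points, 3.5 kcal/mol after optimisation + frequencies, both
  overridable per step).
- **qRRHO thermochemistry.** Gibbs energies from standard ideal-gas partition
  functions with the low-frequency vibrational entropy damped toward the
  free-rotor value by w(ν) = 1/(1 + (ν₀/ν)^α), so soft torsions stay finite.
  Populations follow p_i = g_i·exp(−ΔE_i/RT) / Σ_j g_j·exp(−ΔE_j/RT).
- **PCA/K-means clustering.** Conformers are described by the sorted
  eigenvalues of their interatomic distance matrices (rigid-motion and
  permutation invariant, hydrogens optional), reduced by PCA, and clustered;
  the cluster count is either fixed or chosen by a silhouette scan over
  k ∈ [max(2, ⌈0.10·n⌉), ⌊0.80·n⌋]. Each cluster keeps its lowest-energy
  member, and the diagnostic ΔE_av = E_av,TOT − E_av,clustered quantifies the
  energy cost of the reduction.
- **Spectra.** Boltzmann-weighted ensemble spectra via Lorentzian (IR/VCD,
  L(X) = Σ I_i γ²/(γ² + 4(X − ω_iΔ)²)) or Gaussian (UV/ECD, with
  σ = γ/(2√(2 ln 2))) broadening, and an automated alignment that fits the
  FWHM γ and the shift Δ (multiplicative in wavenumber, additive in nm) by
  bounded L-BFGS-B minimisation of a weighted RMSD against a two-column XY
  experimental trace, reporting the similarity index
  S = 1 − RMSD/max (max = 1 achiral, 2 chiral).

## Worked example

`examples/` holds one short script per capability. Pruning
(`python examples/01_prune_ensemble.py`):

```
starting ensemble: 20 conformers (3 planted duplicates)
after deduplication: 17 conformers (each removed one matched an earlier conformer in BOTH energy and B norm)
after 3.5 kcal/mol energy window: 14 conformers (high-energy structures carry negligible Boltzmann weight)
```

The three planted duplicates are exact geometric copies with sub-threshold
energy jitter, so the dual filter removes exactly those three; the window
then drops the structures too high in energy to carry Boltzmann weight.
Spectral alignment (`python examples/04_spectra_fit.py`):

```
synthetic experiment built at γ = 9.0 cm⁻¹, Δ = 0.97 from 12 sticks
recovered γ = 9.000 cm⁻¹, Δ = 0.97000 (errors 0.000% / 0.000%)
weighted RMSD = 1.82e-10, similarity index S = 1.0000 (1 means the normalised spectra coincide)
```

A full three-step refinement — cheap single point, DFT-style
optimisation + frequencies (switching the filters to Gibbs energies), final
single point — runs in `examples/05_run_protocol.py` and from the shell:

```sh
enref fixtures --out fx --seed 3          # synthetic ensemble + truth record
enref init --out protocol.json            # three-step protocol template
enref run --ensemble fx/ensemble.xyz --protocol protocol.json --out run --seed 3
```

Each step writes a `stepN_report.tsv` (per-conformer energy, B norm,
population, kept/duplicate-of-k/over-window status), a `stepN_ensemble.xyz`
checkpoint, and the run ends with `run_summary.json`. Identical inputs and
seed reproduce every report byte-for-byte.

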