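"""Dual-filter pruning of a conformer ensemble.

Builds a synthetic 20-conformer ensemble with 3 planted duplicates, then
removes duplicates (simultaneous energy + rotational-constant-norm match) and
applies the 3.5 kcal/mol retention window used after optimisation steps.
"""

from enref import (
    FixtureSpec,
    deduplicate,
    default_thresholds,
    energy_window,
    make_ensemble,
)

ens, truth = make_ensemble(
    FixtureSpec(n_conformers=20, n_atoms=8, n_planted_duplicates=3, seed=11)
)
print(f"starting ensemble: {ens.n_active} conformers "
      f"({len(truth['duplicates'])} planted duplicates)")

thr = default_thresholds("opt_freq")  # thrG=0.05 kcal/mol, thrB=15 MHz, window 3.5
deduplicate(ens, thr)
print(f"after deduplication: {ens.n_active} conformers "
      f"(each removed one matched an earlier conformer in BOTH energy and B norm)")

energy_window(ens, thr.thr_g_max)
print(f"after {thr.thr_g_max} kcal/mol energy window: {ens.n_active} conformers "
      f"(high-energy structures carry negligible Boltzmann weight)")
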