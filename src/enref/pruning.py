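"""Dual-filter pruning of conformer ensembles.

Two conformers are considered duplicates when they agree simultaneously in
energy (|E_i − E_j| < thrG) and in the scalar norm of the rotational-constant
vector (|B_i − B_j| < thrB); of such a pair the higher-energy one is
discarded. This pairwise scalar test deliberately avoids any structural
alignment. A second filter drops conformers more than thrGmax above the
ensemble minimum; single-point steps use a wider window than optimisation
steps so that structures that may relax substantially are carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .ensemble import Ensemble
from .errors import ConfigError, DataError

__all__ = [
    "PruneThresholds",
    "default_thresholds",
    "deduplicate",
    "energy_window",
    "retention_rate",
]

#: default energy-equivalence threshold, kcal/mol (CREST-like)
DEFAULT_THR_G = 0.05
#: default rotational-constant-norm equivalence threshold, MHz (CREST-like)
DEFAULT_THR_B = 15.0
#: default retention windows above the minimum, kcal/mol, per step kind
DEFAULT_WINDOWS = {
    "single_point": 6.0,
    "opt": 3.5,
    "opt_freq": 3.5,
    "freq": 3.5,
}


@dataclass(frozen=True)
class PruneThresholds:
    """thrG (kcal/mol), thrB (MHz), thrGmax (kcal/mol) — all strictly positive."""

    thr_g: float = DEFAULT_THR_G
    thr_b: float = DEFAULT_THR_B
    thr_g_max: float = 6.0

    def __post_init__(self) -> None:
        if min(self.thr_g, self.thr_b, self.thr_g_max) <= 0:
            raise ConfigError("all pruning thresholds must be positive")


def default_thresholds(
    step_kind: str,
    thr_g: float | None = None,
    thr_b: float | None = None,
    thr_g_max: float | None = None,
) -> PruneThresholds:
    """Step-kind-dependent thresholds; explicit user values always override.

    Single-point steps keep a 6.0 kcal/mol window, optimisation/frequency
    steps tighten it to 3.5 kcal/mol.
    """
    if step_kind not in DEFAULT_WINDOWS:
        raise ConfigError(
            f"unknown step kind {step_kind!r}; expected one of {sorted(DEFAULT_WINDOWS)}"
        )
    base = PruneThresholds(thr_g_max=DEFAULT_WINDOWS[step_kind])
    overrides = {
        k: v
        for k, v in {"thr_g": thr_g, "thr_b": thr_b, "thr_g_max": thr_g_max}.items()
        if v is not None
    }
    return replace(base, **overrides) if overrides else base


def retention_rate(n_start: int, n_final: int) -> int:
    """Final-over-starting conformer count as an integer percentage."""
    if n_start <= 0 or n_final < 0 or n_final > n_start:
        raise ConfigError("need 0 ≤ n_final ≤ n_start with n_start > 0")
    return round(100.0 * n_final / n_start)


def _check_active_data(ens: Ensemble, use_gibbs: bool, need_b: bool) -> None:
    for c in ens.active:
        c.energy(use_gibbs)  # raises DataError when missing
        if need_b and c.b_norm is None:
            raise DataError(f"conformer {c.index} has no rotational-constant norm")


def deduplicate(
    ens: Ensemble, thr: PruneThresholds, use_gibbs: bool = False
) -> Ensemble:
    """Deactivate duplicates by the greedy dual-filter scan.

    Active conformers are visited in ascending energy (ties broken by original
    index); a conformer is deactivated when both |ΔE| < thrG and |ΔB| < thrB
    hold against any already-kept conformer. The global minimum always
    survives, and the operation is idempotent. Deactivated conformers are
    annotated in the ensemble log with the index they duplicate.
    """
    _check_active_data(ens, use_gibbs, need_b=True)
    order = sorted(ens.active, key=lambda c: (c.energy(use_gibbs), c.index))
    kept: list = []
    duplicates: dict[int, int] = {}
    for c in order:
        dup_of = None
        for k in kept:
            if (
                abs(c.energy(use_gibbs) - k.energy(use_gibbs)) < thr.thr_g
                and abs(c.b_norm - k.b_norm) < thr.thr_b
            ):
                dup_of = k.index
                break
        if dup_of is None:
            kept.append(c)
        else:
            c.active = False
            duplicates[c.index] = dup_of
    ens.log(
        {
            "op": "deduplicate",
            "thr_g": thr.thr_g,
            "thr_b": thr.thr_b,
            "use_gibbs": use_gibbs,
            "duplicates": duplicates,
            "n_active": ens.n_active,
        }
    )
    return ens


def energy_window(
    ens: Ensemble, thr_g_max: float, use_gibbs: bool = False
) -> Ensemble:
    """Deactivate conformers at or above thrGmax over the active minimum.

    Retention is strict (ΔE < thrGmax); the minimum itself always stays.
    """
    if thr_g_max <= 0:
        raise ConfigError("thrGmax must be positive")
    _check_active_data(ens, use_gibbs, need_b=False)
    active = ens.active
    e_min = min(c.energy(use_gibbs) for c in active)
    removed = []
    for c in active:
        if c.energy(use_gibbs) - e_min >= thr_g_max:
            c.active = False
            removed.append(c.index)
    ens.log(
        {
            "op": "energy_window",
            "thr_g_max": thr_g_max,
            "use_gibbs": use_gibbs,
            "removed": removed,
            "n_active": ens.n_active,
        }
    )
    return ens
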