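import numpy as np
import pytest

from enref import Conformer, Ensemble, FixtureSpec, make_ensemble, rotational_constants


@pytest.fixture
def water_conformer():
    return Conformer(
        symbols=["O", "H", "H"],
        coords=[[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]],
    )


@pytest.fixture
def small_ensemble():
    """Five-conformer ensemble with energies/B norms set by hand."""
    rng = np.random.default_rng(7)
    energies = [0.00, 0.03, 0.10, 0.12, 5.00]
    b_norms = [1000.0, 1001.0, 1000.5, 1200.0, 1000.2]
    confs = []
    for i, (e, b) in enumerate(zip(energies, b_norms)):
        coords = rng.normal(size=(4, 3)) * 2.0
        c = Conformer(symbols=["C", "C", "O", "N"], coords=coords, e_el=e, index=i)
        c.b_norm = b
        confs.append(c)
    return Ensemble(conformers=confs)


@pytest.fixture
def fixture_ensemble():
    ens, truth = make_ensemble(
        FixtureSpec(n_conformers=20, n_atoms=8, n_planted_duplicates=3, seed=11)
    )
    return ens, truth


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
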