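import numpy as np
import pytest

from g3k import synthetic


@pytest.fixture(scope="session")
def lacnac():
    """LacNAc disaccharide with known torsions: model, component, truth."""
    spec = synthetic.GlycanBuildSpec(sequence="Galb1-4GlcNAc", torsions={2: (-70.0, 120.0)})
    return synthetic.build_glycan(spec)


@pytest.fixture(scope="session")
def branched7():
    """Branched 7-residue N-glycan-like topology."""
    seq = "Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)Man"
    return synthetic.build_glycan(seq)


@pytest.fixture(scope="session")
def small_ensemble():
    """5-conformer ensemble with torsion noise, uneven weights, root anchored."""
    ens, truth = synthetic.make_ensemble(
        synthetic.GlycanBuildSpec(sequence="Mana1-3(Mana1-6)Manb1-4GlcNAc"),
        synthetic.EnsembleSpec(
            n_conformers=5, kappa=15.0, jitter_sigma=0.02,
            weights=np.array([0.4, 0.25, 0.15, 0.1, 0.1]), seed=11, n_anchor=1,
        ),
    )
    return ens, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
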