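import numpy as np
import pandas as pd
import pytest

from caspfold import synthetic
from caspfold.ensemble import ConformationalEnsemble


def make_atoms(rows):
    """Atom table from (residue_index, residue_name, chain, atom_name, element) rows."""
    return pd.DataFrame(
        rows, columns=["residue_index", "residue_name", "chain_id", "atom_name", "element"]
    )


@pytest.fixture
def salt_bridge_pair():
    """Lys NZ 3.5 A from Glu OE1, residues 1 and 3 (non-adjacent)."""
    atoms = make_atoms(
        [
            (1, "LYS", "A", "CA", "C"),
            (1, "LYS", "A", "NZ", "N"),
            (3, "GLU", "A", "CA", "C"),
            (3, "GLU", "A", "OE1", "O"),
        ]
    )
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [10.0, 10.0, 10.0],
            [5.0, 0.0, 0.0],  # 3.5 A from NZ
        ]
    )
    return coords, atoms


@pytest.fixture
def two_mode_ensemble():
    """1000-frame ensemble with planted modes of sd 2 and 1 A, light noise."""
    rng = np.random.default_rng(42)
    n_res = 20
    modes = synthetic.random_orthonormal_modes(2 * n_res, 2, rng)
    spec = synthetic.EnsembleSpec(
        n_residues=n_res,
        n_frames=1000,
        planted_modes=[(modes[0], 2.0), (modes[1], 1.0)],
        isotropic_noise_sd=0.05,
        seed=7,
    )
    return synthetic.make_toy_ensemble(spec), modes


@pytest.fixture
def small_ensemble():
    spec = synthetic.EnsembleSpec(
        n_residues=20, n_frames=10, isotropic_noise_sd=0.05, seed=3
    )
    return synthetic.make_toy_ensemble(spec)


def ensemble_from_frames(coords, atoms):
    return ConformationalEnsemble(np.asarray(coords, dtype=float), atoms)
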