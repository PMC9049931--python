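import numpy as np
import pytest

import amphitraj as at


@pytest.fixture(scope="session")
def toy_micelle():
    """15 lipids + 1 peptide, 4 frames, with planted ground truth."""
    return at.gen_toy_micelle_trajectory(
        n_lipids=15, n_peptides=1, n_frames=4, box=60.0, seed=11)


@pytest.fixture(scope="session")
def ideal_helix_20():
    return at.gen_ideal_helix("A" * 20, phi=-57.0, psi=-47.0)


@pytest.fixture(scope="session")
def extended_chain_20():
    return at.gen_ideal_helix("A" * 20, phi=180.0, psi=180.0)


@pytest.fixture(scope="session")
def harmonic_ensemble_small():
    """3 atoms, diagonal covariance 0.04 A^2, 5000 frames."""
    return at.gen_harmonic_ensemble(
        masses=np.full(3, 12.011), sigma_diag=np.full(9, 0.04),
        temperature=310.0, n_frames=5000, seed=21)


@pytest.fixture
def water_pdb(tmp_path):
    """Minimal 3-atom water PDB file."""
    path = tmp_path / "water.pdb"
    path.write_text(
        "ATOM      1  O   HOH A   1       0.000   0.000   0.000"
        "  1.00  0.00           O\n"
        "ATOM      2  H1  HOH A   1       0.957   0.000   0.000"
        "  1.00  0.00           H\n"
        "ATOM      3  H2  HOH A   1      -0.240   0.927   0.000"
        "  1.00  0.00           H\n"
        "END\n")
    return path
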