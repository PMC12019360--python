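import numpy as np
import pytest

from dmgen.synthetic import ChainParams, make_dataset


def make_pdb_text(residues, chain="A", resname="ALA"):
    """Build minimal PDB text.

    ``residues`` is a list of (resnum, atoms) where atoms is a list of
    (name, x, y, z, altloc, occupancy) tuples.
    """
    lines = []
    serial = 1
    for resnum, atoms in residues:
        for (name, x, y, z, altloc, occ) in atoms:
            el = name.strip()[0]
            lines.append(
                "ATOM  " + f"{serial:5d}" + " " + f"{name:^4s}" + (altloc or " ")
                + f"{resname:>3s}" + " " + chain + f"{resnum:4d}" + "    "
                + f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
                + " " * 10 + f"{el:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def ca_residue(resnum, x, y=0.0, z=0.0):
    return (resnum, [("CA", x, y, z, "", 1.0)])


@pytest.fixture(scope="session")
def small_dataset():
    """24 synthetic 32x32 distance matrices (session-cached)."""
    return make_dataset(24, ChainParams(n_residues=32, seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_symmetric_matrix(rng, n, scale=20.0):
    """Random symmetric zero-diagonal nonnegative matrix (not metric)."""
    a = rng.random((n, n)) * scale
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d
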