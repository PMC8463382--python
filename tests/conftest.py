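import io

import numpy as np
import pytest

from neetkit.sites import detect_cluster_sites, load_structure
from neetkit.synthetic import gen_mock_neet_structure


@pytest.fixture(scope="session")
def mock_pdb_and_truth():
    return gen_mock_neet_structure(seed=0)


@pytest.fixture(scope="session")
def mock_structure(mock_pdb_and_truth):
    pdb_text, _ = mock_pdb_and_truth
    return load_structure(io.StringIO(pdb_text), "mock")


@pytest.fixture(scope="session")
def mock_site(mock_structure):
    sites = detect_cluster_sites(mock_structure)
    assert len(sites) == 1
    return sites[0]


def gaussian_cube_text(origin, step, counts, atoms, values, angstrom=False,
                       orbital=False):
    """Hand-rolled cube text in either unit dialect, for parser tests."""
    from neetkit.units import BOHR_ANGSTROM
    scale = BOHR_ANGSTROM if angstrom else 1.0
    sign = -1 if angstrom else 1
    nat = -len(atoms) if orbital else len(atoms)
    lines = ["test cube", "comment"]
    o = np.asarray(origin, float) * scale
    lines.append(f"{nat} {o[0]:.12f} {o[1]:.12f} {o[2]:.12f}")
    for i in range(3):
        v = np.zeros(3)
        v[i] = step * scale
        lines.append(f"{sign * counts[i]} {v[0]:.12f} {v[1]:.12f} {v[2]:.12f}")
    for z, pos in atoms:
        p = np.asarray(pos, float) * scale
        lines.append(f"{z} {float(z):.6f} {p[0]:.12f} {p[1]:.12f} {p[2]:.12f}")
    if orbital:
        lines.append("1 1")
    flat = np.asarray(values, float).ravel()
    for k in range(0, flat.size, 6):
        lines.append(" ".join(f"{x:.6e}" for x in flat[k:k + 6]))
    return "\n".join(lines) + "\n"
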