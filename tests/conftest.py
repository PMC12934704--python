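"""Shared fixtures: restraint library and synthetic tangled models.

Everything is generated programmatically; session scope keeps the
refinement-heavy fixtures to one construction each.
"""

import numpy as np
import pytest

from untangler.restraints import RestraintLibrary
from untangler.synthetic import FixtureSpec, make_toy_ensemble


@pytest.fixture(scope="session")
def library():
    return RestraintLibrary.load()


@pytest.fixture(scope="session")
def fx_single(library):
    """High-strain single-swap trap (8 split groups)."""
    return make_toy_ensemble(
        FixtureSpec(n_residues=2, tangle_mode="single_swap", seed=1),
        library=library)


@pytest.fixture(scope="session")
def fx_none(library):
    """Untangled fixture: the tangled slot holds the refined ground truth."""
    return make_toy_ensemble(
        FixtureSpec(n_residues=3, tangle_mode="none", seed=3),
        library=library)


@pytest.fixture(scope="session")
def fx_block(library):
    """Contiguous 2-residue block swap in a 4-residue chain."""
    return make_toy_ensemble(
        FixtureSpec(n_residues=4, tangle_mode="block_swap", block_window=2,
                    seed=7),
        library=library)


@pytest.fixture(scope="session")
def fx_water(library):
    """Low-strain trap: a mis-assigned split water clashing with its
    cognate side chain."""
    return make_toy_ensemble(
        FixtureSpec(n_residues=3, tangle_mode="water_swap", waters=1,
                    seed=2),
        library=library)


def two_residue_peptide_pdb() -> str:
    """A hand-written two-residue ALA-ALA PDB with CB of residue 2 split."""
    lines = []
    rows = [
        ("N", "", 1, (0.000, 0.000, 0.000), 1.00),
        ("CA", "", 1, (1.458, 0.000, 0.000), 1.00),
        ("C", "", 1, (2.009, 1.420, 0.000), 1.00),
        ("O", "", 1, (1.251, 2.390, 0.000), 1.00),
        ("CB", "", 1, (2.000, -0.700, -1.200), 1.00),
        ("N", "", 2, (3.332, 1.536, 0.000), 1.00),
        ("CA", "", 2, (4.023, 2.825, 0.000), 1.00),
        ("C", "", 2, (5.530, 2.688, 0.000), 1.00),
        ("O", "", 2, (6.090, 1.590, 0.000), 1.00),
        ("OXT", "", 2, (6.200, 3.730, 0.000), 1.00),
        ("CB", "A", 2, (3.600, 3.650, 1.220), 0.50),
        ("CB", "B", 2, (3.600, 3.650, -1.220), 0.50),
    ]
    serial = 1
    for name, alt, resnum, (x, y, z), occ in rows:
        elem = name[0]
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{alt or ' '}ALA A{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{15.0:6.2f}          "
            f"{elem:>2s}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def peptide_pdb(tmp_path):
    path = tmp_path / "dipeptide.pdb"
    path.write_text(two_residue_peptide_pdb())
    return path
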