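import numpy as np
import pytest

from bdpath import BDParams, FixtureSpec, make_two_state, run_transition


def pdb_line(serial, resname, chain, resnum, x, y, z, *, name=" CA ", altloc=" ",
             icode=" ", occ=1.0, record="ATOM  ", element="C"):
    """One fixed-width PDB coordinate record."""
    return (f"{record}{serial:>5} {name}{altloc}{resname:>3} {chain}{resnum:>4}"
            f"{icode}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{0.0:>6.2f}"
            f"           {element}")


def simple_pdb(coords, chain="A", start_resnum=1):
    lines = [pdb_line(i + 1, "ALA", chain, start_resnum + i, *xyz)
             for i, xyz in enumerate(coords)]
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture(scope="session")
def hinge_pair():
    """The standard 60-residue two-state hinge (~8 Å end-state RMSD)."""
    return make_two_state(FixtureSpec(n_residues=60, motion="hinge", amplitude=75.0))


@pytest.fixture(scope="session")
def hinge_path(hinge_pair):
    """One sampled transition on the standard hinge, default parameters."""
    return run_transition(hinge_pair.start, hinge_pair.target,
                          bd_params=BDParams(seed=1))
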