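import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cntkit.builder import (
    NanotubeSpec,
    build_armchair_swcnt,
    carboxylate_edges,
)
from cntkit.model import AtomRecord, Structure


@pytest.fixture(scope="session")
def small_tube():
    """(5,5) tube, ~1 nm, no carboxyls."""
    return build_armchair_swcnt(NanotubeSpec(n=5, target_length=1.0))


@pytest.fixture(scope="session")
def small_ctube():
    """(5,5) tube with 4 carboxylates."""
    tube = build_armchair_swcnt(NanotubeSpec(n=5, target_length=1.0, carboxyl_count=4))
    return carboxylate_edges(tube, 4, seed=0)


@pytest.fixture(scope="session")
def default_tube():
    """The (12,12) / 7.0 nm tube."""
    return build_armchair_swcnt(NanotubeSpec(n=12, target_length=7.0))


def make_structure(entries, groups=None, box=None):
    """entries: (name, element, resname, resid, chain, xyz)."""
    atoms = [
        AtomRecord(
            index=i,
            name=name,
            element=element,
            residue_name=resname,
            residue_id=resid,
            chain_id=chain,
            position=tuple(xyz),
        )
        for i, (name, element, resname, resid, chain, xyz) in enumerate(entries)
    ]
    return Structure(atoms=atoms, groups=groups or {}, box=box)


@pytest.fixture
def toy_protein():
    """Compact body with three lining residues (10-12) forming a mouth at
    +x and filler bulk behind it, so mouth centroid != center of geometry."""
    entries = []
    # bulk: a 3x3x3 grid of CA pseudo-atoms centred at origin
    resid = 100
    for ix in range(3):
        for iy in range(3):
            for iz in range(3):
                entries.append(
                    ("CA", "C", "ALA", resid, "A",
                     (0.3 * (ix - 1), 0.3 * (iy - 1), 0.3 * (iz - 1)))
                )
                resid += 1
    # mouth: lining Calphas on a small ring at x = +0.6
    for k, resid in enumerate((10, 11, 12)):
        theta = 2 * np.pi * k / 3
        entries.append(
            ("CA", "C", "GLY", resid, "A",
             (0.6, 0.25 * np.cos(theta), 0.25 * np.sin(theta)))
        )
    return make_structure(entries)
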