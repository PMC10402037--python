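import numpy as np
import pandas as pd
import pytest

import pairbondmap as pbm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def design12():
    """Full study-scale design (12 pairs per cell, 192 animals)."""
    return pbm.generate_design(12)


@pytest.fixture(scope="session")
def design2():
    """Small design (2 pairs per cell, 32 animals)."""
    return pbm.generate_design(2)


def random_tree(rng, n_nodes: int) -> pbm.AtlasHierarchy:
    """Random rooted tree built edge by edge (independent of generate_atlas)."""
    nodes = [pbm.StructureNode(id=1, acronym="n1", name="n1", parent_id=None)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes.append(
            pbm.StructureNode(id=i, acronym=f"n{i}", name=f"n{i}", parent_id=parent)
        )
    return pbm.AtlasHierarchy(nodes)


@pytest.fixture
def mini_design():
    """Hand-built 6-pair design over 3 timepoints for exhaustive tests."""
    rows = []
    specs = [
        ("P1", "mate", ("F", "M"), 1, 1),
        ("P2", "sibling", ("F", "F"), 1, 1),
        ("P3", "mate", ("F", "M"), 2, 2),
        ("P4", "sibling", ("M", "M"), 2, 2),
        ("P5", "mate", ("F", "M"), 3, 1),
        ("P6", "sibling", ("F", "F"), 3, 2),
    ]
    i = 0
    for pid, ptype, sexes, tp, block in specs:
        for sex in sexes:
            i += 1
            rows.append(
                {
                    "animal_id": f"A{i:02d}",
                    "pair_id": pid,
                    "sex": sex,
                    "partner_type": ptype,
                    "timepoint": tp,
                    "block": block,
                    "behavior_included": True,
                    "ieg_included": True,
                }
            )
    return pd.DataFrame(rows)
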