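import pytest
from hypothesis import HealthCheck, settings

from nfymap.contact_map import build_contact_map
from nfymap.structure_io import parse_pdb, select
from nfymap.synthetic_data import (PlantedContactSpec, make_paired_structures,
                                   make_toy_structure)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# six planted contacts, two per distance-rule family, all >=0.5 A inside
# their cutoffs (hbond O/N limit 3.5 -> planted at 3.0)
SIX_PLANTED = [
    PlantedContactSpec("hydrophobic", "LEU", "LEU", 4.5),
    PlantedContactSpec("hydrophobic", "ILE", "VAL", 4.0),
    PlantedContactSpec("ionic", "LYS", "GLU", 5.5),
    PlantedContactSpec("ionic", "ARG", "ASP", 5.0),
    PlantedContactSpec("hbond", "SER", "ASP", 3.0),
    PlantedContactSpec("cation_pi", "LYS", "PHE", 5.0),
]


@pytest.fixture(scope="session")
def toy_fixture():
    """Toy interface with 6 planted contacts, 10 decoys and a DNA stub."""
    text, truth = make_toy_structure(SIX_PLANTED, decoys=10, dna=True, seed=7)
    structure = parse_pdb(text, "toy")
    return structure, truth


@pytest.fixture(scope="session")
def toy_map(toy_fixture):
    structure, truth = toy_fixture
    side_a = select(structure, "A", "all")
    side_b = select(structure, "B", "all")
    dna = select(structure, "D", "all")
    return build_contact_map(side_a, side_b, dna=dna, source="toy"), truth


@pytest.fixture(scope="session")
def paired_fixture():
    """Two structures sharing two contacts, one extra on each side."""
    shared = SIX_PLANTED[:2]
    a_only = [SIX_PLANTED[2], SIX_PLANTED[4]]
    b_only = [SIX_PLANTED[3], SIX_PLANTED[5]]
    return make_paired_structures(shared, a_only, b_only, decoys=3, seed=11)


def build_maps(pair):
    """Contact maps of a PairedFixture, full chain A vs chain B."""
    maps = []
    for text, sid in ((pair.pdb_a, "synthA"), (pair.pdb_b, "synthB")):
        structure = parse_pdb(text, sid)
        maps.append(build_contact_map(select(structure, "A", "all"),
                                      select(structure, "B", "all"),
                                      source=sid))
    return maps
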