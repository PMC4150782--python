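import numpy as np
import pytest

from hydrna.structure_io import AtomRecord, parse_structure
from hydrna.reporting import analyze_complex
from hydrna.synthetic import GeneratorSpec, make_complex


def make_atom(name="O", element=None, res_name="HOH", chain="W", res_seq=1,
              xyz=(0.0, 0.0, 0.0), occupancy=1.0, serial=1, i_code=""):
    """Shorthand AtomRecord constructor for unit tests."""
    if element is None:
        element = next(c for c in name if c.isalpha()).upper()
    return AtomRecord(serial=serial, name=name, element=element, alt_loc="",
                      res_name=res_name, chain_id=chain, res_seq=res_seq,
                      i_code=i_code, xyz=np.asarray(xyz, dtype=float),
                      occupancy=occupancy, is_hetero=res_name == "HOH")


@pytest.fixture(scope="session")
def bridging_complex():
    """One seeded complex with 5 planted bridging waters, analyzed."""
    spec = GeneratorSpec(seed=11, n_waters=12, n_bridging_planted=5)
    pdb, truth = make_complex(spec)
    model = parse_structure(pdb)
    return pdb, truth, model, analyze_complex(model)


@pytest.fixture(scope="session")
def groove_complex():
    """End-cap docked complex with groove-anchored bridging waters."""
    spec = GeneratorSpec(seed=7, n_waters=5, n_bridging_planted=5,
                         n_major_contacts=2, n_minor_contacts=1)
    pdb, truth = make_complex(spec)
    model = parse_structure(pdb)
    return pdb, truth, model, analyze_complex(model)
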