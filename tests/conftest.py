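import pytest

from zfscreen.chem import make_compound
from zfscreen.synth import SynthConfig, generate_library

# A small, chemically varied set of real drug-like structures.
DRUG_SMILES = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibmx": "CC(C)Cn1c(=O)c2[nH]cnc2n(C)c1=O",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "nifedipine": "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]",
    "nitrendipine": "CCOC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1cccc(c1)[N+](=O)[O-]",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "ethanol": "CCO",
}


def compound(cid, smiles, library="T", plate="T01", well="B02", name=""):
    return make_compound(cid, library, plate, well, name or cid, smiles)


@pytest.fixture(scope="session")
def drug_compounds():
    return [compound(name, smi) for name, smi in DRUG_SMILES.items()]


@pytest.fixture(scope="session")
def small_library():
    """A 60-compound synthetic library with family structure (seeded)."""
    cfg = SynthConfig(n_compounds=(20, 40), duplicate_fraction=0.1, seed=7)
    return generate_library(cfg)
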