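import numpy as np
import pytest

from attasm.sitelib import default_library
from attasm.seqmodel import DnaMolecule, Feature


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture
def rng():
    return np.random.default_rng(20130228)


def random_molecule(rng, lib, topology="circular", n_sites=0, site_specs=None,
                    length=120, mol_id="mol"):
    """A random molecule with library sites placed at non-overlapping spots."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    sites = []
    pos = rng.integers(0, 8)
    for spec in site_specs or []:
        s = lib.site(*spec[:2], state=spec[2], start=int(pos))
        sites.append(s)
        seq = seq[: s.start] + s.site_seq() + seq[s.start :]
        pos = s.end + int(rng.integers(4, 12))
    return DnaMolecule(mol_id, topology, seq, [], sites)
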