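import numpy as np
import pytest

from gpcrpocket.energy import ScoreConfig
from gpcrpocket.params import ParameterTable
from gpcrpocket.synth import (BundleSpec, DEFAULT_PLANTED_LABELS,
                              PlantedEnsembleSpec, build_bundle_receptor,
                              generate_planted_ensemble, place_peptide)


@pytest.fixture(scope="session")
def params():
    return ParameterTable.default()


@pytest.fixture(scope="session")
def cfg():
    return ScoreConfig()


@pytest.fixture(scope="session")
def bundle():
    """Toy seven-helix bundle plus its ground-truth anchors."""
    return build_bundle_receptor(BundleSpec())


@pytest.fixture(scope="session")
def planted_complex():
    """One receptor with a peptide contacting every default planted label."""
    receptor, anchors = build_bundle_receptor(BundleSpec())
    cs = place_peptide(receptor, anchors, DEFAULT_PLANTED_LABELS,
                       peptide_length=24, seed=5)
    return cs, anchors


@pytest.fixture(scope="session")
def ensemble9():
    """The nine-complex planted ensemble under default study conditions."""
    return generate_planted_ensemble(PlantedEnsembleSpec(seed=11))


def make_residue(name3, atom_specs, chain_id="A", seq=1, icode=""):
    """Helper: ResidueRecord from (atom_name, element, xyz) triples."""
    from gpcrpocket.structure_io import AtomRecord, ResidueRecord
    atoms = [AtomRecord(n, e, np.asarray(c, dtype=float)) for n, e, c in atom_specs]
    return ResidueRecord(chain_id=chain_id, seq_number=seq, insertion_code=icode,
                         name3=name3, atoms=atoms)
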