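import numpy as np
import pytest

from xlcal.fixtures import lobster_model, make_crosslink_table
from xlcal.restraints import RestraintPolicy, build_restraints
from xlcal.xlms import CrosslinkRecord, dedupe_to_residue_pairs


@pytest.fixture(scope="session")
def lobster():
    """Canonical single-chain helical-bundle fixture with planted lysines."""
    return lobster_model()


@pytest.fixture(scope="session")
def lobster_pairs(lobster):
    """14 unique intra-chain pairs sampled from the fixture's reachable lysines."""
    table = make_crosslink_table(lobster, n_pairs=14, psm_multiplicity=3, seed=7)
    records = [
        CrosslinkRecord(
            protein_a=r.protein_a, peptide_a=r.peptide_a, link_pos_a=int(r.link_pos_a),
            protein_b=r.protein_b, peptide_b=r.peptide_b, link_pos_b=int(r.link_pos_b),
            charge=int(r.charge), psm_id=r.psm_id,
        )
        for r in table.itertuples()
    ]
    return dedupe_to_residue_pairs(records)


@pytest.fixture(scope="session")
def lobster_restraints(lobster_pairs):
    return build_restraints(lobster_pairs, RestraintPolicy())


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
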