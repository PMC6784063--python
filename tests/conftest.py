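import numpy as np
import pytest

from fcensemble.structure_io import AtomRecord, Structure
from fcensemble.synthetic import SyntheticEnsembleConfig, build_template, generate_ensemble


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def small_ensemble(template):
    cfg = SyntheticEnsembleConfig(n_conformers=30, seed=11)
    return generate_ensemble(template, cfg)


@pytest.fixture(scope="session")
def angle_recovery_ensemble(template):
    """n = 1000 ensemble at the default angle distribution (mean 90, sd 10)."""
    cfg = SyntheticEnsembleConfig(n_conformers=1000, seed=2024)
    return generate_ensemble(template, cfg)


def make_atom(serial=1, name="CA", element="C", res_name="GLY", chain="A",
              res_seq=1, xyz=(0.0, 0.0, 0.0), occupancy=1.0, alt_loc="",
              hetero=False):
    return AtomRecord(
        serial=serial, name=name, element=element, alt_loc=alt_loc,
        res_name=res_name, chain_id=chain, res_seq=res_seq, i_code="",
        xyz=tuple(float(v) for v in xyz), occupancy=occupancy, b_factor=0.0,
        is_hetero=hetero,
    )


def point_structure(points, chain="A", res_start=1, res_name="GLY"):
    """One CA-only residue per point — convenient rigid test bodies."""
    atoms = [
        make_atom(serial=i + 1, res_seq=res_start + i, chain=chain, xyz=p)
        for i, p in enumerate(np.asarray(points, dtype=float))
    ]
    return Structure(atoms=atoms, id="points")
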