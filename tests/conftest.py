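import numpy as np
import pytest

from lidflex import enm
from lidflex.io import Structure


def make_structure(atoms, title=""):
    """Build a Structure from (chain, resid, resname, atom, element, xyz) tuples."""
    return Structure(
        chain_ids=np.array([a[0] for a in atoms], dtype=object),
        res_ids=np.array([a[1] for a in atoms]),
        res_names=np.array([a[2] for a in atoms], dtype=object),
        atom_names=np.array([a[3] for a in atoms], dtype=object),
        elements=np.array([a[4] for a in atoms], dtype=object),
        coords=np.array([a[5] for a in atoms], dtype=float),
        title=title,
    )


GLY_PDB = """\
TITLE     toy glycine
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def gly_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    return path


@pytest.fixture(scope="session")
def ring20():
    return enm.make_ring(20)


@pytest.fixture(scope="session")
def cluster20():
    return enm.make_compact_cluster(20)


@pytest.fixture(scope="session")
def protein161():
    return enm.make_test_protein()


@pytest.fixture(scope="session")
def ring_model(ring20):
    return enm.build_enm(ring20, cutoff=10.0, gamma=50.0)


@pytest.fixture(scope="session")
def ring_ensemble(ring_model):
    return enm.sample_ensemble(ring_model, 5000, seed=101)


@pytest.fixture(scope="session")
def lid_model(protein161):
    return enm.build_enm(protein161, cutoff=10.0, gamma=50.0)


@pytest.fixture(scope="session")
def lid_two_state(protein161, lid_model):
    """(ensemble, planted) with open occupancy 2/3 and 4 A displacement."""
    from lidflex.io import select

    lid_mask = select(protein161, "ca and resid 182-199")
    planted = enm.plant_two_state_lid(lid_model, lid_mask,
                                      open_occupancy=2 / 3, displacement=4.0)
    ensemble = enm.sample_ensemble(lid_model, 600, seed=103, planted=planted)
    return ensemble, planted


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Demo workspace plus the pipeline report computed on it (built once)."""
    import time

    from lidflex.pipeline import AnalysisConfig, make_demo, run_pipeline

    outdir = tmp_path_factory.mktemp("demo")
    t0 = time.time()
    config_path = make_demo(seed=11, outdir=outdir)
    config = AnalysisConfig.from_yaml(config_path)
    report = run_pipeline(config)
    elapsed = time.time() - t0
    return outdir, config_path, report, elapsed
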