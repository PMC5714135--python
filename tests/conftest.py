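import numpy as np
import pytest

import recascan as rs

# Root seed for the seeded statistical tests in this suite.
SUITE_SEED = 20170831


@pytest.fixture(scope="session")
def params37():
    return rs.preset("37C")


@pytest.fixture(scope="session")
def image_config():
    return rs.ImageConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Renderer config with the noise switched off (analytic height checks)."""
    return rs.ImageConfig(noise_sd_nm=0.0)


def match_trace_to_truth(trace, truth):
    """Nearest ground-truth molecule by polyline centroid; (molecule, dist)."""
    c = trace.vertices_nm.mean(axis=0)
    dists = [
        float(np.linalg.norm(c - m.vertices_nm.mean(axis=0)))
        for m in truth.molecules
    ]
    k = int(np.argmin(dists))
    return truth.molecules[k], dists[k]


def truth_category(molecule, params):
    """Operational category of a ground-truth molecule."""
    joints = [
        rs.BoundFilament(f.position_bp, f.state, 0.0)
        for f in molecule.filaments
    ]
    from recascan.kinetic_model import molecule_category

    return molecule_category(joints, params, operational=True)
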