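import numpy as np
import pytest
from hypothesis import settings

from kinkgate.synthetic import SyntheticSpec, generate
from kinkgate.trajectory_io import (
    ATOMIC_MASSES,
    VDW_RADII_NM,
    FrameSeries,
    Topology,
    infer_element,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def build_topology(rows):
    """Topology from rows of (atom_name, resname, resid, subunit)."""
    names = [r[0] for r in rows]
    elements = [infer_element(n) for n in names]
    return Topology(
        atom_name=names,
        residue_name=[r[1] for r in rows],
        residue_id=[r[2] for r in rows],
        subunit=[r[3] for r in rows],
        element=elements,
        vdw_radius=[VDW_RADII_NM.get(e, 0.17) for e in elements],
    )


def make_frames(coords, box=(10.0, 10.0, 10.0), dt=0.1):
    """FrameSeries from (n_frames, n_atoms, 3) or (n_atoms, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[0]
    return FrameSeries(
        times=np.arange(n) * dt,
        coordinates=coords,
        box=np.broadcast_to(np.asarray(box, float), (n, 3)).copy(),
    )


def tetramer_points(points_by_subunit):
    """Rows + coords for one named atom per subunit (A-D in order)."""
    rows, coords = [], []
    for sub, (name, resname, resid, xyz) in zip("ABCD", points_by_subunit):
        rows.append((name, resname, resid, sub))
        coords.append(xyz)
    return build_topology(rows), np.asarray(coords, dtype=float)


@pytest.fixture(scope="session")
def default_system():
    """A 200 ns mixed-state replicate at the default (high-current-like)
    conditions, shared read-only across tests."""
    return generate(SyntheticSpec(n_frames=2000, seed=7))


@pytest.fixture(scope="session")
def noiseless_system():
    """Short noise-free replicate: descriptors must equal the templates."""
    return generate(
        SyntheticSpec(
            n_frames=200,
            seed=11,
            noise_sigma=0.0,
            water_jitter=0.0,
            ion_jitter=0.0,
            lipid_jitter=0.0,
        )
    )
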