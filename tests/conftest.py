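import numpy as np
import pytest

from bilayerlab.core import AnalysisConfig
from bilayerlab.core.trajectory import Trajectory


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def make_bilayer():
    """Factory for small hand-built bilayer trajectories.

    Creates n_per_leaflet phosphorus particles at +z_p and -z_p (optionally
    with noise), a fixed box, and optional solute tracks supplied as an
    (F, S) z array.
    """

    def _make(
        n_frames=5,
        n_per_leaflet=4,
        z_p=20.0,
        box=(80.0, 80.0, 100.0),
        dt=1.0,
        solute_z=None,
        rng=None,
    ):
        n_p = 2 * n_per_leaflet
        n_s = 0 if solute_z is None else solute_z.shape[1]
        coords = np.zeros((n_frames, n_p + n_s, 3))
        if rng is not None:
            coords[:, :n_p, :2] = rng.uniform(0, box[0], size=(n_frames, n_p, 2))
        coords[:, :n_per_leaflet, 2] = z_p
        coords[:, n_per_leaflet:n_p, 2] = -z_p
        roles = np.array(
            ["phosphorus"] * n_p + ["solute_com"] * n_s, dtype=object
        )
        mol_ids = np.arange(n_p + n_s)
        if solute_z is not None:
            coords[:, n_p:, 2] = solute_z
        return Trajectory(
            times=np.arange(n_frames) * dt,
            boxes=np.tile(np.asarray(box, dtype=float), (n_frames, 1)),
            coords=coords,
            roles=roles,
            molecule_ids=mol_ids,
        )

    return _make
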