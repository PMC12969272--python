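"""Leaflet assignment from phosphate (and polar-marker) z positions.

Membership is frozen at a reference frame: a molecule is `upper` if its
marker sits above the phosphate midplane there, `lower` otherwise.
Molecules that later change sides are logged as flip events but never
reassigned, so every per-leaflet statistic uses a fixed population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from bilayerlab.core.trajectory import Trajectory, TrajectoryError

logger = logging.getLogger(__name__)


class DegenerateBilayerError(TrajectoryError):
    """All marker molecules lie on one side of the midplane."""


@dataclass
class FlipEvent:
    molecule_id: int
    frame: int
    from_leaflet: str
    to_leaflet: str


@dataclass
class LeafletMap:
    assignment: dict[int, str]            # molecule_id -> upper | lower
    midplane_z: np.ndarray                # (F,) per-frame mean phosphorus z
    reference_frame: int
    flips: list[FlipEvent] = field(default_factory=list)

    def molecules(self, leaflet: str) -> np.ndarray:
        return np.array(
            sorted(m for m, side in self.assignment.items() if side == leaflet),
            dtype=int,
        )

    @property
    def n_upper(self) -> int:
        return sum(1 for s in self.assignment.values() if s == "upper")

    @property
    def n_lower(self) -> int:
        return sum(1 for s in self.assignment.values() if s == "lower")


def _marker_z(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-molecule marker z series.

    Returns (molecule ids, (F, M) z array, boolean mask of phosphorus-bearing
    molecules).  Phosphorus particles define the marker where present;
    molecules with only a polar_marker (hopanoids) use that instead.
    """
    p_idx = traj.indices("phosphorus")
    m_idx = traj.indices("polar_marker")
    if len(p_idx) == 0:
        raise TrajectoryError("no phosphorus particles tagged; cannot assign leaflets")

    p_mols = set(traj.molecule_ids[p_idx].tolist())
    marker_idx = list(p_idx) + [
        i for i in m_idx if traj.molecule_ids[i] not in p_mols
    ]
    marker_idx = np.array(marker_idx, dtype=int)
    mol_of_marker = traj.molecule_ids[marker_idx]
    mols, inverse = np.unique(mol_of_marker, return_inverse=True)

    z = traj.coords[:, marker_idx, 2]  # (F, K)
    # mean of markers per molecule (handles multi-phosphorus lipids like CL)
    counts = np.bincount(inverse, minlength=len(mols)).astype(float)
    sums = np.zeros((traj.n_frames, len(mols)))
    np.add.at(sums.T, inverse, z.T)
    z_mol = sums / counts
    is_p = np.array([m in p_mols for m in mols])
    return mols, z_mol, is_p


def assign_leaflets(traj: Trajectory, reference_frame: int = 0) -> LeafletMap:
    """Assign every marker-bearing molecule to a leaflet.

    The midplane is the per-frame mean of all phosphorus z (robust to
    membrane drift, unlike the box center).  Requires at least two
    molecules on each side at the reference frame.
    """
    mols, z_mol, is_p = _marker_z(traj)
    p_idx = traj.indices("phosphorus")
    midplane = traj.coords[:, p_idx, 2].mean(axis=1)  # (F,)

    if not 0 <= reference_frame < traj.n_frames:
        raise TrajectoryError(f"reference frame {reference_frame} out of range")

    side = np.where(z_mol - midplane[:, None] >= 0, "upper", "lower")
    ref_side = side[reference_frame]
    n_up = int(np.sum(ref_side == "upper"))
    n_lo = len(mols) - n_up
    if n_up < 2 or n_lo < 2:
        raise DegenerateBilayerError(
            f"degenerate bilayer: {n_up} upper / {n_lo} lower molecules at "
            f"reference frame {reference_frame}"
        )

    assignment = {int(m): str(s) for m, s in zip(mols, ref_side)}

    flips: list[FlipEvent] = []
    changed = side != ref_side[None, :]
    for j in np.flatnonzero(changed.any(axis=0)):
        frames = np.flatnonzero(changed[:, j])
        first = int(frames[0])
        ev = FlipEvent(
            molecule_id=int(mols[j]),
            frame=first,
            from_leaflet=str(ref_side[j]),
            to_leaflet=str(side[first, j]),
        )
        flips.append(ev)
        logger.info(
            "leaflet flip logged (not reassigned): molecule %d crosses midplane "
            "at frame %d (%s -> %s)",
            ev.molecule_id, ev.frame, ev.from_leaflet, ev.to_leaflet,
        )

    return LeafletMap(
        assignment=assignment,
        midplane_z=midplane,
        reference_frame=reference_frame,
        flips=flips,
    )
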