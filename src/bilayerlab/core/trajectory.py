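"""In-memory trajectory model plus readers/writers for standard MD formats.

Coordinates are stored in a dense ``(n_frames, n_particles, 3)`` array in
Angstrom, times in ns.  Each particle carries a fixed role tag:

- ``phosphorus``     lipid phosphate marker (leaflets, thickness, diffusion)
- ``chain_carbon`` / ``chain_hydrogen``   acyl C-H pairs (order parameter)
- ``solute_com``     solute center-of-mass tracks (PMF, permeability)
- ``polar_marker``   polar-end marker for tail-less lipids such as hopanoids
- ``other``          everything else (ignored by the analyses)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ROLES = (
    "phosphorus",
    "chain_carbon",
    "chain_hydrogen",
    "solute_com",
    "polar_marker",
    "other",
)

#: atom name used for each role when writing standard formats (and the
#: default selection used to recover the role when reading them back)
ROLE_ATOM_NAMES = {
    "phosphorus": "P",
    "chain_carbon": "C",
    "chain_hydrogen": "H",
    "solute_com": "S",
    "polar_marker": "O",
}

DEFAULT_ROLE_SPEC = {role: f"name {name}" for role, name in ROLE_ATOM_NAMES.items()}

#: allowed relative jitter in frame spacing before sampling is non-uniform
FRAME_INTERVAL_RTOL = 0.01


class TrajectoryError(ValueError):
    pass


class MissingUnitCellError(TrajectoryError):
    """A frame has no periodic box; the lateral-area analyses are undefined."""


@dataclass(frozen=True)
class TrajectoryFrame:
    """Read-only view of a single frame."""

    time: float
    box_lengths: np.ndarray
    coords: np.ndarray
    particle_roles: np.ndarray
    molecule_ids: np.ndarray


@dataclass
class Trajectory:
    times: np.ndarray            # (F,) ns
    boxes: np.ndarray            # (F, 3) A
    coords: np.ndarray           # (F, N, 3) A
    roles: np.ndarray            # (N,) strings from ROLES
    molecule_ids: np.ndarray     # (N,) int
    ch_pairs: np.ndarray | None = None   # (P, 2) indices (carbon, hydrogen)
    replica_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(f"coords must be (F, N, 3), got {self.coords.shape}")
        F, N, _ = self.coords.shape
        if self.times.shape != (F,) or self.boxes.shape != (F, 3):
            raise TrajectoryError("times/boxes shape inconsistent with coords")
        if self.roles.shape != (N,) or self.molecule_ids.shape != (N,):
            raise TrajectoryError("roles/molecule_ids shape inconsistent with coords")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise TrajectoryError(f"unknown particle roles: {sorted(unknown)}")
        if not np.all(self.boxes > 0):
            raise MissingUnitCellError("non-positive box lengths in at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("non-finite coordinates")
        if F > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        self._validate_ch_pairs()

    def _validate_ch_pairs(self) -> None:
        n_h = int(np.sum(self.roles == "chain_hydrogen"))
        if self.ch_pairs is None:
            if n_h:
                raise TrajectoryError(
                    f"{n_h} chain_hydrogen particles present but no ch_pairs given"
                )
            return
        self.ch_pairs = np.asarray(self.ch_pairs, dtype=int)
        if self.ch_pairs.ndim != 2 or self.ch_pairs.shape[1] != 2:
            raise TrajectoryError("ch_pairs must be (P, 2)")
        c, h = self.ch_pairs[:, 0], self.ch_pairs[:, 1]
        if not (np.all(self.roles[c] == "chain_carbon")
                and np.all(self.roles[h] == "chain_hydrogen")):
            raise TrajectoryError("ch_pairs must index (chain_carbon, chain_hydrogen)")
        if len(np.unique(h)) != len(h) or len(h) != n_h:
            raise TrajectoryError("every chain_hydrogen must appear in exactly one pair")

    # -- basic accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_interval(self) -> float:
        """Uniform frame spacing in ns (0.0 for single-frame trajectories)."""
        if self.n_frames < 2:
            return 0.0
        dt = np.diff(self.times)
        ref = float(np.median(dt))
        if np.max(np.abs(dt - ref)) > FRAME_INTERVAL_RTOL * ref:
            raise TrajectoryError(
                "non-uniform frame spacing (>1% jitter); resample before analysis"
            )
        return ref

    def frame(self, i: int) -> TrajectoryFrame:
        return TrajectoryFrame(
            time=float(self.times[i]),
            box_lengths=self.boxes[i],
            coords=self.coords[i],
            particle_roles=self.roles,
            molecule_ids=self.molecule_ids,
        )

    def indices(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise TrajectoryError(f"unknown role {role!r}")
        return np.flatnonzero(self.roles == role)

    def duration(self) -> float:
        """Analyzed time span in ns (n_frames * frame_interval)."""
        return self.n_frames * self.frame_interval


def select_window(traj: Trajectory, cfg) -> Trajectory:
    """Drop the leading equilibration fraction of frames.

    ``floor(fraction * n_frames)`` frames are discarded, so the retained
    window holds ``ceil((1 - fraction) * n_frames)`` frames; with fraction
    0.2 of a 1000-frame run, frames 200..999 remain.
    """
    frac = cfg.equilibration_fraction
    n = traj.n_frames
    n_drop = int(np.floor(frac * n))
    if n_drop >= n:
        raise TrajectoryError("equilibration window leaves no frames")
    if n_drop == 0:
        return traj
    return Trajectory(
        times=traj.times[n_drop:],
        boxes=traj.boxes[n_drop:],
        coords=traj.coords[n_drop:],
        roles=traj.roles,
        molecule_ids=traj.molecule_ids,
        ch_pairs=traj.ch_pairs,
        replica_id=traj.replica_id,
        metadata=dict(traj.metadata),
    )


# ---------------------------------------------------------------------------
# Standard-format IO (PDB topology + DCD coordinates via MDAnalysis)
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, directory: str | Path, stem: str = "traj"):
    """Write the trajectory as ``<stem>.pdb`` + ``<stem>.dcd``.

    Atom names encode roles (see ROLE_ATOM_NAMES); residue ids encode
    molecule ids.  Returns ``(topology_path, coords_path)``.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    top_path = directory / f"{stem}.pdb"
    dcd_path = directory / f"{stem}.dcd"

    n = traj.n_particles
    mol_ids = traj.molecule_ids
    uniq, resindex = np.unique(mol_ids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=resindex, trajectory=True
    )
    names = [ROLE_ATOM_NAMES.get(r, "X") for r in traj.roles]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", (uniq % 9999) + 1)
    u.add_TopologyAttr("resnames", ["MOL"] * len(uniq))

    interval_ps = (traj.frame_interval or 1.0) * 1000.0
    u.atoms.positions = traj.coords[0]
    u.dimensions = [*traj.boxes[0], 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(top_path))
        with DCDWriter(str(dcd_path), n, dt=interval_ps) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i]
                u.dimensions = [*traj.boxes[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)
    return top_path, dcd_path


def load_trajectory(
    topology: str | Path,
    coords: str | Path,
    role_spec: dict[str, str] | None = None,
    replica_id: int = 0,
) -> Trajectory:
    """Read a trajectory from standard MD formats (PDB/PSF + DCD/XTC).

    ``role_spec`` maps role names to MDAnalysis selection strings; particles
    matching no selection are tagged ``other``.  Chain C-H pairs are formed by
    pairing the k-th selected carbon with the k-th selected hydrogen within
    each molecule (the writer above guarantees this ordering).
    """
    import MDAnalysis as mda

    explicit = role_spec is not None
    role_spec = dict(role_spec) if explicit else dict(DEFAULT_ROLE_SPEC)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), str(coords))
    n = len(u.atoms)

    roles = np.array(["other"] * n, dtype=object)
    for role, sel in role_spec.items():
        if role not in ROLES:
            raise TrajectoryError(f"role_spec contains unknown role {role!r}")
        group = u.select_atoms(sel)
        if len(group) == 0:
            if explicit:
                raise TrajectoryError(
                    f"role selection for {role!r} matched no atoms: {sel!r}"
                )
            continue  # default spec: absent roles are simply not present
        roles[group.indices] = role

    molecule_ids = np.asarray(u.atoms.resindices, dtype=int)

    ch_pairs = None
    c_idx = np.flatnonzero(roles == "chain_carbon")
    h_idx = np.flatnonzero(roles == "chain_hydrogen")
    if len(h_idx):
        pairs = []
        for mol in np.unique(molecule_ids[h_idx]):
            cm = c_idx[molecule_ids[c_idx] == mol]
            hm = h_idx[molecule_ids[h_idx] == mol]
            if len(cm) != len(hm):
                raise TrajectoryError(
                    f"molecule {mol}: {len(cm)} chain carbons vs {len(hm)} hydrogens; "
                    "cannot pair C-H by order"
                )
            pairs.extend(zip(cm, hm))
        ch_pairs = np.array(pairs, dtype=int)

    times, boxes, xyz = [], [], []
    for ts in u.trajectory:
        if ts.dimensions is None or not np.all(np.asarray(ts.dimensions[:3]) > 0):
            raise MissingUnitCellError(
                f"frame {ts.frame}: unit cell absent; lateral area is undefined"
            )
        times.append(ts.time / 1000.0)  # ps -> ns
        boxes.append(np.array(ts.dimensions[:3], dtype=float))
        xyz.append(ts.positions.astype(float).copy())

    return Trajectory(
        times=np.array(times),
        boxes=np.array(boxes),
        coords=np.array(xyz),
        roles=roles,
        molecule_ids=molecule_ids,
        ch_pairs=ch_pairs,
        replica_id=replica_id,
    )
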