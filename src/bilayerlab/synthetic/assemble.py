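"""Assemble component generators into a full Trajectory plus a ground-truth sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from bilayerlab.core.trajectory import Trajectory
from bilayerlab.synthetic.generators import (
    generate_box_and_phosphates,
    generate_chain_vectors,
    generate_lipid_xy,
    generate_solute_tracks,
)
from bilayerlab.synthetic.spec import A_PER_NS_TO_CM_PER_S, SyntheticSpec

CH_BOND_LENGTH = 1.09  # A


def _ground_truth(spec: SyntheticSpec, pm_isd: float | None) -> dict:
    z_grid = np.linspace(-spec.box0[2] / 2, spec.box0[2] / 2, 201)
    sidecar = {
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "dt_ns": spec.dt,
        "n_lipids_per_leaflet": spec.n_lipids_per_leaflet,
        "box0": list(spec.box0),
        "apl_target": spec.apl_target,
        "apl_sd": spec.apl_sd,
        "thickness_target": spec.thickness_target,
        "thickness_sd": spec.thickness_sd,
        "lipid_D": spec.lipid_D,
        "chain_S_target": spec.chain_S_target,
        "n_solutes": spec.n_solutes,
        "solute_D_z": spec.solute_D_z,
        "temperature": spec.temperature,
        "membrane_halfwidth": spec.halfwidth,
        "lateral_mode": spec.lateral_mode,
        "pmf": {
            "form": spec.pmf.form,
            "barrier_height": spec.pmf.barrier_height,
            "well_depth": spec.pmf.well_depth,
            "well_position": spec.pmf.well_position,
            "width": spec.pmf.width,
            "z": z_grid.tolist(),
            "g_kcal_mol": spec.pmf.value(z_grid).tolist(),
        },
    }
    if pm_isd is not None:
        sidecar["pm_isd_A_per_ns"] = pm_isd
        sidecar["pm_isd_cm_per_s"] = pm_isd * A_PER_NS_TO_CM_PER_S
    return sidecar


def assemble_trajectory(spec: SyntheticSpec, out_dir: str | Path | None = None):
    """Build a Trajectory from all component generators.

    Particles per lipid: one phosphorus plus ``n_ch_pairs_per_lipid`` C-H
    pairs hanging below/above the phosphate toward the midplane.  Solutes
    contribute one ``solute_com`` particle each.  Returns
    ``(trajectory, sidecar_dict)``; when ``out_dir`` is given, also writes
    ``traj.pdb`` + ``traj.dcd`` and ``ground_truth.json`` there.

    Reproducible: the same spec (same seed) yields identical output.
    """
    f = spec.n_frames
    xy = generate_lipid_xy(spec)
    bp = generate_box_and_phosphates(spec)
    chains = generate_chain_vectors(spec)
    solutes = generate_solute_tracks(spec) if spec.n_solutes > 0 else None

    parts = {"xy": xy.unwrapped.shape[0], "box": bp.boxes.shape[0], "chains": chains.shape[0]}
    if solutes is not None:
        parts["solutes"] = solutes.z_wrapped.shape[0]
    if len(set(parts.values())) != 1:
        raise ValueError(f"component generators disagree on frame count: {parts}")

    m = 2 * spec.n_lipids_per_leaflet
    npairs = spec.n_ch_pairs_per_lipid
    per_lipid = 1 + 2 * npairs
    n_particles = m * per_lipid + spec.n_solutes

    coords = np.zeros((f, n_particles, 3))
    roles = np.empty(n_particles, dtype=object)
    mol_ids = np.empty(n_particles, dtype=int)
    ch_pairs = []

    # lipids: wrap xy into the per-frame box so readers see a periodic system
    frac = xy.unwrapped / np.array(xy.box_xy)          # fractional lateral coords
    frac = np.mod(frac, 1.0)
    lat = frac * bp.boxes[:, None, :2]                 # (F, M, 2)

    upper = np.arange(m) < bp.n_upper
    for i in range(m):
        base = i * per_lipid
        roles[base] = "phosphorus"
        mol_ids[base] = i
        coords[:, base, :2] = lat[:, i]
        coords[:, base, 2] = bp.phosphate_z[:, i]
        inward = -1.0 if upper[i] else 1.0             # chains point to midplane
        for k in range(npairs):
            c_idx, h_idx = base + 1 + 2 * k, base + 2 + 2 * k
            roles[c_idx], roles[h_idx] = "chain_carbon", "chain_hydrogen"
            mol_ids[c_idx] = mol_ids[h_idx] = i
            coords[:, c_idx, :2] = lat[:, i]
            coords[:, c_idx, 2] = bp.phosphate_z[:, i] + inward * 2.0 * (k + 1)
            vec = chains[:, (i * npairs + k) % chains.shape[1]]
            coords[:, h_idx] = coords[:, c_idx] + CH_BOND_LENGTH * vec
            ch_pairs.append((c_idx, h_idx))

    pm_isd = None
    if solutes is not None:
        s0 = m * per_lipid
        rng = spec.rng(6)
        sx = rng.uniform(0.0, spec.box0[0], size=spec.n_solutes)
        sy = rng.uniform(0.0, spec.box0[1], size=spec.n_solutes)
        for j in range(spec.n_solutes):
            idx = s0 + j
            roles[idx] = "solute_com"
            mol_ids[idx] = m + j
            coords[:, idx, 0] = sx[j]
            coords[:, idx, 1] = sy[j]
            coords[:, idx, 2] = solutes.z_wrapped[:, j]
        pm_isd = solutes.pm_isd

    times = np.arange(f) * spec.dt
    traj = Trajectory(
        times=times,
        boxes=bp.boxes,
        coords=coords,
        roles=roles,
        molecule_ids=mol_ids,
        ch_pairs=np.array(ch_pairs, dtype=int) if ch_pairs else None,
        metadata={"synthetic_seed": spec.seed},
    )
    sidecar = _ground_truth(spec, pm_isd)

    if out_dir is not None:
        from bilayerlab.core.trajectory import write_trajectory

        out_dir = Path(out_dir)
        write_trajectory(traj, out_dir, stem="traj")
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
    return traj, sidecar
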