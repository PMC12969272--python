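"""Config-driven orchestration of the analysis stages.

A run config is a single YAML file:

.. code-block:: yaml

    run_dir: runs/demo
    stages: [simulate, structure, dynamics, pmf, permeability, mixing, report]
    composition: wild_type          # packaged name or a CSV path
    analysis: { equilibration_fraction: 0.2, crossing_margin: 5.0, ... }
    synthetic: { n_lipids_per_leaflet: 50, n_solutes: 20, ... }  # for simulate
    trajectory: { topology: t.pdb, coords: t.dcd }               # alternative

Outputs land in ``run_dir``: structure.csv, diffusion.csv, pmf.csv,
pmf_folded.csv, crossings.csv, permeability.json, enrichment.csv and a
manifest.json tying every product to the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from bilayerlab.core.composition import MembraneComposition, load_composition, packaged_composition
from bilayerlab.core.config import AnalysisConfig
from bilayerlab.core.leaflets import assign_leaflets
from bilayerlab.core.trajectory import Trajectory, load_trajectory, select_window
from bilayerlab.dynamics import lateral_diffusion
from bilayerlab.mixing import enrichment_index, neighbor_census
from bilayerlab.partitioning import (
    boltzmann_invert,
    density_profile,
    fold_and_aggregate,
    split_leaflets,
)
from bilayerlab.permeability import estimate_permeability, events_to_frame
from bilayerlab.structure import structure_metrics
from bilayerlab.synthetic.generators import generate_lateral_types
from bilayerlab.synthetic.spec import PMFSpec, SyntheticSpec

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "structure", "dynamics", "pmf", "permeability", "mixing", "report")


class DependencyError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    run_dir: str
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "run_dir": self.run_dir,
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "summary": self.summary,
        }


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_synthetic_spec(section: dict) -> SyntheticSpec:
    section = dict(section)
    pmf_raw = section.pop("pmf", None)
    pmf = PMFSpec(**pmf_raw) if pmf_raw else PMFSpec()
    if "box0" in section:
        section["box0"] = tuple(section["box0"])
    known = {f.name for f in fields(SyntheticSpec)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown synthetic keys: {sorted(unknown)}")
    return SyntheticSpec(pmf=pmf, **section)


def _load_composition(value) -> MembraneComposition:
    if value in ("wild_type", "hopanoid_free"):
        return packaged_composition(value)
    return load_composition(value)


def run_pipeline(config_path: str | Path, stages: list[str] | None = None) -> RunManifest:
    """Execute the requested stages in dependency order and write all outputs."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")

    requested = list(stages or raw.get("stages", list(ALL_STAGES)))
    unknown = set(requested) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    run_dir = Path(raw.get("run_dir", "run"))
    if not run_dir.is_absolute():
        run_dir = config_path.parent / run_dir
    run_dir.mkdir(parents=True, exist_ok=True)

    cfg = AnalysisConfig(**raw.get("analysis", {}))
    comp = _load_composition(raw.get("composition", "wild_type"))
    manifest = RunManifest(
        config_hash=_config_hash(raw),
        seed=raw.get("synthetic", {}).get("seed", cfg.seed),
        run_dir=str(run_dir),
        stages=requested,
    )

    spec: SyntheticSpec | None = None
    traj: Trajectory | None = None
    sidecar = None
    if "simulate" in requested:
        if "synthetic" not in raw:
            raise DependencyError("stage 'simulate' requires a 'synthetic' section")
        spec = _build_synthetic_spec(raw["synthetic"])
        from bilayerlab.synthetic.assemble import assemble_trajectory

        traj, sidecar = assemble_trajectory(spec, out_dir=run_dir)
        manifest.outputs["trajectory"] = str(run_dir / "traj.dcd")
        manifest.outputs["ground_truth"] = str(run_dir / "ground_truth.json")
        logger.info("simulate: %d frames, %d particles", traj.n_frames, traj.n_particles)
    elif "trajectory" in raw:
        t = raw["trajectory"]
        traj = load_trajectory(t["topology"], t["coords"], t.get("role_spec"))
        if "synthetic" in raw:
            spec = _build_synthetic_spec(raw["synthetic"])

    analysis_stages = [s for s in requested if s not in ("simulate", "report")]
    needs_traj = [s for s in analysis_stages if s != "mixing"]
    if needs_traj and traj is None and "synthetic" in raw:
        # analysis requested without an explicit simulate stage or input files:
        # fall back to simulating from the synthetic section
        spec = _build_synthetic_spec(raw["synthetic"])
        from bilayerlab.synthetic.assemble import assemble_trajectory

        traj, sidecar = assemble_trajectory(spec, out_dir=run_dir)
        logger.info("implicit simulate: no trajectory section, used 'synthetic'")
    if needs_traj and traj is None:
        raise DependencyError(
            f"stages {needs_traj} need a trajectory: add a 'simulate' stage "
            "(with a 'synthetic' section) or a 'trajectory' section"
        )

    leaflets = window = None
    if needs_traj:
        window = select_window(traj, cfg)
        leaflets = assign_leaflets(window)
        logger.info(
            "window: %d/%d frames; leaflets: %d upper / %d lower (%d flips logged)",
            window.n_frames, traj.n_frames, leaflets.n_upper, leaflets.n_lower,
            len(leaflets.flips),
        )

    n_leaflet = comp.leaflet_total
    if spec is not None:
        n_leaflet = spec.n_lipids_per_leaflet

    if "structure" in requested:
        res = structure_metrics(window, leaflets, n_leaflet)
        out = run_dir / "structure.csv"
        res.to_frame().to_csv(out, index=False)
        manifest.outputs["structure"] = str(out)
        manifest.summary["structure"] = {
            "apl_A2": {"mean": res.apl.mean, "sd": res.apl.sd},
            "thickness_A": {"mean": res.thickness.mean, "sd": res.thickness.sd},
            "minus_s_ch": {"mean": res.minus_s_ch.mean, "sd": res.minus_s_ch.sd},
        }

    if "dynamics" in requested:
        res = lateral_diffusion(window, leaflets, cfg)
        out = run_dir / "diffusion.csv"
        res.to_frame().to_csv(out, index=False)
        manifest.outputs["dynamics"] = str(out)
        manifest.summary["dynamics"] = {
            "D_A2_per_ns": {"mean": res.mean_D, "sem": res.sem_D},
            "D_cm2_per_s": {"mean": res.mean_D_cm2_s, "sem": res.sem_D_cm2_s},
        }

    if "pmf" in requested:
        if len(window.indices("solute_com")) == 0:
            raise DependencyError("stage 'pmf' requires solutes in the trajectory")
        prof = density_profile(window, leaflets, cfg)
        cutoff = cfg.bulk_cutoff_z
        if cutoff is None:
            from bilayerlab.structure import membrane_thickness

            cutoff = membrane_thickness(window, leaflets).mean / 2 + 10.0
            logger.info("bulk_cutoff_z defaulted to thickness/2 + 10 = %.1f A", cutoff)
        fep = boltzmann_invert(prof, cfg, bulk_cutoff_z=cutoff)
        out = run_dir / "pmf.csv"
        df = fep.to_frame()
        df.insert(1, "probability", prof.probability)
        df.to_csv(out, index=False)
        manifest.outputs["pmf"] = str(out)
        upper, lower = split_leaflets(fep)
        folded = fold_and_aggregate([upper, lower])
        out2 = run_dir / "pmf_folded.csv"
        folded.to_frame().to_csv(out2, index=False)
        manifest.outputs["pmf_folded"] = str(out2)
        defined = fep.delta_g[~fep.undefined]
        manifest.summary["pmf"] = {
            "max_delta_g_kcal_mol": float(np.nanmax(defined)),
            "min_delta_g_kcal_mol": float(np.nanmin(defined)),
            "bulk_cutoff_z_A": float(cutoff),
        }

    if "permeability" in requested:
        if len(window.indices("solute_com")) == 0:
            raise DependencyError("stage 'permeability' requires solutes in the trajectory")
        est, events = estimate_permeability(window, leaflets, cfg)
        out = run_dir / "crossings.csv"
        events_to_frame(events).to_csv(out, index=False)
        manifest.outputs["crossings"] = str(out)
        out2 = run_dir / "permeability.json"
        with open(out2, "w") as fh:
            json.dump(est.to_dict(), fh, indent=2, sort_keys=True)
        manifest.outputs["permeability"] = str(out2)
        manifest.summary["permeability"] = est.to_dict()

    if "mixing" in requested:
        if spec is None:
            raise DependencyError(
                "stage 'mixing' requires a 'synthetic' section (lateral type layout)"
            )
        n_frames = raw.get("mixing", {}).get("n_frames", 200)
        lat = generate_lateral_types(spec, comp, n_frames=n_frames)
        census = neighbor_census(
            lat.positions, lat.labels, lat.box_xy, cfg.neighbor_cutoff_xy
        )
        em = enrichment_index(census)
        out = run_dir / "enrichment.csv"
        em.to_frame().to_csv(out, index=False)
        manifest.outputs["mixing"] = str(out)
        manifest.summary["mixing"] = {
            "mean_index": float(np.nanmean(em.index)),
            "classes": list(em.classes),
        }

    out = run_dir / "manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    manifest.outputs["manifest"] = str(out)
    return manifest
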