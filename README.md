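# bilayerlab

Analysis toolkit for lipid-bilayer MD trajectories with a synthetic
ground-truth trajectory generator, so every estimator is validated by
parameter recovery rather than by eyeballing.

Analyses:

- **structure** — area per lipid (lateral box area / leaflet size),
  phosphate-plane membrane thickness, and the pooled C–H order parameter
  `S_CH = <(3 cos^2 theta - 1)/2>` (reported as −S_CH);
- **dynamics** — lateral lipid diffusion from non-overlapping 10-ns segment
  MSD fits, `D_xy = slope/4`, sem across segments, reported in Å²/ns and
  cm²/s (1 Å²/ns = 1e-7 cm²/s);
- **partitioning** — solute depth histograms, Boltzmann inversion
  `dG = -RT ln(p/p0)` with an aqueous reference, per-leaflet folding about
  the midplane onto |z| with mean ± sd across leaflets;
- **permeability** — complete leaflet-to-leaflet crossing events via a
  three-state automaton (periodic-wrap safe) and the flux estimate
  `Pm = N / (2 A Δt C)`;
- **mixing** — grouped lipid enrichment/depletion index (HOP/sat/MU/PU)
  over lateral neighbors within a periodic 2-D cutoff (1 = random mixing).

The `synthetic` subpackage generates trajectories with analytically known
ground truth: Brownian lateral tracks (known D), fluctuating box/phosphate
planes (known APL and thickness), chain C–H orientations with an exact
target order parameter, and overdamped Langevin solute z-tracks in a known
PMF, whose sidecar includes the closed-form inhomogeneous
solubility–diffusion permeability for cross-validation.

## CLI

Runs are driven by a single YAML config (see `tests/test_pipeline.py` for a
complete example):

```yaml
run_dir: runs/demo
stages: [simulate, structure, dynamics, pmf, permeability, mixing]
composition: wild_type        # packaged table, or a CSV path
analysis:
  equilibration_fraction: 0.2
  crossing_margin: 5.0
synthetic:
  n_lipids_per_leaflet: 50
  n_solutes: 20
  pmf: {form: single_gaussian_barrier, barrier_height: 3.0, width: 3.0}
  dt: 0.1
  n_frames: 2000
  seed: 1
```

```bash
bilayerlab run config.yaml          # all stages in the config
bilayerlab structure config.yaml    # a single stage
bilayerlab -v run config.yaml       # with INFO logging of every convention
```

Outputs land in `run_dir`: `structure.csv`, `diffusion.csv`, `pmf.csv`,
`pmf_folded.csv`, `crossings.csv`, `permeability.json`, `enrichment.csv`
and a `manifest.json` tying everything to the config hash and seed.
External trajectories are read from standard formats (PDB/PSF topology +
DCD/XTC coordinates) through a `trajectory:` config section with
MDAnalysis selection strings mapping atoms to roles.

Two composition tables ship with the package
(`bilayerlab.core.packaged_composition`): `wild_type` (12 phospholipid
species + 2 hopanoid species, 100 molecules/leaflet) and `hopanoid_free`
(the 12 phospholipids at doubled counts).

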