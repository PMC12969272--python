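"""Component generators for synthetic membrane trajectories.

Each generator consumes a SyntheticSpec (and its own deterministic RNG
stream) and returns arrays whose statistics match the spec's ground truth:
Brownian lateral tracks, fluctuating box + phosphate planes, chain C-H
orientation vectors with an exact target order parameter, overdamped
Langevin solute z-tracks in a known PMF, and typed lateral point sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from bilayerlab.core.composition import MembraneComposition, assign_groups
from bilayerlab.synthetic.spec import PMFSpec, SyntheticSpec, isd_permeability

# deterministic RNG sub-stream ids per generator
_STREAMS = {"xy": 1, "box": 2, "chains": 3, "solutes": 4, "lateral": 5}


@dataclass
class LateralTracks:
    unwrapped: np.ndarray   # (F, M, 2) A
    wrapped: np.ndarray     # (F, M, 2) A, in [0, L)
    box_xy: tuple[float, float]


def generate_lipid_xy(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> LateralTracks:
    """2-D Brownian tracks for all lipids (both leaflets).

    Per-step increments are N(0, 2 * lipid_D * dt) on each axis, so the
    ensemble MSD slope is 4 * lipid_D.  Wrapped coordinates use the initial
    lateral box.
    """
    if spec.dt <= 0:
        raise ValueError("dt must be positive")
    rng = rng if rng is not None else spec.rng(_STREAMS["xy"])
    m = 2 * spec.n_lipids_per_leaflet
    lx, ly = spec.lateral_box()
    start = rng.uniform(0.0, [lx, ly], size=(m, 2))
    sigma = np.sqrt(2.0 * spec.lipid_D * spec.dt)
    steps = rng.normal(0.0, 1.0, size=(spec.n_frames - 1, m, 2)) * sigma
    unwrapped = np.concatenate(
        [start[None], start[None] + np.cumsum(steps, axis=0)], axis=0
    )
    wrapped = np.mod(unwrapped, [lx, ly])
    return LateralTracks(unwrapped=unwrapped, wrapped=wrapped, box_xy=(lx, ly))


@dataclass
class BoxAndPhosphates:
    boxes: np.ndarray       # (F, 3) A
    phosphate_z: np.ndarray  # (F, M) A; first half upper leaflet, second half lower
    n_upper: int


def generate_box_and_phosphates(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> BoxAndPhosphates:
    """Fluctuating lateral box and per-leaflet phosphate z planes.

    The per-frame lateral area is n_lipids_per_leaflet * (apl_target + eps)
    with eps ~ N(0, apl_sd); leaflet phosphate z values are drawn about
    +-thickness_target/2 with sd thickness_sd.
    """
    if spec.apl_sd < 0 or spec.thickness_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = rng if rng is not None else spec.rng(_STREAMS["box"])
    f, n = spec.n_frames, spec.n_lipids_per_leaflet
    apl = spec.apl_target + (
        rng.normal(0.0, spec.apl_sd, size=f) if spec.apl_sd else np.zeros(f)
    )
    apl = np.clip(apl, 0.05 * spec.apl_target, None)  # guard absurd fluctuations
    area = n * apl
    aspect = spec.box0[0] / spec.box0[1]
    ly = np.sqrt(area / aspect)
    lx = area / ly
    boxes = np.column_stack([lx, ly, np.full(f, spec.box0[2])])

    half = spec.thickness_target / 2.0
    noise = (
        rng.normal(0.0, spec.thickness_sd, size=(f, 2 * n))
        if spec.thickness_sd
        else np.zeros((f, 2 * n))
    )
    z = np.empty((f, 2 * n))
    z[:, :n] = half + noise[:, :n]
    z[:, n:] = -half + noise[:, n:]
    return BoxAndPhosphates(boxes=boxes, phosphate_z=z, n_upper=n)


def generate_chain_vectors(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    n_vectors: int | None = None,
) -> np.ndarray:
    """Unit C-H vectors (F, P, 3) whose second Legendre moment is exactly
    chain_S_target in expectation.

    Sampling mixes a delta-orientation component with an isotropic one:
    for S >= 0 the delta sits at theta = 0 (P2 = 1, weight S); for S < 0 it
    sits in-plane at theta = 90 deg (P2 = -1/2, weight -2S).  The isotropic
    component has P2 expectation 0, so the mixture mean is S by construction.
    """
    s = spec.chain_S_target
    if not -0.5 <= s <= 1.0:
        raise ValueError(f"order-parameter target {s} unreachable (range [-0.5, 1])")
    rng = rng if rng is not None else spec.rng(_STREAMS["chains"])
    p = n_vectors if n_vectors is not None else 2 * spec.n_lipids_per_leaflet * spec.n_ch_pairs_per_lipid
    f = spec.n_frames

    if s >= 0:
        weight, aligned_in_plane = s, False
    else:
        weight, aligned_in_plane = -2.0 * s, True

    take_aligned = rng.random(size=(f, p)) < weight
    phi = rng.uniform(0.0, 2 * np.pi, size=(f, p))
    cos_t = rng.uniform(-1.0, 1.0, size=(f, p))
    if aligned_in_plane:
        cos_t = np.where(take_aligned, 0.0, cos_t)
    else:
        cos_t = np.where(take_aligned, 1.0, cos_t)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None))
    vec = np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1
    )
    return vec


@dataclass
class SoluteTracks:
    z_wrapped: np.ndarray    # (F, S) in [-Lz/2, Lz/2)
    z_unwrapped: np.ndarray  # (F, S)
    pm_isd: float            # A/ns over [-halfwidth, halfwidth]
    halfwidth: float
    lz: float


def generate_solute_tracks(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> SoluteTracks:
    """Overdamped Langevin z-tracks in the spec PMF with periodic z.

    Euler-Maruyama: z' = z - (D/RT) G'(z) dt + sqrt(2 D dt) xi.  The
    stationary density is proportional to exp(-G/RT).  Solutes start
    uniformly in the aqueous region |z| > halfwidth.
    """
    if spec.n_solutes <= 0:
        raise ValueError("spec.n_solutes must be positive")
    rng = rng if rng is not None else spec.rng(_STREAMS["solutes"])
    pmf, d = spec.pmf, spec.solute_D_z
    lz = spec.box0[2]
    half_l = lz / 2.0
    dt = spec.dt / spec.substeps
    step_sd = np.sqrt(2.0 * d * dt)
    if step_sd > pmf.width / 5.0 and pmf.form != "flat":
        warnings.warn(
            f"Langevin step sd {step_sd:.2f} A exceeds PMF width/5 "
            f"({pmf.width / 5.0:.2f} A); reduce dt or increase substeps",
            stacklevel=2,
        )

    s = spec.n_solutes
    # start uniformly in the water region (both sides of the membrane)
    water = rng.uniform(spec.halfwidth, lz - spec.halfwidth, size=s)
    z = np.mod(water + half_l, lz) - half_l

    mobility = d / spec.rt
    z_w = np.empty((spec.n_frames, s))
    z_u = np.empty((spec.n_frames, s))
    z_w[0] = z
    unwrapped = z.copy()
    z_u[0] = unwrapped
    n_steps = (spec.n_frames - 1) * spec.substeps
    chunk = 20000
    noise_iter = None
    step = 0
    for frame in range(1, spec.n_frames):
        for _ in range(spec.substeps):
            if step % chunk == 0:
                noise_block = rng.normal(0.0, step_sd, size=(min(chunk, n_steps - step), s))
                noise_iter = iter(noise_block)
            xi = next(noise_iter)
            dz = -mobility * pmf.grad(z) * dt + xi
            z = z + dz
            unwrapped = unwrapped + dz
            # periodic wrap of the image-local coordinate
            z = np.mod(z + half_l, lz) - half_l
            step += 1
        z_w[frame] = z
        z_u[frame] = unwrapped

    pm = isd_permeability(pmf, d, spec.rt, spec.halfwidth)
    return SoluteTracks(
        z_wrapped=z_w, z_unwrapped=z_u, pm_isd=pm, halfwidth=spec.halfwidth, lz=lz
    )


@dataclass
class LateralTypes:
    positions: np.ndarray   # (F, n, 2) in [0, L)
    labels: np.ndarray      # (n,) grouped class strings
    box_xy: tuple[float, float]
    mode: str


def generate_lateral_types(
    spec: SyntheticSpec,
    comp: MembraneComposition,
    rng: np.random.Generator | None = None,
    n_frames: int | None = None,
) -> LateralTypes:
    """Typed lateral point set for one leaflet, redrawn every frame.

    random mode: class labels are a fixed permutation matching the
    composition counts and positions are uniform in the box.  segregated
    mode: each class occupies its own x-strip, strips separated by
    ``segregation_gap`` so cross-class contacts vanish for small cutoffs.
    """
    rng = rng if rng is not None else spec.rng(_STREAMS["lateral"])
    f = n_frames if n_frames is not None else spec.n_frames
    lx, ly = spec.box0[0], spec.box0[1]
    n = comp.leaflet_total
    if n == 0:
        raise ValueError("empty composition")
    if n > 10 * spec.n_lipids_per_leaflet:
        raise ValueError("composition counts exceed the leaflet size by >10x")

    labels = np.array(assign_groups(comp, rng=rng), dtype=object)
    if spec.lateral_mode == "random":
        pos = rng.uniform(0.0, [lx, ly], size=(f, n, 2))
        return LateralTypes(positions=pos, labels=labels, box_xy=(lx, ly), mode="random")

    classes = sorted(set(labels.tolist()))
    k = len(classes)
    strip_w = lx / k
    gap = spec.segregation_gap
    if gap >= strip_w:
        raise ValueError(
            f"segregation_gap {gap} A leaves no room in strips of width {strip_w:.1f} A"
        )
    pos = np.empty((f, n, 2))
    for ci, cls in enumerate(classes):
        sel = labels == cls
        lo = ci * strip_w + gap / 2.0
        hi = (ci + 1) * strip_w - gap / 2.0
        m = int(np.sum(sel))
        pos[:, sel, 0] = rng.uniform(lo, hi, size=(f, m))
        pos[:, sel, 1] = rng.uniform(0.0, ly, size=(f, m))
    return LateralTypes(positions=pos, labels=labels, box_xy=(lx, ly), mode="segregated")
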