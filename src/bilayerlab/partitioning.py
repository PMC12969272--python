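"""Solute depth distributions, Boltzmann inversion and leaflet folding.

The solute z histogram (midplane-referenced) is converted to a free-energy
profile via dG = -RT ln(p / p0), with p0 the mean probability over aqueous
reference bins.  Per-leaflet profiles are folded about the midplane onto
|z| and aggregated as a mean with a leaflet-to-leaflet standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bilayerlab.core.config import AnalysisConfig
from bilayerlab.core.leaflets import LeafletMap
from bilayerlab.core.trajectory import Trajectory, TrajectoryError

logger = logging.getLogger(__name__)


@dataclass
class DensityProfile:
    bin_edges: np.ndarray      # (B+1,), uniform, z = 0 is an edge
    counts: np.ndarray         # (B,) int
    probability: np.ndarray    # (B,), sums to 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    delta_g: np.ndarray            # kcal/mol; nan on undefined bins
    undefined: np.ndarray          # bool mask of zero-count bins
    reference: str = "mean probability over aqueous bins"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_A": self.bin_centers,
                "delta_g_kcal_mol": self.delta_g,
                "undefined": self.undefined,
            }
        )


@dataclass
class FoldedProfile:
    abs_z: np.ndarray
    mean_delta_g: np.ndarray
    sd_delta_g: np.ndarray
    n_leaflets: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "abs_z_A": self.abs_z,
                "mean_delta_g_kcal_mol": self.mean_delta_g,
                "sd_delta_g_kcal_mol": self.sd_delta_g,
            }
        )


def symmetric_bins(half_extent: float, width: float) -> np.ndarray:
    """Uniform bin edges covering [-half_extent, half_extent] with z = 0 an
    edge, so every bin center at +c has a mirror at -c."""
    k = int(np.ceil(half_extent / width))
    return np.arange(-k, k + 1) * width


def density_profile(
    traj: Trajectory, leaflets: LeafletMap, cfg: AnalysisConfig
) -> DensityProfile:
    """Normalized histogram of solute z relative to the per-frame midplane."""
    s_idx = traj.indices("solute_com")
    if len(s_idx) == 0:
        raise TrajectoryError("no solutes tagged; density profile undefined")
    lz = traj.boxes[:, 2]
    z = traj.coords[:, s_idx, 2] - leaflets.midplane_z[:, None]
    z = np.mod(z + lz[:, None] / 2, lz[:, None]) - lz[:, None] / 2
    edges = symmetric_bins(float(lz.max()) / 2, cfg.bin_width_z)
    counts, _ = np.histogram(z.ravel(), bins=edges)
    total = counts.sum()
    if total == 0:
        raise TrajectoryError("no solute samples fell inside the histogram range")
    return DensityProfile(
        bin_edges=edges, counts=counts, probability=counts / total
    )


def boltzmann_invert(
    prof: DensityProfile,
    cfg: AnalysisConfig,
    bulk_cutoff_z: float | None = None,
    single_bin_reference: bool = False,
) -> FreeEnergyProfile:
    """dG = -RT ln(p / p0) with p0 from the aqueous region.

    ``p0`` defaults to the mean probability over all occupied bins beyond
    ``bulk_cutoff_z`` (falling back to ``cfg.bulk_cutoff_z``); with
    ``single_bin_reference`` the single most-occupied bulk bin is used
    instead.  Zero-count bins are masked as undefined, never +-inf.
    """
    cutoff = bulk_cutoff_z if bulk_cutoff_z is not None else cfg.bulk_cutoff_z
    if cutoff is None:
        raise ValueError("bulk_cutoff_z not set (neither argument nor config)")
    centers = prof.bin_centers
    bulk = (np.abs(centers) > cutoff) & (prof.counts > 0)
    if not bulk.any():
        raise TrajectoryError(
            f"no occupied aqueous bins beyond |z| > {cutoff} A; no free-energy reference"
        )
    if single_bin_reference:
        ref_bin = np.flatnonzero(bulk)[np.argmax(prof.counts[bulk])]
        p0 = prof.probability[ref_bin]
        ref_desc = f"single aqueous bin at z = {centers[ref_bin]:.1f} A"
    else:
        p0 = float(prof.probability[bulk].mean())
        ref_desc = f"mean probability over {int(bulk.sum())} aqueous bins (|z| > {cutoff} A)"
    logger.info("Boltzmann inversion reference: %s (p0 = %.3g)", ref_desc, p0)

    undefined = prof.counts == 0
    dg = np.full(len(centers), np.nan)
    ok = ~undefined
    dg[ok] = -cfg.rt * np.log(prof.probability[ok] / p0)
    return FreeEnergyProfile(
        bin_centers=centers, delta_g=dg, undefined=undefined, reference=ref_desc
    )


def split_leaflets(profile: FreeEnergyProfile) -> tuple[FreeEnergyProfile, FreeEnergyProfile]:
    """Split a full-z profile into upper (z > 0) and lower (z < 0) leaflet
    profiles on the same grid, masking the opposite half."""
    out = []
    for keep_upper in (True, False):
        mask = profile.bin_centers < 0 if keep_upper else profile.bin_centers > 0
        dg = profile.delta_g.copy()
        dg[mask] = np.nan
        out.append(
            FreeEnergyProfile(
                bin_centers=profile.bin_centers,
                delta_g=dg,
                undefined=profile.undefined | mask,
                reference=profile.reference,
            )
        )
    return out[0], out[1]


def fold_and_aggregate(profiles: list[FreeEnergyProfile]) -> FoldedProfile:
    """Fold each profile about z = 0 onto |z| and aggregate across profiles.

    Folding averages the defined values at +z and -z (or keeps the single
    defined one).  The output mean and standard deviation (ddof = 1) run
    across the input profiles, bin by bin.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    centers = profiles[0].bin_centers
    for p in profiles[1:]:
        if not np.allclose(p.bin_centers, centers):
            raise ValueError("profiles have mismatched bin grids")

    pos = centers > 0
    abs_z = centers[pos]
    order = np.argsort(abs_z)
    abs_z = abs_z[order]

    folded = []
    for p in profiles:
        pos_vals = p.delta_g[pos][order]
        # mirror: for each +c find the bin at -c (keys rounded for float safety)
        neg_map = {round(-c, 6): v for c, v in zip(centers[~pos], p.delta_g[~pos])}
        neg_vals = np.array(
            [neg_map.get(round(c, 6), np.nan) for c in centers[pos][order]]
        )
        both = np.stack([pos_vals, neg_vals])
        with np.errstate(invalid="ignore"):
            folded.append(np.nanmean(both, axis=0))
    folded = np.asarray(folded)   # (L, B+)

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(folded, axis=0)
        n_def = np.sum(~np.isnan(folded), axis=0)
        sd = np.full(len(abs_z), np.nan)
        enough = n_def > 1
        if enough.any():
            sd[enough] = np.nanstd(folded[:, enough], axis=0, ddof=1)
    return FoldedProfile(
        abs_z=abs_z, mean_delta_g=mean, sd_delta_g=sd, n_leaflets=len(profiles)
    )
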