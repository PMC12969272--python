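"""Lateral lipid diffusion from segment-wise MSD regression.

The trajectory is cut into consecutive fixed-length segments; within each
segment the lateral MSD of the phosphorus atoms is computed relative to the
segment's first frame, a straight line (with intercept) is fitted, and
D_xy = slope / 4.  The reported coefficient is the mean over segments with
the sem taken across segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bilayerlab.core.config import AnalysisConfig
from bilayerlab.core.leaflets import LeafletMap
from bilayerlab.core.trajectory import Trajectory, TrajectoryError

logger = logging.getLogger(__name__)

#: unit identity: 1 A^2/ns = 1e-7 cm^2/s
A2_PER_NS_TO_CM2_PER_S = 1e-7

#: log-log MSD exponent above which a segment is flagged superdiffusive
SUPERDIFFUSIVE_ALPHA = 1.5


@dataclass
class MSDCurve:
    tau: np.ndarray        # ns, starting at 0
    msd: np.ndarray        # A^2
    n_particles: int


@dataclass
class DiffusionResult:
    per_segment_D: np.ndarray          # A^2/ns
    mean_D: float                      # A^2/ns
    sem_D: float                       # A^2/ns
    superdiffusive: np.ndarray = field(default=None)  # per-segment bool flags

    @property
    def mean_D_cm2_s(self) -> float:
        return self.mean_D * A2_PER_NS_TO_CM2_PER_S

    @property
    def sem_D_cm2_s(self) -> float:
        return self.sem_D * A2_PER_NS_TO_CM2_PER_S

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": np.arange(len(self.per_segment_D)),
                "D_A2_per_ns": self.per_segment_D,
                "D_cm2_per_s": self.per_segment_D * A2_PER_NS_TO_CM2_PER_S,
                "superdiffusive": self.superdiffusive,
            }
        )


def _unwrap_xy(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    """Unwrap lateral coordinates of the selected particles via
    minimum-image increments between consecutive frames."""
    xy = traj.coords[:, idx, :2]
    box = traj.boxes[:, None, :2]
    inc = np.diff(xy, axis=0)
    inc -= np.round(inc / box[1:]) * box[1:]
    if np.any(np.abs(inc) >= box[1:] / 2 * (1 - 1e-12)):
        raise TrajectoryError(
            "lateral displacement per frame reaches half the box; sampling "
            "rate too low to unwrap"
        )
    out = np.empty_like(xy)
    out[0] = xy[0]
    out[1:] = xy[0] + np.cumsum(inc, axis=0)
    return out


def segment_msd(
    traj: Trajectory, leaflets: LeafletMap, cfg: AnalysisConfig
) -> list[MSDCurve]:
    """Per-segment lateral MSD curves of the phosphorus atoms.

    Each non-overlapping segment spans ``cfg.segment_length`` ns; the MSD at
    lag tau is averaged over all phosphorus atoms with the origin fixed at
    the segment's first frame.  Optionally (default on) the per-leaflet
    center-of-mass drift is removed frame by frame before displacement
    accumulation.
    """
    dt = traj.frame_interval
    if dt <= 0:
        raise TrajectoryError("need at least two frames for MSD")
    n_per_seg = int(round(cfg.segment_length / dt))
    if n_per_seg < 3:
        raise TrajectoryError(
            f"segment_length {cfg.segment_length} ns spans fewer than 3 frame "
            f"intervals at dt = {dt} ns"
        )
    n_seg = traj.n_frames // (n_per_seg + 1)
    if n_seg < 1:
        raise TrajectoryError(
            f"trajectory ({traj.n_frames} frames) shorter than one segment "
            f"({n_per_seg + 1} frames)"
        )

    p_idx = traj.indices("phosphorus")
    if len(p_idx) == 0:
        raise TrajectoryError("no phosphorus particles tagged")
    unwrapped = _unwrap_xy(traj, p_idx)    # (F, P, 2)

    if cfg.msd_remove_drift:
        mols = traj.molecule_ids[p_idx]
        for leaflet in ("upper", "lower"):
            ids = set(leaflets.molecules(leaflet).tolist())
            sel = np.array([m in ids for m in mols])
            if sel.any():
                com = unwrapped[:, sel, :].mean(axis=1, keepdims=True)
                unwrapped[:, sel, :] -= com
        logger.info("removed per-leaflet center-of-mass drift before MSD")

    curves = []
    tau = np.arange(n_per_seg + 1) * dt
    for s in range(n_seg):
        a = s * (n_per_seg + 1)
        block = unwrapped[a : a + n_per_seg + 1]
        disp = block - block[0]
        msd = np.mean(np.sum(disp ** 2, axis=2), axis=1)
        curves.append(MSDCurve(tau=tau.copy(), msd=msd, n_particles=len(p_idx)))
    return curves


def estimate_dxy(curves: list[MSDCurve], cfg: AnalysisConfig | None = None) -> DiffusionResult:
    """OLS fit of each segment MSD against lag time; D = slope / 4.

    All-zero MSD gives D = 0 with zero sem.  Segments whose log-log MSD
    exponent exceeds 1.5 are flagged superdiffusive (ballistic artifacts).
    """
    if not curves:
        raise ValueError("need at least one MSD curve")
    ds, flags = [], []
    for c in curves:
        if np.allclose(c.msd, 0.0):
            ds.append(0.0)
            flags.append(False)
            continue
        slope, _ = np.polyfit(c.tau, c.msd, 1)
        ds.append(slope / 4.0)
        pos = (c.tau > 0) & (c.msd > 0)
        if pos.sum() >= 2:
            alpha, _ = np.polyfit(np.log(c.tau[pos]), np.log(c.msd[pos]), 1)
            flags.append(bool(alpha > SUPERDIFFUSIVE_ALPHA))
        else:
            flags.append(False)
    ds = np.asarray(ds)
    mean = float(ds.mean())
    sem = float(ds.std(ddof=1) / np.sqrt(len(ds))) if len(ds) > 1 else 0.0
    return DiffusionResult(
        per_segment_D=ds, mean_D=mean, sem_D=sem, superdiffusive=np.asarray(flags)
    )


def lateral_diffusion(
    traj: Trajectory, leaflets: LeafletMap, cfg: AnalysisConfig
) -> DiffusionResult:
    return estimate_dxy(segment_msd(traj, leaflets, cfg), cfg)
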