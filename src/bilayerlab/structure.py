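"""Membrane structure metrics: area per lipid, thickness, C-H order parameter."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bilayerlab.core.leaflets import LeafletMap
from bilayerlab.core.trajectory import Trajectory, TrajectoryError


@dataclass
class SeriesResult:
    """A per-frame scalar series with its window mean."""

    times: np.ndarray
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass
class StructureResult:
    apl: SeriesResult
    thickness: SeriesResult
    minus_s_ch: SeriesResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.apl.times,
                "apl_A2": self.apl.values,
                "thickness_A": self.thickness.values,
                "minus_s_ch": self.minus_s_ch.values,
            }
        )


def area_per_lipid(traj: Trajectory, n_lipids_per_leaflet: int) -> SeriesResult:
    """Per-frame lateral box area divided by the leaflet molecule count.

    The denominator is the full leaflet size (hopanoids included), matching
    the convention of dividing the periodic box area by the fixed number of
    molecules in one leaflet.
    """
    if n_lipids_per_leaflet <= 0:
        raise ValueError("n_lipids_per_leaflet must be positive")
    area = traj.boxes[:, 0] * traj.boxes[:, 1]
    return SeriesResult(times=traj.times, values=area / n_lipids_per_leaflet)


def membrane_thickness(traj: Trajectory, leaflets: LeafletMap) -> SeriesResult:
    """Per-frame |mean z of upper-leaflet phosphorus - mean z of lower|."""
    p_idx = traj.indices("phosphorus")
    mols = traj.molecule_ids[p_idx]
    up_ids = set(leaflets.molecules("upper").tolist())
    lo_ids = set(leaflets.molecules("lower").tolist())
    up_sel = p_idx[[m in up_ids for m in mols]]
    lo_sel = p_idx[[m in lo_ids for m in mols]]
    if len(up_sel) == 0 or len(lo_sel) == 0:
        raise TrajectoryError("one leaflet has no phosphorus particles")
    thick = np.abs(
        traj.coords[:, up_sel, 2].mean(axis=1) - traj.coords[:, lo_sel, 2].mean(axis=1)
    )
    return SeriesResult(times=traj.times, values=thick)


def order_parameter(traj: Trajectory) -> SeriesResult:
    """-S_CH series, with S_CH = <(3 cos^2 theta - 1) / 2> over all C-H pairs.

    theta is the angle between each C-H bond vector and the membrane normal
    (the z axis).  Zero-length bond vectors are skipped with a warning.
    """
    if traj.ch_pairs is None or len(traj.ch_pairs) == 0:
        raise TrajectoryError("no C-H pairs tagged; cannot compute order parameter")
    c, h = traj.ch_pairs[:, 0], traj.ch_pairs[:, 1]
    vec = traj.coords[:, h, :] - traj.coords[:, c, :]   # (F, P, 3)
    norm = np.linalg.norm(vec, axis=2)
    bad = norm == 0.0
    if np.any(bad):
        warnings.warn(
            f"skipping {int(bad.sum())} zero-length C-H vectors", stacklevel=2
        )
        norm = np.where(bad, np.nan, norm)
    cos2 = (vec[:, :, 2] / norm) ** 2
    s_ch = np.nanmean(0.5 * (3.0 * cos2 - 1.0), axis=1)
    return SeriesResult(times=traj.times, values=-s_ch)


def structure_metrics(
    traj: Trajectory, leaflets: LeafletMap, n_lipids_per_leaflet: int
) -> StructureResult:
    return StructureResult(
        apl=area_per_lipid(traj, n_lipids_per_leaflet),
        thickness=membrane_thickness(traj, leaflets),
        minus_s_ch=order_parameter(traj),
    )
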