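"""Crossing-event detection and the flux-based permeability coefficient.

A crossing is a complete translocation from one bulk aqueous region to the
other.  Each solute is tracked by a three-state automaton (upper bulk /
membrane interior / lower bulk); excursions that return to the same bulk
count zero.  The periodic z boundary is handled by unwrapping, so a solute
that wraps through the water slab is never mistaken for a crossing.

Pm = N / (2 * A * dt * C), the factor 2 covering the two bilayer faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bilayerlab.core.config import AnalysisConfig
from bilayerlab.core.leaflets import LeafletMap
from bilayerlab.core.trajectory import Trajectory, TrajectoryError

A2_TO_CM2 = 1e-16
NS_TO_S = 1e-9
PER_A3_TO_PER_CM3 = 1e24


@dataclass(frozen=True)
class CrossingEvent:
    solute_id: int
    entry_frame: int
    exit_frame: int
    direction: str   # up | down

    def __post_init__(self) -> None:
        if self.entry_frame >= self.exit_frame:
            raise ValueError("entry_frame must precede exit_frame")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up|down, got {self.direction!r}")


@dataclass
class PermeabilityEstimate:
    n_crossings: int
    area_cm2: float
    delta_t_s: float
    concentration_cm3: float
    pm_cm_s: float
    pm_upper_bound_cm_s: float | None = None   # reported when N = 0

    @property
    def log10_pm(self) -> float:
        return float(np.log10(self.pm_cm_s)) if self.pm_cm_s > 0 else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_crossings": self.n_crossings,
            "area_cm2": self.area_cm2,
            "delta_t_s": self.delta_t_s,
            "concentration_per_cm3": self.concentration_cm3,
            "pm_cm_s": self.pm_cm_s,
            "log10_pm": None if self.pm_cm_s <= 0 else self.log10_pm,
            "pm_upper_bound_cm_s": self.pm_upper_bound_cm_s,
        }


def _bulk_bounds(traj: Trajectory, leaflets: LeafletMap, cfg: AnalysisConfig):
    """Per-frame bulk boundaries (midplane-referenced): upper bulk beyond
    the mean upper-phosphate plane + margin, lower bulk mirrored."""
    p_idx = traj.indices("phosphorus")
    mols = traj.molecule_ids[p_idx]
    up_ids = set(leaflets.molecules("upper").tolist())
    lo_ids = set(leaflets.molecules("lower").tolist())
    up_sel = p_idx[[m in up_ids for m in mols]]
    lo_sel = p_idx[[m in lo_ids for m in mols]]
    if len(up_sel) == 0 or len(lo_sel) == 0:
        raise TrajectoryError("one leaflet has no phosphorus particles")
    mid = leaflets.midplane_z
    b_up = traj.coords[:, up_sel, 2].mean(axis=1) - mid + cfg.crossing_margin
    b_lo = traj.coords[:, lo_sel, 2].mean(axis=1) - mid - cfg.crossing_margin
    lz = traj.boxes[:, 2]
    if np.any(b_up >= lz / 2) or np.any(b_lo <= -lz / 2):
        raise ValueError(
            f"crossing margin {cfg.crossing_margin} A reaches the box edge; "
            "no bulk region remains"
        )
    return b_up, b_lo


def _solute_z_rel(traj: Trajectory, leaflets: LeafletMap):
    s_idx = traj.indices("solute_com")
    if len(s_idx) == 0:
        raise TrajectoryError("no solutes tagged")
    lz = traj.boxes[:, 2][:, None]
    z = traj.coords[:, s_idx, 2] - leaflets.midplane_z[:, None]
    z = np.mod(z + lz / 2, lz) - lz / 2
    return s_idx, z, lz[:, 0]


def detect_crossings(
    traj: Trajectory, leaflets: LeafletMap, cfg: AnalysisConfig
) -> list[CrossingEvent]:
    """Full leaflet-to-leaflet crossings per solute.

    z tracks are unwrapped with minimum-image increments; each unwrapped
    position maps to a water-slab index (the contiguous aqueous region
    between periodic membrane images), and every unit change of that index
    between consecutive bulk visits is one crossing.
    """
    b_up, b_lo = _bulk_bounds(traj, leaflets, cfg)
    _, z, lz = _solute_z_rel(traj, leaflets)

    inc = np.diff(z, axis=0)
    inc -= np.round(inc / lz[1:, None]) * lz[1:, None]
    unwrapped = np.concatenate([z[:1], z[:1] + np.cumsum(inc, axis=0)], axis=0)

    lz_ref = lz[:, None]
    image = np.floor((unwrapped + lz_ref / 2) / lz_ref)
    zloc = unwrapped - image * lz_ref

    water = np.full(z.shape, np.nan)
    water = np.where(zloc > b_up[:, None], image, water)
    water = np.where(zloc < b_lo[:, None], image - 1, water)

    events: list[CrossingEvent] = []
    for j in range(z.shape[1]):
        defined = np.flatnonzero(~np.isnan(water[:, j]))
        if len(defined) < 2:
            continue
        w = water[defined, j]
        jumps = np.flatnonzero(np.diff(w) != 0)
        for k in jumps:
            delta = int(w[k + 1] - w[k])
            direction = "up" if delta > 0 else "down"
            for _ in range(abs(delta)):
                events.append(
                    CrossingEvent(
                        solute_id=j,
                        entry_frame=int(defined[k]),
                        exit_frame=int(defined[k + 1]),
                        direction=direction,
                    )
                )
    return events


def events_to_frame(events: list[CrossingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.solute_id, e.entry_frame, e.exit_frame, e.direction) for e in events],
        columns=["solute_id", "entry_frame", "exit_frame", "direction"],
    )


def bulk_concentration(
    traj: Trajectory, leaflets: LeafletMap, cfg: AnalysisConfig
) -> float:
    """Time-averaged solute number density in the bulk aqueous region,
    in molecules per cm^3.  Volume = lateral area x total bulk slab height
    (both faces combined)."""
    b_up, b_lo = _bulk_bounds(traj, leaflets, cfg)
    _, z, lz = _solute_z_rel(traj, leaflets)
    height = lz - (b_up - b_lo)
    if np.any(height <= 0):
        raise ValueError("zero bulk volume: membrane fills the box")
    in_bulk = (z > b_up[:, None]) | (z < b_lo[:, None])
    area = traj.boxes[:, 0] * traj.boxes[:, 1]
    density_a3 = np.mean(in_bulk.sum(axis=1) / (area * height))
    return float(density_a3 * PER_A3_TO_PER_CM3)


def permeability_coefficient(
    n_crossings: int, area_cm2: float, delta_t_s: float, concentration_cm3: float
) -> PermeabilityEstimate:
    """Pm = N / (2 A dt C) in cm/s.

    With zero crossings the point estimate is 0 and a one-sided upper bound
    of 1 / (2 A dt C) (one event) is reported instead of log10 Pm.
    """
    if area_cm2 <= 0 or delta_t_s <= 0 or concentration_cm3 <= 0:
        raise ValueError("area, time and concentration must all be positive")
    if n_crossings < 0:
        raise ValueError("crossing count cannot be negative")
    denom = 2.0 * area_cm2 * delta_t_s * concentration_cm3
    if n_crossings == 0:
        return PermeabilityEstimate(
            n_crossings=0,
            area_cm2=area_cm2,
            delta_t_s=delta_t_s,
            concentration_cm3=concentration_cm3,
            pm_cm_s=0.0,
            pm_upper_bound_cm_s=1.0 / denom,
        )
    return PermeabilityEstimate(
        n_crossings=n_crossings,
        area_cm2=area_cm2,
        delta_t_s=delta_t_s,
        concentration_cm3=concentration_cm3,
        pm_cm_s=n_crossings / denom,
    )


def estimate_permeability(
    traj: Trajectory, leaflets: LeafletMap, cfg: AnalysisConfig
) -> tuple[PermeabilityEstimate, list[CrossingEvent]]:
    """End-to-end counting estimate on one trajectory."""
    events = detect_crossings(traj, leaflets, cfg)
    conc = bulk_concentration(traj, leaflets, cfg)
    area_cm2 = float(np.mean(traj.boxes[:, 0] * traj.boxes[:, 1])) * A2_TO_CM2
    delta_t_s = traj.duration() * NS_TO_S
    est = permeability_coefficient(len(events), area_cm2, delta_t_s, conc)
    return est, events
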