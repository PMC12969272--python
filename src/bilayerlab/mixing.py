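"""Grouped lipid enrichment/depletion index over lateral nearest neighbors.

For each reference class i, the index against class j is the frame-averaged
fraction of class-j molecules among the neighbors of class-i molecules
(2-D distance within a cutoff, periodic in xy, same leaflet) divided by the
bulk fraction of class j with the reference molecule excluded from its own
denominator.  1 means random mixing; >1 enrichment; <1 depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from bilayerlab.core.composition import GROUP_ORDER


@dataclass
class NeighborCensus:
    classes: tuple[str, ...]
    pair_counts: np.ndarray      # (F, K, K): neighbors of class j around refs of class i
    class_counts: np.ndarray     # (K,) molecules per class in the leaflet
    cutoff: float

    @property
    def n_frames(self) -> int:
        return self.pair_counts.shape[0]


@dataclass
class EnrichmentMatrix:
    classes: tuple[str, ...]
    index: np.ndarray            # (K, K); nan where undefined
    sem: np.ndarray              # (K, K) standard error over frames
    n_frames: int
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ci in enumerate(self.classes):
            for j, cj in enumerate(self.classes):
                rows.append((ci, cj, self.index[i, j], self.sem[i, j]))
        return pd.DataFrame(rows, columns=["ref_class", "neighbor_class", "index", "sem"])


def neighbor_census(
    positions: np.ndarray,
    labels: np.ndarray,
    box_xy: tuple[float, float],
    cutoff: float,
    classes: tuple[str, ...] | None = None,
) -> NeighborCensus:
    """Count same-leaflet neighbor pairs by class within a lateral cutoff.

    ``positions`` is (F, n, 2) (a single frame (n, 2) is promoted); distances
    are periodic in xy.  A molecule is never its own neighbor.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    labels = np.asarray(labels, dtype=object)
    n = positions.shape[1]
    if n == 0:
        raise ValueError("empty leaflet")
    if labels.shape != (n,):
        raise ValueError("labels must match the number of molecules")
    if cutoff > min(box_xy) / 2:
        raise ValueError("cutoff exceeds half the box; periodic distances ambiguous")

    if classes is None:
        present = set(labels.tolist())
        classes = tuple(c for c in GROUP_ORDER if c in present) or tuple(sorted(present))
    class_ids = {c: k for k, c in enumerate(classes)}
    lab_ids = np.array([class_ids[l] for l in labels])
    k = len(classes)

    counts = np.zeros((positions.shape[0], k, k), dtype=int)
    box = np.asarray(box_xy, dtype=float)
    for f in range(positions.shape[0]):
        pts = np.mod(positions[f], box)
        tree = cKDTree(pts, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            a, b = lab_ids[pairs[:, 0]], lab_ids[pairs[:, 1]]
            np.add.at(counts[f], (a, b), 1)
            np.add.at(counts[f], (b, a), 1)
    class_counts = np.array([np.sum(lab_ids == i) for i in range(k)])
    return NeighborCensus(
        classes=classes, pair_counts=counts, class_counts=class_counts, cutoff=cutoff
    )


def enrichment_index(census: NeighborCensus, comp=None) -> EnrichmentMatrix:
    """Frame-averaged neighbor-fraction matrix over bulk fractions.

    The bulk fraction of class j seen from a reference of class i excludes
    the reference molecule itself: f_j|i = (N_j - delta_ij) / (N - 1).  By
    construction sum_j f_j|i * index[i, j] = 1 for every well-sampled row.
    """
    counts = census.pair_counts.astype(float)     # (F, K, K)
    k = len(census.classes)
    n_tot = int(census.class_counts.sum())
    if n_tot < 2:
        raise ValueError("need at least two molecules")

    # bulk fractions with self-exclusion
    f_bulk = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            f_bulk[i, j] = (census.class_counts[j] - (i == j)) / (n_tot - 1)

    # pooled (frame-summed) fractions define the headline index
    pooled = counts.sum(axis=0)
    row_tot = pooled.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(row_tot > 0, pooled / row_tot, np.nan)
        index = np.where(f_bulk > 0, frac / f_bulk, np.nan)

    # per-frame indices give the sampling error
    ft = counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_frame = np.where(ft > 0, counts / ft, np.nan) / f_bulk[None]
    n_def = np.sum(~np.isnan(per_frame), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sem = np.where(
            n_def > 1,
            np.nanstd(per_frame, axis=0, ddof=1) / np.sqrt(np.maximum(n_def, 1)),
            np.nan,
        )
    sem = np.where(np.isnan(index), np.nan, sem)
    return EnrichmentMatrix(
        classes=census.classes,
        index=index,
        sem=sem,
        n_frames=census.n_frames,
        cutoff=census.cutoff,
    )
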