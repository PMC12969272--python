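"""Per-leaflet membrane composition tables.

A composition lists, for one leaflet, every molecular species with its
headgroup class (PE/PG/PC/CL or HOP for hopanoids), a grouped tail class
(sat / MU / PU, or ``none`` for tail-less classification such as hopanoids)
and the number of copies per leaflet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

HEADGROUP_CLASSES = ("PE", "PG", "PC", "CL", "HOP")
TAIL_CLASSES = ("sat", "MU", "PU", "none")

#: order used everywhere grouped tail classes are reported
GROUP_ORDER = ("HOP", "sat", "MU", "PU")

_REQUIRED_COLUMNS = ("name", "headgroup_class", "tail_class", "count_per_leaflet")


class CompositionError(ValueError):
    """Raised when a composition table fails validation."""


@dataclass(frozen=True)
class LipidSpecies:
    name: str
    headgroup_class: str
    tail_class: str
    count_per_leaflet: int

    def __post_init__(self) -> None:
        if self.headgroup_class not in HEADGROUP_CLASSES:
            raise CompositionError(
                f"species {self.name!r}: unknown headgroup_class "
                f"{self.headgroup_class!r} (expected one of {HEADGROUP_CLASSES})"
            )
        if self.tail_class not in TAIL_CLASSES:
            raise CompositionError(
                f"species {self.name!r}: unknown tail_class {self.tail_class!r} "
                f"(expected one of {TAIL_CLASSES})"
            )
        if self.headgroup_class == "HOP" and self.tail_class != "none":
            raise CompositionError(
                f"species {self.name!r}: hopanoids must have tail_class 'none'"
            )
        if not isinstance(self.count_per_leaflet, int) or isinstance(
            self.count_per_leaflet, bool
        ):
            raise CompositionError(
                f"species {self.name!r}: count_per_leaflet must be an integer, "
                f"got {self.count_per_leaflet!r}"
            )
        if self.count_per_leaflet < 0:
            raise CompositionError(
                f"species {self.name!r}: negative count {self.count_per_leaflet}"
            )

    @property
    def group(self) -> str:
        """Grouped mixing class: HOP for hopanoids, else the tail class."""
        return "HOP" if self.headgroup_class == "HOP" else self.tail_class


@dataclass(frozen=True)
class MembraneComposition:
    species: tuple[LipidSpecies, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.species:
            warnings.warn("empty composition: leaflet total is 0", stacklevel=3)

    @property
    def leaflet_total(self) -> int:
        return sum(s.count_per_leaflet for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def count(self, *, headgroup_class: str | None = None, group: str | None = None) -> int:
        """Total per-leaflet count of species matching the given filters."""
        total = 0
        for s in self.species:
            if headgroup_class is not None and s.headgroup_class != headgroup_class:
                continue
            if group is not None and s.group != group:
                continue
            total += s.count_per_leaflet
        return total

    def group_fractions(self) -> dict[str, float]:
        """Leaflet fraction of each grouped class, in GROUP_ORDER."""
        total = self.leaflet_total
        if total == 0:
            raise CompositionError("cannot compute fractions of an empty composition")
        return {g: self.count(group=g) / total for g in GROUP_ORDER}

    def doubled_phospholipids(self) -> "MembraneComposition":
        """Hopanoid-free variant: drop hopanoids, double every phospholipid count."""
        doubled = tuple(
            LipidSpecies(s.name, s.headgroup_class, s.tail_class, 2 * s.count_per_leaflet)
            for s in self.species
            if s.headgroup_class != "HOP"
        )
        return MembraneComposition(doubled)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.name, s.headgroup_class, s.tail_class, s.count_per_leaflet)
                for s in self.species
            ],
            columns=list(_REQUIRED_COLUMNS),
        )


def _from_frame(df: pd.DataFrame, source: str) -> MembraneComposition:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CompositionError(f"{source}: missing required column(s) {missing}")
    species = []
    for idx, row in df.iterrows():
        raw = row["count_per_leaflet"]
        try:
            count = int(raw)
        except (TypeError, ValueError):
            raise CompositionError(
                f"{source}, row {idx} ({row['name']!r}): count_per_leaflet "
                f"{raw!r} is not an integer"
            ) from None
        if count != float(raw):
            raise CompositionError(
                f"{source}, row {idx} ({row['name']!r}): count_per_leaflet "
                f"{raw!r} is not an integer"
            )
        species.append(
            LipidSpecies(
                name=str(row["name"]),
                headgroup_class=str(row["headgroup_class"]),
                tail_class=str(row["tail_class"]),
                count_per_leaflet=count,
            )
        )
    return MembraneComposition(tuple(species))


def load_composition(path: str | Path) -> MembraneComposition:
    """Read a composition CSV with columns name, headgroup_class, tail_class,
    count_per_leaflet and return a validated :class:`MembraneComposition`."""
    path = Path(path)
    df = pd.read_csv(path)
    return _from_frame(df, str(path))


def packaged_composition(which: str = "wild_type") -> MembraneComposition:
    """Load one of the packaged composition tables.

    Parameters
    ----------
    which:
        ``"wild_type"`` — 12 phospholipid species plus 2 hopanoid species,
        100 molecules per leaflet; ``"hopanoid_free"`` — the 12 phospholipid
        species at doubled counts, also 100 per leaflet.
    """
    names = {
        "wild_type": "wild_type_composition.csv",
        "hopanoid_free": "hopanoid_free_composition.csv",
    }
    if which not in names:
        raise ValueError(f"unknown packaged composition {which!r}; options: {sorted(names)}")
    ref = resources.files("bilayerlab.data").joinpath(names[which])
    with resources.as_file(ref) as p:
        return load_composition(p)


def assign_groups(comp: MembraneComposition, rng=None) -> list[str]:
    """Expand a composition into a flat per-molecule list of grouped classes.

    Order follows the species order in the table (deterministic); shuffle with
    an rng if a random arrangement is needed.
    """
    labels: list[str] = []
    for s in comp.species:
        labels.extend([s.group] * s.count_per_leaflet)
    if rng is not None:
        perm = rng.permutation(len(labels))
        labels = [labels[i] for i in perm]
    return labels


def iter_molecules(comp: MembraneComposition) -> Iterable[LipidSpecies]:
    for s in comp.species:
        for _ in range(s.count_per_leaflet):
            yield s
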