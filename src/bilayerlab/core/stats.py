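"""Replica aggregation: grand mean over replica means, sem over replicas."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ReplicaSummary:
    per_replica_means: tuple[float, ...]
    grand_mean: float
    sem: float
    sem_defined: bool = True

    @property
    def n_replicas(self) -> int:
        return len(self.per_replica_means)


def aggregate_replicas(values) -> ReplicaSummary:
    """Aggregate per-replica series (or scalars) into a grand mean and sem.

    The sem is the standard deviation of the *replica means* divided by
    sqrt(n_replicas) — never a pooled-frame sem.  With a single replica the
    mean passes through and the sem is reported as 0 with a warning and
    ``sem_defined=False``.
    """
    series = list(values)
    if len(series) == 0:
        raise ValueError("aggregate_replicas requires at least one replica")
    means = []
    for i, s in enumerate(series):
        arr = np.atleast_1d(np.asarray(s, dtype=float))
        if arr.size == 0:
            raise ValueError(f"replica {i} is empty")
        means.append(float(arr.mean()))
    n = len(means)
    grand = float(np.mean(means))
    if n == 1:
        warnings.warn(
            "single replica: sem over replicas is undefined (reported as 0)",
            stacklevel=2,
        )
        return ReplicaSummary((means[0],), grand, 0.0, sem_defined=False)
    sem = float(np.std(means, ddof=1) / np.sqrt(n))
    return ReplicaSummary(tuple(means), grand, sem)
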