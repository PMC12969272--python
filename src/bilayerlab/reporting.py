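"""Condition-vs-property summaries and the with/without delta comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd


def delta_report(result_a: dict, result_b: dict) -> pd.DataFrame:
    """Per-property difference of means, a minus b, with sems combined in
    quadrature.

    Inputs map property name -> {"mean": float, "sem": float}.  With a =
    the hopanoid-free condition and b = the hopanoid-containing one, a
    positive delta means the property is larger in the absence of hopanoids.
    """
    if set(result_a) != set(result_b):
        raise ValueError(
            f"property schemas differ: {sorted(set(result_a) ^ set(result_b))}"
        )
    rows = []
    for prop in sorted(result_a):
        a, b = result_a[prop], result_b[prop]
        for d in (a, b):
            if "mean" not in d:
                raise ValueError(f"property {prop!r} lacks a 'mean' entry")
        delta = float(a["mean"]) - float(b["mean"])
        sem = float(np.hypot(a.get("sem", 0.0), b.get("sem", 0.0)))
        rows.append((prop, float(a["mean"]), float(b["mean"]), delta, sem))
    return pd.DataFrame(
        rows, columns=["property", "mean_a", "mean_b", "delta", "delta_sem"]
    )
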