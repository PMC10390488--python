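"""Tornado sensitivity analysis.

For each patient descriptor, the population is split at the descriptor's
median into a low half (values at or below the median) and a high half
(values above it). The impact of each half is the relative change of the
output's median within that half against the whole-population median:

    impact = 100 * (median(output | category) - median(output)) / median(output)

Descriptors are ranked by ``max(|impact_low|, |impact_high|)``. The split
makes no distributional assumption about how a descriptor drives the
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TornadoEntry:
    descriptor: str
    impact_low_pct: float
    impact_high_pct: float
    rank: int


def tornado(outputs, descriptors: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Median-split sensitivity ranking of descriptors for one output.

    ``outputs`` is a per-patient vector aligned with the rows of
    ``descriptors`` (numeric columns; booleans and binary categories coded
    0/1). Returns the ``top_k`` most impactful descriptors as a frame with
    columns (descriptor, impact_low_pct, impact_high_pct, rank).

    Raises when the overall output median is zero (relative impact is then
    undefined); constant descriptors get zero impacts with a notice.
    """
    y = np.asarray(outputs, dtype=float)
    if y.size != len(descriptors):
        raise ValueError("outputs and descriptors must be aligned")
    overall = float(np.median(y))
    if overall == 0.0:
        raise ValueError("overall output median is zero; relative impact undefined")
    rows = []
    for name in descriptors.columns:
        x = np.asarray(descriptors[name], dtype=float)
        med = float(np.median(x))
        low = x <= med   # ties at the median go to the low category
        high = ~low
        if not high.any():
            warnings.warn(f"descriptor {name!r} is constant below its median; impacts 0")
            rows.append((name, 0.0, 0.0))
            continue
        imp_low = 100.0 * (float(np.median(y[low])) - overall) / overall
        imp_high = 100.0 * (float(np.median(y[high])) - overall) / overall
        rows.append((name, imp_low, imp_high))
    df = pd.DataFrame(rows, columns=["descriptor", "impact_low_pct", "impact_high_pct"])
    strength = np.maximum(df.impact_low_pct.abs(), df.impact_high_pct.abs())
    df = df.loc[strength.sort_values(ascending=False, kind="mergesort").index]
    df = df.head(top_k).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
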