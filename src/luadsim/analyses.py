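"""Composite analyses built from the core modules.

Currently: assembling the inputs of a tornado sensitivity run (simulate a
general-population cohort, collect one clinical output per patient and a
numeric descriptor matrix).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import model_settings, vpop_spec
from .pipeline import simulate_cohort
from .vpop import patients_from_frame, sample_descriptors

#: numeric coding for binary/categorical descriptors in the tornado matrix
_CODINGS = {
    "sex": {"female": 0.0, "male": 1.0},
    "egfr_variant": {"exon19del": 0.0, "l858r": 1.0},
    "smoking": {"never": 0.0, "former": 1.0, "current": 2.0},
    "ethnicity": {"non_asian": 0.0, "asian": 1.0},
    "stage": {"IIIb": 0.0, "IV": 1.0},
    "kras": {"none": 0.0, "carrier": 1.0},
    "pik3ca": {"none": 0.0, "carrier": 1.0},
}


def numeric_descriptors(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptor table with categorical columns coded numerically."""
    out = {}
    for col in df.columns:
        if col in _CODINGS:
            out[col] = df[col].map(_CODINGS[col]).astype(float)
        else:
            out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


def tornado_inputs(cfg: dict | None, n: int, seed, output_kind: str = "ttp",
                   which: str = "general"):
    """Simulate a sensitivity cohort; return (outputs, numeric descriptors).

    ``output_kind`` is ``"ttp"`` (months) or ``"radius_change"`` (percent
    radius change at 6 months vs baseline). The cohort is drawn from the
    general-population spec (50/50 EGFR variants by default).
    """
    desc = sample_descriptors(vpop_spec(cfg, which), n, seed)
    patients = patients_from_frame(desc)
    outcomes = simulate_cohort(patients, model_settings(cfg))
    if output_kind == "ttp":
        outputs = outcomes["ttp_months"].to_numpy(float)
    elif output_kind == "radius_change":
        outputs = outcomes["change_6mo_pct"].to_numpy(float)
    else:
        raise ValueError(f"unknown output kind {output_kind!r}")
    return outputs, numeric_descriptors(desc)
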