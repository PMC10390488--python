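"""Tornado sensitivity analysis of patient descriptors on TTP.

Simulates a 5000-patient general population (50/50 EGFR variants), splits
the cohort at each descriptor's median, and ranks descriptors by the
relative shift of the median time to progression in the low/high halves.
Impacts are percentages of the overall median TTP; large magnitudes mark
the descriptors that drive progression timing.
"""

import warnings

import numpy as np

import luadsim as L
from luadsim.analyses import tornado_inputs

warnings.filterwarnings("ignore", message=".*constant below its median.*")

outputs, descriptors = tornado_inputs(None, n=5000, seed=0, output_kind="ttp")
print(f"median TTP over {len(outputs)} patients: {np.median(outputs):.2f} months\n")
ranking = L.tornado(outputs, descriptors, top_k=10)
print(ranking.to_string(index=False, float_format=lambda x: f"{x:+.1f}"))
print()
print("Impact = 100 x (median TTP in half - overall median) / overall median.")
print("Resistant-subclone size, tumor pace, immune pressure, neo-angiogenesis")
print("and initial size dominate; demographics have no mechanistic effect.")
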