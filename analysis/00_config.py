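"""Shared settings for the analysis scripts.

One simulated randomized cohort is analysed end to end: two arms (drug vs
placebo, 25 subjects each), 105 cortical parcels (15 per network — the desk
scale at which the generative segregation contrast is identifiable; see
docs/methods.md), the drug arm carrying both a larger network-level load
response (+0.4 signal units) and load-segregated whole-brain dynamics
(per-parcel pattern scale 1.0).
"""

from pathlib import Path

SEED = 7
N_PER_GROUP = 25
N_PARCELS = 105
GROUP_DELTA = 0.4
STATE_SEPARATION = 1.0

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
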