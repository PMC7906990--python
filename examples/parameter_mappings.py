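"""Evaluate the five correction-to-stimulus mappings on a correction grid.

The correction variable c is (desired band representative) - (normalized
EDA): negative c means the user is calmer than desired and every parameter
strengthens.  The rows at c = 0 and c = -0.1 are the published on-target
anchor values.
"""

import numpy as np

from vretsim import HIGH, LOW, map_parameters

print(f"{'c':>6} {'state':>5} {'SGF':>7} {'SJF [N]':>8} {'SPU':>7} {'SS':>7} {'SV':>9}")
for state in (LOW, HIGH):
    for c in np.round(np.arange(-0.6, 0.31, 0.1), 10):
        p = map_parameters(state, float(c))
        print(
            f"{c:6.1f} {state.label:>5} {p.sgf:7.1f} {p.sjf:8.4f} "
            f"{p.spu:7.4f} {p.ss:7.4f} {p.sv:9.5f}"
        )
    print()

print(
    "At c = 0 the LOW bundle is (120, 0.035, 0.3265, 1.20, 0.00471): the\n"
    "weakest on-target stimulus.  More negative corrections (calmer user)\n"
    "raise every parameter - more, bigger, faster, bolder spiders."
)
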