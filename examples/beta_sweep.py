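"""Grid-search the soft-constraint strength beta against a reference.

On a toy RNA where two energetically identical helices compete, unweighted
folding cannot decide between them, while probing data built from one of the
two recovers it for every beta > 0.  Also prints the expected-distance curve
ED(beta), which is guaranteed to be strictly decreasing.
"""

import numpy as np

from shapefold import (
    SecondaryStructure,
    beta_grid_search,
    build_weights,
    expected_distance,
    inside,
    load_params,
    pair_probabilities,
)

params = load_params("turner-min")
seq = "GGGGAAAACCCCAAAAGGGG"
left = SecondaryStructure(
    n=20, pairs=((0, 11), (1, 10), (2, 9), (3, 8)), theta=3, sequence=seq
)
q = left.x  # perfect data for the left-helix structure

best, profile = beta_grid_search(seq, q, left, params,
                                 grid=np.round(np.arange(0, 2.01, 0.25), 10))
print("beta  sens   ppv    objective")
for row in profile:
    print(f"{row['beta']:4.2f}  {row['sensitivity'] or 0:.3f}  "
          f"{row['ppv'] or 0:.3f}  {row['objective']:.3f}")
print(f"best beta = {best}")

print("\nED(beta) curve (strictly decreasing):")
for beta in [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]:
    t = inside(seq, build_weights(q, beta, params.RT), params)
    ed = expected_distance(pair_probabilities(t, seq, params), q)
    print(f"  beta={beta:4.2f}  ED={ed:.4f}")
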