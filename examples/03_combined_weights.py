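"""Subjective, objective and game-combined indicator weights.

AHP turns the bundled expert judgement matrices into subjective weights
(with a consistency check); improved CRITIC extracts objective weights
from the simulated panel; the game-theoretic combination fuses both.
"""

import numpy as np

from fleetdea import (FleetConfig, build_panel, generate_dataset,
                      reference_judgement_matrices)
from fleetdea.pipeline import compute_combined_weights

events, costs = generate_dataset(FleetConfig(n_months=12, seed=42))
panel = build_panel(events, costs)
jm_in, jm_out = reference_judgement_matrices()

weights = compute_combined_weights(panel, jm_in, jm_out)
for group in ("input", "output"):
    res = weights[group]
    print(f"\n{group} indicators {res['labels']}")
    print(f"  AHP     {np.round(res['ahp'].weights, 4)}  "
          f"(CR={res['consistency'].cr:.4f}, acceptable "
          f"{'yes' if res['consistency'].acceptable else 'no'})")
    print(f"  CRITIC  {np.round(res['critic'].weights, 4)}")
    print(f"  game    {np.round(res['game'].weights, 4)}  "
          f"(lambda={np.round(res['lambda'], 4)})")
print("\nA CR below 0.10 means the expert matrix is consistent enough to "
      "use; the game weights are the convex fusion fed to the DEA cone.")
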