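"""Simulate a collared herd and undo per-collar detection bias.

Generates one synthetic single-sex herd across the 3-density x 2-replicate
design, degrades one treatment's true encounter matrix with a half-efficient
collar, and shows the iterative correction recovering both the collar's
scale factor and the true matrix.
"""

import numpy as np

from proxnet import (SimulationParams, correct_collar_bias,
                     inject_collar_asymmetry, simulate_experiment,
                     triangle_correlation)

params = SimulationParams(n_individuals=12, seed=42)
logs, truth = simulate_experiment(params)
print(f"simulated {len(logs)} treatment x replicate networks, "
      f"{len(next(iter(logs.values())))} dyad-day records each")

key = (1.05, 1)  # intermediate density, first replicate
true_m = truth.true_counts[key]

efficiencies = np.ones(12)
efficiencies[4] = 0.5  # collar C05 logs only half of its true encounters
raw = inject_collar_asymmetry(true_m, efficiencies, seed=7)
print(f"\ntriangle correlation of raw (biased) matrix:  "
      f"{triangle_correlation(raw):.4f}")

corrected, factors = correct_collar_bias(raw)
print(f"triangle correlation after correction:        "
      f"{triangle_correlation(corrected):.4f}")
print(f"recovered scale factor for collar C05:        {factors[4]:.3f} "
      "(a half-efficient collar should earn ~2.0)")
rel_err = (np.linalg.norm(corrected.weights - true_m.weights)
           / np.linalg.norm(true_m.weights))
print(f"relative error of corrected matrix vs truth:  {100 * rel_err:.2f}%")
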