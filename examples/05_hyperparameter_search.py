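"""Gaussian-process hyperparameter optimization on an analytic objective.

Uses the GP expected-improvement loop on a cheap 2-D surrogate objective to
show the search machinery (the same `optimize` drives network tuning via
`mmgp tune`), then decodes a point of the full network search space into
architecture and training configurations.
"""

import math

import numpy as np

from mmgp import hyperopt as ho

space = ho.SearchSpace([ho.Dimension("x", 0.0, 1.0), ho.Dimension("y", 0.0, 1.0)])
objective = lambda r: (r[0] - 0.62) ** 2 + (r[1] - 0.21) ** 2  # noqa: E731

best, history = ho.optimize(objective, space, n_iter=50, seed=0, strategy="gp")
print(f"budget: {len(history)} evaluations (10 quasi-random + 40 GP-EI proposals)")
print(f"incumbent: x = {best.raw.round(4)}, score = {best.score:.2e}")
print(f"true minimizer: (0.62, 0.21)")

scores = [t.score for t in history]
print(f"incumbent trace (running minimum): {np.minimum.accumulate(scores)[-5:].round(6)}")

full = ho.default_search_space()
raw = np.array([2, 1, 1, 2, 60, 796, 285, 32,
                0.0003, 0.19, math.log(0.31), 120, math.log(0.006)])
arch, cfg = ho.decode(raw, full)
print("\ndecoded network configuration from a raw search-space point:")
print(f"  modality depths {arch.modality_depths}, widths {arch.modality_first_widths}")
print(f"  fusion depth {arch.fusion_depth}, width {arch.fusion_first_width}")
print(f"  lr0 = {cfg.lr0:.4g}, weight decay = {cfg.weight_decay_rate:.3g}, "
      f"patience = {cfg.patience}")
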