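"""Bounded black-box search with the hawk/shepherd metaheuristic.

Minimizes a 2-D multimodal function and prints the convergence trace;
the escape-energy schedule moves the population from exploration to
the four besiege strategies as iterations pass.
"""

import numpy as np

from mihawk import OptimizerConfig, optimize
from mihawk.optimizer import levy_sigma

def himmelblau(x):
    return float((x[0] ** 2 + x[1] - 11) ** 2 + (x[0] + x[1] ** 2 - 7) ** 2)

cfg = OptimizerConfig(n_hawks=30, n_iter=150, lb=-5.0, ub=5.0, dim=2, seed=0)
res = optimize(himmelblau, cfg)
print(f"best position {np.round(res.best_position, 4)}, "
      f"best value {res.best_fitness:.2e}")
print("convergence (best value every 25 iterations):")
for h in res.history[::25]:
    print(f"  iter {h['iteration']:3d}: best {h['best_fitness']:.3e} "
          f"mean {h['mean_fitness']:.3e}")
# Himmelblau has four global minima with value 0; any of them is correct
print(f"\nMantegna Levy scale sigma(gamma=1.5) = {levy_sigma(1.5):.4f}")
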