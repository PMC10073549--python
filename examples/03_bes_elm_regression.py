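"""ELM vs BES-ELM: optimizing the random hidden layer by validation RMSE.

An extreme learning machine draws its hidden weights at random, which makes
its accuracy a lottery. The Bald Eagle Search metaheuristic searches the
hidden-weight space directly, scoring each candidate by the validation-set
RMSE of the resulting ELM.
"""

import numpy as np

from ricenni.models import BesConfig, bes_elm_train, bes_optimize, elm_predict, elm_train

rng = np.random.default_rng(7)
X = rng.uniform(size=(120, 5))
y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2 - X[:, 2] + rng.normal(0, 0.05, 120)
Xtr, ytr, Xv, yv = X[:80], y[:80], X[80:], y[80:]

plain = elm_train(Xtr, ytr, n_hidden=15, seed=0)
plain_rmse = float(np.sqrt(np.mean((yv - elm_predict(plain, Xv)) ** 2)))

cfg = BesConfig(population=20, iterations=30, seed=0)
model, bes_rmse, trace = bes_elm_train(Xtr, ytr, Xv, yv, n_hidden=15, cfg=cfg)
print(f"plain ELM validation RMSE : {plain_rmse:.4f}")
print(f"BES-ELM validation RMSE   : {bes_rmse:.4f} "
      f"({100 * (1 - bes_rmse / plain_rmse):.0f}% lower)")
print(f"BES best-fitness trace    : {trace[0]:.4f} -> {trace[-1]:.4f} "
      f"over {len(trace) - 1} iterations (never increases)")

# The optimizer itself, on a classical benchmark:
best, fit, _ = bes_optimize(lambda p: float(np.sum(p**2)), dim=5,
                            cfg=BesConfig(population=30, iterations=100,
                                          lower=-5, upper=5, seed=1))
print(f"\n5-D sphere minimum found by BES: {fit:.2e} (true optimum 0 at origin)")
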