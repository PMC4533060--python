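"""Parameter-recovery simulations for the behavioral models.

Simulate replicate datasets on the default design from a known chooser,
refit by maximum likelihood, and summarize the recovered parameter — the
standard check that an estimator is unbiased at the study's trial count.
"""

from __future__ import annotations

import numpy as np

from . import behavior as bh
from . import task_design as td

__all__ = ["recover_gamble_bias", "recover_loss_aversion"]


def recover_gamble_bias(
    true_g: float, seed: int, n_replicates: int = 500
) -> float:
    """Mean model-1 ML bias estimate over replicate simulated datasets."""
    design = td.generate_design(seed=seed)
    params = bh.DecisionParams(g=true_g)
    estimates = []
    for r in range(n_replicates):
        trials = bh.simulate_choices(design, 1, params, seed=seed + 1 + r)
        estimates.append(bh.fit_model(trials, 1).params.g)
    return float(np.mean(estimates))


def recover_loss_aversion(
    true_lam: float,
    seed: int,
    n_replicates: int = 500,
    mu: float = 0.1,
    g: float = 0.5,
) -> float:
    """Median model-3 ML loss-aversion estimate over replicate datasets."""
    design = td.generate_design(seed=seed)
    params = bh.DecisionParams(g=g, mu=mu, lam=true_lam)
    estimates = []
    for r in range(n_replicates):
        trials = bh.simulate_choices(design, 3, params, seed=seed + 1 + r)
        estimates.append(bh.fit_model(trials, 3).params.lam)
    return float(np.median(estimates))
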