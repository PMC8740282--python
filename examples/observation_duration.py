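"""How the observation duration shapes what the validation metrics can see.

Simulates the bundled E-I network, then (a) compares its CV and CC
distributions against uniformly time-randomized surrogate data — the null
hypothesis that only the firing rates matter — and (b) tracks how the
distributions drift as the observation window grows.  FR converges fast;
CC needs long observations before it carries information beyond the rates.
"""

import warnings

import numpy as np

from synquant import NeuronParams, SimulationConfig
from synquant.datasets import make_toy_ei_network
from synquant.pipeline import (
    convergence_diagnostics,
    simulate_network,
    surrogate_specificity_check,
)

warnings.filterwarnings("ignore")

spec = make_toy_ei_network(seed=0)
sim = SimulationConfig(duration=41_000.0, transient=1000.0, seed=0)
_, _, trains = simulate_network(spec, NeuronParams(), sim)

print("model vs. rate-preserving surrogate (KS):")
df = surrogate_specificity_check(trains, np.random.default_rng(0))
print(df.groupby("statistic")["ks_model_vs_surrogate"].mean().round(3).to_string())
print("-> FR is 0 by construction; CV/CC > 0 means they reflect structure\n")

print("distribution drift vs. observation duration (KS against full window):")
conv = convergence_diagnostics(trains, durations=[10_000.0, 20_000.0, 40_000.0])
trunc = conv[conv.window == "truncated"]
print(
    trunc.pivot_table(
        index="duration_ms", columns="statistic", values="ks", aggfunc="mean"
    ).round(3).to_string()
)
print("-> FR stabilizes quickly; CC keeps tightening with more data")
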