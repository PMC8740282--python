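"""Synthetic spike trains and toy networks with known ground truth.

These generators make every layer of the package testable without running
the full cortical microcircuit: spike trains with analytically known FR, CV
and CC, and a small two-population E-I network in the same specification
format as the microcircuit, parameterized to fire in an asynchronous
irregular regime at desk scale.
"""

from __future__ import annotations

import numpy as np

from .network import ConnectionSpec, NetworkSpec, PopulationSpec
from .stats import SpikeTrainSet
from .weights import NormalWeightSpec

__all__ = [
    "make_periodic_train",
    "make_poisson_trains",
    "make_correlated_pair",
    "make_toy_ei_network",
]


def make_periodic_train(rate: float, duration: float, t_start: float = 0.0):
    """Equally spaced spikes: FR = rate, CV = 0.

    ``rate`` in 1/s, ``duration``/``t_start`` in ms.  The first spike sits
    half a period into the window so edge truncation cannot drop it.
    """
    period = 1000.0 / rate
    if rate * duration / 1000.0 < 3:
        raise ValueError("need at least three spikes (rate * duration >= 3)")
    times = np.arange(t_start + period / 2, t_start + duration, period)
    return times


def make_poisson_trains(
    rate: float,
    duration: float,
    n: int,
    rng: np.random.Generator,
    t_start: float = 0.0,
    population: str = "P",
) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains: CV -> 1, pairwise CC -> 0."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    lam = rate * duration / 1000.0
    trains = []
    for _ in range(n):
        count = rng.poisson(lam)
        trains.append(np.sort(rng.uniform(t_start, t_start + duration, count)))
    return SpikeTrainSet(
        trains=trains,
        t_start=t_start,
        t_stop=t_start + duration,
        population=np.full(n, population, dtype=object),
    )


def make_correlated_pair(
    rate: float,
    target_cc: float,
    duration: float,
    bin_size: float,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> SpikeTrainSet:
    """Two trains with a prescribed zero-lag count correlation.

    Single-interaction-process construction: a common Poisson "mother"
    train of rate ``target_cc * rate`` is injected into both children, each
    topped up by an independent Poisson train of rate
    ``(1 - target_cc) * rate``.  Counts in disjoint bins are then sums of
    independent Poisson variables with covariance c*rate*dt and variance
    rate*dt, so the expected zero-lag count correlation is ``target_cc``
    for any bin size.
    """
    if not 0 <= target_cc <= 1:
        raise ValueError("target_cc must lie in [0, 1]")
    if rate <= 0:
        raise ValueError("rate must be positive")
    lam_common = target_cc * rate * duration / 1000.0
    lam_own = (1 - target_cc) * rate * duration / 1000.0
    common = rng.uniform(t_start, t_start + duration, rng.poisson(lam_common))
    trains = []
    for _ in range(2):
        own = rng.uniform(t_start, t_start + duration, rng.poisson(lam_own))
        trains.append(np.sort(np.concatenate([common, own])))
    return SpikeTrainSet(
        trains=trains,
        t_start=t_start,
        t_stop=t_start + duration,
        population=np.array(["pair", "pair"], dtype=object),
    )


def make_toy_ei_network(
    n_e: int = 400,
    n_i: int = 100,
    k_e: int = 160,
    k_i: int = 40,
    k_ext: int = 900,
    g: float = -5.0,
    weight_cv: float = 0.1,
    rule: str = "fixed_in_degree",
    seed: int = 0,
    reference_weight: float = 87.81,
) -> NetworkSpec:
    """Two-population E-I network in the microcircuit's specification format.

    The defaults place the network in an asynchronous irregular regime at
    desk scale: suprathreshold Poisson drive balanced by inhibition-dominated
    recurrence (g = -5 with k_i/k_e = 1/4), LIF parameters and the 10%
    weight CV (j = 0.01) of the cortical microcircuit.  In-degrees are
    given per target for the fixed in-degree rule and converted to totals
    for the fixed total number rule.
    """
    exc = NormalWeightSpec(reference_weight, weight_cv * reference_weight)
    inh = NormalWeightSpec(
        g * reference_weight, weight_cv * abs(g) * reference_weight
    )
    pops = [
        PopulationSpec("E", n_e, k_ext, v0_mean=-58.0, v0_std=5.0),
        PopulationSpec("I", n_i, k_ext, v0_mean=-58.0, v0_std=5.0),
    ]
    conns = []
    for target, n_t in (("E", n_e), ("I", n_i)):
        conns.append(
            ConnectionSpec(
                source="E", target=target, weight_spec=exc,
                delay_mean=1.5, delay_std=0.75,
                in_degree=k_e, total_synapses=k_e * n_t,
            )
        )
        conns.append(
            ConnectionSpec(
                source="I", target=target, weight_spec=inh,
                delay_mean=0.75, delay_std=0.375,
                in_degree=k_i, total_synapses=k_i * n_t,
            )
        )
    return NetworkSpec(populations=pops, connections=conns, rule=rule, seed=seed)
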