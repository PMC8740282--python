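"""Parameters of the Potjans-Diesmann cortical microcircuit model.

The model describes the local circuit under 1 mm^2 of early sensory cortex:
eight populations (an excitatory and an inhibitory one in each of layers
L2/3, L4, L5, L6), current-based LIF neurons with exponential postsynaptic
currents, population-specific random connectivity, normally distributed
weights and delays, and independent Poisson external drive.

This module stores the printed parameter set (population sizes, per-pair
synapse counts and in-degrees, weight/delay distributions, neuron and
simulation parameters) and assembles :class:`~synquant.network.NetworkSpec`
objects from it.  Note that constructing the full-scale network means
~3x10^8 synapses; desk-scale work should use ``scale_network`` or the toy
networks in :mod:`synquant.datasets`.
"""

from __future__ import annotations

import pandas as pd

from .network import ConnectionSpec, NetworkSpec, PopulationSpec
from .simulator import NeuronParams
from .weights import NormalWeightSpec

__all__ = [
    "POPULATIONS",
    "POPULATION_SIZES",
    "EXTERNAL_IN_DEGREES",
    "in_degree_table",
    "synapse_count_table",
    "total_recurrent_synapses",
    "weight_memory_gb",
    "weight_spec",
    "neuron_params",
    "microcircuit_spec",
    "REFERENCE_WEIGHT_PA",
    "WEIGHT_CV",
]

POPULATIONS = ["L2/3E", "L2/3I", "L4E", "L4I", "L5E", "L5I", "L6E", "L6I"]

POPULATION_SIZES = dict(
    zip(POPULATIONS, [20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948])
)

EXTERNAL_IN_DEGREES = dict(
    zip(POPULATIONS, [1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100])
)

# initial membrane potential distribution, mean / std in mV, per population
INITIAL_V_MEAN = dict(
    zip(POPULATIONS, [-68.28, -63.16, -63.33, -63.45, -63.11, -61.66, -66.72, -61.43])
)
INITIAL_V_STD = dict(
    zip(POPULATIONS, [5.36, 4.57, 4.74, 4.94, 4.94, 4.55, 5.46, 4.48])
)

# in-degrees K_YX of the fixed in-degree model variant; rows = target Y,
# columns = source X, ordered as POPULATIONS
_K_YX = [
    [2200, 1080, 980, 468, 160, 0, 110, 0],
    [2991, 861, 704, 290, 381, 0, 61, 0],
    [160, 35, 1118, 795, 33, 1, 668, 0],
    [1481, 17, 1814, 954, 17, 0, 1609, 0],
    [2189, 375, 1136, 32, 421, 497, 297, 0],
    [1166, 160, 571, 13, 301, 405, 125, 0],
    [326, 39, 468, 92, 286, 22, 582, 753],
    [767, 6, 75, 3, 137, 9, 980, 460],
]

# total synapse numbers S_YX of the fixed total number model variant
_S_YX = [
    [45499804, 22323576, 20253647, 9670918, 3293577, 0, 2271403, 0],
    [17443694, 5018762, 4105338, 1690073, 2221212, 0, 353460, 0],
    [3503669, 756561, 24482849, 17413575, 714524, 7002, 14624431, 0],
    [8114253, 92831, 9933537, 5223271, 87836, 0, 8810905, 0],
    [10613575, 1817058, 5507804, 151900, 2040738, 2407889, 1438969, 0],
    [1241436, 169424, 607666, 12851, 319601, 430443, 132414, 0],
    [4681225, 556108, 6727569, 1320233, 4112224, 305028, 8372649, 10827677],
    [2260836, 17207, 220032, 8078, 401637, 25217, 2888426, 1354319],
]

#: reference synaptic strength w̄∞; all recurrent weights in units of it
REFERENCE_WEIGHT_PA = 87.81

#: relative spread of every weight distribution (std = 0.1 × |mean|)
WEIGHT_CV = 0.1

MEAN_DELAY_MS = {"E": 1.5, "I": 0.75}  # delay std is 0.5 × mean

EXTERNAL_RATE_HZ = 8.0
SIMULATION_RESOLUTION_MS = 0.1
TRANSIENT_MS = 1000.0


def in_degree_table() -> pd.DataFrame:
    """K_YX, indexed by target population, columns = source population."""
    return pd.DataFrame(_K_YX, index=POPULATIONS, columns=POPULATIONS)


def synapse_count_table() -> pd.DataFrame:
    """S_YX, indexed by target population, columns = source population."""
    return pd.DataFrame(_S_YX, index=POPULATIONS, columns=POPULATIONS)


def total_recurrent_synapses() -> int:
    """Total recurrent synapse count of the fixed-total-number model."""
    return int(synapse_count_table().to_numpy().sum())


def weight_memory_gb(bits_per_weight: int = 64) -> float:
    """Memory (GB, 10^9 bytes) to store one weight value per synapse."""
    return total_recurrent_synapses() * bits_per_weight / 8 / 1e9


def _relative_strength(source: str, target: str) -> float:
    if source.endswith("I"):
        return -4.0
    if (source, target) == ("L4E", "L2/3E"):
        return 2.0
    return 1.0


def weight_spec(source: str, target: str) -> NormalWeightSpec:
    """Reference weight distribution for the projection source -> target.

    Excitatory sources use (w̄∞, 0.1 w̄∞); inhibitory sources scale by
    g = −4; the L4E -> L2/3E projection doubles mean and std.
    """
    g = _relative_strength(source, target)
    mean = g * REFERENCE_WEIGHT_PA
    return NormalWeightSpec(mean=mean, std=WEIGHT_CV * abs(mean))


def neuron_params() -> NeuronParams:
    """LIF parameters shared by all eight populations."""
    return NeuronParams(
        membrane_capacitance=250.0,
        membrane_time_constant=10.0,
        leak_reversal=-65.0,
        threshold=-50.0,
        reset=-65.0,
        refractory_period=2.0,
        synaptic_time_constant=0.5,
    )


def microcircuit_spec(
    rule: str = "fixed_in_degree", scale: float = 1.0, seed: int = 0
) -> NetworkSpec:
    """Assemble the full eight-population network specification.

    Parameters
    ----------
    rule
        ``"fixed_in_degree"`` (every target neuron receives exactly K_YX
        inputs) or ``"fixed_total_number"`` (exactly S_YX synapses per pair,
        binomial in-degrees).
    scale
        Optional downscaling factor applied to population sizes and synapse
        counts; see :func:`synquant.network.scale_network` for the caveats
        (scaled networks do not reproduce full-scale statistics).
    """
    populations = [
        PopulationSpec(
            name=p,
            size=POPULATION_SIZES[p],
            external_in_degree=EXTERNAL_IN_DEGREES[p],
            v0_mean=INITIAL_V_MEAN[p],
            v0_std=INITIAL_V_STD[p],
        )
        for p in POPULATIONS
    ]
    kt = in_degree_table()
    st = synapse_count_table()
    connections = []
    for target in POPULATIONS:
        for source in POPULATIONS:
            k = int(kt.loc[target, source])
            s = int(st.loc[target, source])
            if k == 0 and s == 0:
                continue
            d_mean = MEAN_DELAY_MS["I" if source.endswith("I") else "E"]
            connections.append(
                ConnectionSpec(
                    source=source,
                    target=target,
                    in_degree=k,
                    total_synapses=s,
                    weight_spec=weight_spec(source, target),
                    delay_mean=d_mean,
                    delay_std=0.5 * d_mean,
                )
            )
    spec = NetworkSpec(
        populations=populations, connections=connections, rule=rule, seed=seed
    )
    if scale != 1.0:
        from .network import scale_network

        spec = scale_network(spec, scale)
    return spec
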