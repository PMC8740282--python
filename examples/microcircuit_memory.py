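"""Connectivity arithmetic and the memory case for low-resolution weights.

Reproduces the printed connectivity bookkeeping of the eight-population
cortical microcircuit — per-pair in-degrees from the total synapse counts —
and the memory that one 64-bit weight per synapse costs.  If a 1-bin
(mean-only) discretization preserves the dynamics, those weights collapse
to three stored values (one per weight distribution), saving the full
per-synapse weight storage.
"""

from synquant import in_degree
from synquant import microcircuit as mc

kt, st = mc.in_degree_table(), mc.synapse_count_table()
matches = sum(
    in_degree(int(st.loc[t, s]), mc.POPULATION_SIZES[t]) == int(kt.loc[t, s])
    for t in mc.POPULATIONS
    for s in mc.POPULATIONS
)
total = mc.total_recurrent_synapses()
print(f"in-degree entries reproduced by ceil(S/N): {matches}/64")
print(f"total recurrent synapses: {total:,}")
print(f"64-bit weight storage: {mc.weight_memory_gb(64):.2f} GB")
print(
    "-> replacing per-synapse weights by three per-distribution values frees"
    "\n   that storage entirely (about 15% of the full model's footprint)"
)
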