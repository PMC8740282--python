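# synquant

Synaptic-weight discretization for spiking neuronal networks: how coarse can
the weights of a recurrent network be before its dynamics change, and how do
you check?

Memory for synaptic weights dominates the footprint of large-scale neuronal
network simulations and is scarce on neuromorphic hardware. A natural remedy
is to store each weight as one of a small set of discrete values. `synquant`
implements and validates this program end to end for networks of
current-based leaky integrate-and-fire (LIF) neurons with normally
distributed weights, modeled on the eight-population cortical-microcircuit
architecture:

* **Weight discretization** (`synquant.weights`) — an interval
  [w_min, w_max] is split into N_bins equal bins and every sampled weight is
  rounded to the center of its bin. The *naive* scheme fixes the interval at
  w̄ ± 5Δw; the *moment-preserving* scheme instead solves for the interval at
  which the discrete distribution's standard deviation Δw_Nbins equals the
  reference Δw_∞ (analytically [w̄ − 2Δw, w̄ + 2Δw] for two bins, by
  bracketed root finding otherwise). The discrete probability mass function
  p*_i = F(edge_i) − F(edge_{i−1}) and its exact moments are available for
  any grid.
* **Network construction** (`synquant.network`, `synquant.microcircuit`) —
  multi-population random connectivity under the *fixed in-degree* rule
  (every target neuron receives exactly K_YX synapses) or the *fixed total
  number* rule (exactly S_YX synapses per population pair, binomial
  in-degrees with Fano factor 1 − 1/N_Y); Dale-clipped normal weights,
  left-clipped normal delays, multapses allowed, autapses redrawn. The full
  printed parameter set of the cortical microcircuit (~3×10⁸ synapses) is
  bundled; *twins* of a built network replace weights one-by-one by their
  discrete counterparts while keeping topology, delays, inputs, and initial
  conditions identical.
* **Simulation** (`synquant.simulator`) — exact integration of the linear
  subthreshold dynamics on a fixed time grid (closed-form one-step
  propagator), exponential postsynaptic currents with instantaneous onset,
  threshold/reset with absolute refractoriness, and independent Poisson
  external drive per neuron.
* **Validation statistics** (`synquant.stats`, `synquant.pipeline`) —
  per-population distributions of time-averaged firing rates (FR), ISI
  coefficients of variation (CV), and zero-lag spike-count correlation
  coefficients (CC, 2 ms bins), compared by the two-sample
  Kolmogorov–Smirnov score D_KS = sup|P(x) − Q(x)|. Significance is judged
  against a *realization baseline*: KS scores between independent
  realizations of the reference model. Uniform spike-time surrogates and
  observation-duration diagnostics probe what the metrics can actually
  resolve, including the intrinsic CC lattice
  ΔCC = 1/√(N_i N_j (1 − N_i/M)(1 − N_j/M)).
* **Mean-field theory** (`synquant.meanfield`) — ensemble mean and variance
  of the synaptic-input cumulants μ_i = τ_s Σ w_ij ν_j and
  σ²_i = τ_s Σ w²_ij ν_j across a population, from Wald's and the
  Blackwell–Girshick equations, and the relative errors ε introduced by 1-
  and 2-bin weights as functions of the heterogeneity ratios
  j = ⟨δw²⟩/⟨w⟩², k = ⟨δK²⟩/⟨K⟩, f = ⟨δν²⟩/⟨ν⟩². The theory predicts when
  mean-only weights are safe: ε₁(⟨σ²⟩) = j always, while the
  across-population variance errors vanish as in-degree heterogeneity grows.

## Worked example

```
$ python examples/discretize_weights.py
reference: mean 87.81 pA, std 8.781 pA
n_bins  naive std   m.p. std            m.p. interval
     1     0.0000         --  (std 0 by construction)
     2    21.9525     8.7810   [  70.248,  105.372] pA
     3     9.0492     8.7810   [  68.430,  107.190] pA
     4    11.5086     8.7810   [  67.398,  108.222] pA
     8     9.3352     8.7810   [  64.849,  110.771] pA
    16     8.9228     8.7810   [  62.232,  113.388] pA

2-bin quantized sample: mean 87.780 pA (ref 87.81), std 8.781 pA (ref 8.781)
-> two discrete values at mean +/- std carry the full first two moments
```

Naive binning over ±5σ distorts the weight spread — a 2-bin grid inflates
the std from 8.78 to 21.95 pA (the two centers sit at ±2.5σ), while odd bin
counts underestimate it; only by accident is 3-bin close. The
moment-preserving interval keeps the std at 8.781 pA exactly for every bin
count, so even *one bit per synapse* (two values, w̄ ± Δw) preserves the
first two moments of the weight distribution — and, for the networks
studied here, the firing statistics.

Other examples, one per capability (each prints its interpretation):

* `examples/simulate_toy_network.py` — build and simulate the bundled
  two-population E-I network (asynchronous irregular regime, ~5–6 spikes/s,
  ISI CV ≈ 0.8).
* `examples/twin_validation.py` — reference vs. moment-preserving 2-bin
  twin vs. realization baseline, with KS scores and verdicts.
* `examples/meanfield_error_table.py` — ε table as in-degree heterogeneity
  k varies at the microcircuit's weight spread j = 0.01.
* `examples/microcircuit_memory.py` — connectivity arithmetic of the
  microcircuit (64/64 in-degrees reproduced, 298,880,941 synapses, 2.39 GB
  of 64-bit weights).
* `examples/observation_duration.py` — surrogate specificity and
  distribution convergence with observation time.

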