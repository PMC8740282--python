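# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `synquant`, in the order data flows through the
package.

## Weight discretization

A reference weight distribution is a normal N(w̄, Δw²), clipped to preserve
the sign of its projection (Dale's principle): wrong-signed draws are set to
zero at sampling time. Discretization partitions an interval
[w_min, w_max] into N_bins equal bins with centers
v_i = w_min + (1/2 + i − 1)·w_step, and replaces each sampled weight by the
center of its bin. Out-of-interval weights map to the first/last center; a
weight exactly on an interior edge maps to the larger adjacent center (a
measure-zero event for continuous draws, fixed for determinism).

The induced probability mass function uses the *untruncated* normal CDF,
with the end bins absorbing both tails, so it is exactly the distribution
of quantized reference draws. Its moments are computed in closed form from
centers and masses; a Monte-Carlo quantization of 10⁶ draws is the test
oracle.

The moment-preserving interval is symmetric about the mean (which preserves
the mean exactly, by symmetry) with a half-width chosen so the discrete std
equals the reference std:

* N_bins = 1: impossible — the discrete std is zero by construction. The
  single-center (mean-only) grid is returned with a warning; this *is* the
  1-bin scheme used throughout.
* N_bins = 2: analytic, half-width 2Δw (centers w̄ ± Δw, mass ½ each).
* 3 ≤ N_bins < 2¹⁶: the half-width is found numerically. The discrete std
  starts below the reference for narrow intervals, so scanning half-widths
  upward from 0.1Δw in ×1.5 steps until the sign of (Δw_Nbins − Δw_∞)
  flips brackets the *first* intersection (odd bin counts have a second,
  spurious one at wide intervals); Brent's method then refines to an
  absolute half-width tolerance of 1e−12 (in units of Δw) — far below any
  dynamical effect, and a package choice since no canonical tolerance
  exists for this construction.
* N_bins ≥ 2¹⁶: the naive ±5Δw interval is used unchanged; at that
  resolution its moment distortion is negligible and the optimization is
  wasted effort.

## Network model

Populations are concatenated into one 0-based global index space in listing
order. Connectivity is random with replacement per ordered population pair:
multapses allowed, autapses rejected and redrawn (so synapse counts stay
exact). Under *fixed in-degree*, each target neuron receives exactly K_YX
synapses (⟨δK²⟩ = 0); under *fixed total number*, exactly S_YX (source,
target) pairs are drawn, making in-degrees Binomial(S_YX, 1/N_Y) with Fano
factor 1 − 1/N_Y. The conversion S = log(1 − C)/log((N_Y N_X − 1)/(N_Y N_X))
from a pairwise connection probability rounds half-to-even (the printed
tables give integers; the rounding rule is a package choice). In-degrees
derive from synapse totals as ceil(S/N_Y), so any nonzero projection keeps
at least one synapse.

Weights come from the projection's reference normal with Dale clipping;
delays from a normal left-clipped at the resolution h. The bundled
cortical-microcircuit parameter set assigns the excitatory distribution
(87.81, 8.781) pA to excitatory sources, (−351.24, 35.124) pA (g = −4) to
inhibitory sources, and doubles both for the L4E → L2/3E projection; all
three have a 10% coefficient of variation, hence j = ⟨δw²⟩/⟨w⟩² = 0.01.

A *twin* of a built network copies every column of the synapse table except
the weights, which are quantized per projection — so reference and twin
share connectivity, delays, initial conditions, and external input
realization, and differ only in weight resolution.

`scale_network` shrinks population sizes and synapse counts (in-degrees via
ceiling) for desk-scale property testing. Scaled networks deliberately make
no claim to reproduce full-scale statistics; downscaling cannot preserve
rates and correlations simultaneously.

## Simulator

Neurons are current-based LIF with exponential postsynaptic currents:
τ_m V̇ = −(V − E_L) + R_m (I + I_dc), τ_s İ = −I, threshold V_θ, reset
V_reset, absolute refractory period τ_ref. Between grid points the system
is linear and is propagated *exactly* by the closed-form one-step map
(I ← e^{−h/τ_s} I; V − E_L ← e^{−h/τ_m}(V − E_L) + p_vi·I with the standard
two-exponential coefficient); synaptic events add weight-sized jumps to I
at grid points. The degenerate case τ_m = τ_s (removable singularity in
p_vi) is rejected rather than special-cased. Subthreshold accuracy is
validated against an adaptive high-precision ODE solver (≤ 1e−10 mV per
step) and a 100-step closed form (≤ 1e−9 mV).

Event ordering within a step, which any grid-based simulator must fix:
deliveries due at the step are added to I, the state is propagated, then
threshold is checked and reset applied; the spike time is recorded at the
post-step grid point. All spike times are therefore integer multiples of
h. Refractoriness clamps V at V_reset for round(τ_ref/h) steps while I
continues to decay and accumulate — so consecutive spike times differ by at
least τ_ref exactly. Delays are rounded to the nearest grid multiple,
minimum one step. External drive is an independent Poisson count per neuron
and step with mean K_ext·ν_ext·h, delivered with a one-step delay (the
choice is immaterial for stationary statistics); counts are drawn in blocks
of 2000 steps purely to amortize generator overhead — the event stream is
identical to per-step draws. Randomness (initial potentials, external
input) derives from the configuration seed via independent substreams, so a
record is reproducible bit-for-bit.

Statistical agreement, not event-level agreement, is the design goal when
comparing against other grid-based simulators, whose within-step ordering
may differ.

## Spike-train statistics

All statistics use only the observation window [T_trans, T_sim); the
startup transient is discarded. FR_i = N_i/D (zeros included), hence FR
lives on a 1/D lattice. CV uses the population-std convention (ddof = 0)
and requires ≥ 3 spikes (≥ 2 ISIs); excluded neurons are reported, never
silently dropped. CC is the zero-lag Pearson correlation of spike-count
vectors with Δ = 2 ms bins (matching τ_ref, so counts are near-binary); per
population, the `sample_size` (default 200) lowest-id neurons enter the
pairwise computation — a deterministic rule chosen over random selection so
twins and reference select identical neurons. Pairs involving zero-variance
count vectors are undefined, excluded, and counted. The coincidence-count
form of the CC and its exact lattice spacing
ΔCC = 1/√(N_i N_j (1 − N_i/M)(1 − N_j/M)) are implemented separately and
cross-checked; the lattice is exact in the binary-count regime.

Histograms use Freedman–Diaconis widths 2·IQR/n^{1/3} with
linear-interpolation quartiles (the FD width depends on the quartile
convention; this one is fixed and documented), edges computed from the
*reference* sample and reused for every compared distribution. KS scores
are computed on raw samples, not on histograms. Surrogate spike trains
redraw each neuron's times i.i.d. uniform on the window in continuous time
(grid snapping is immaterial after Δ-binning): counts — and hence FR — are
preserved exactly, correlations and ISI structure destroyed.

## Mean-field theory

The ensemble formulas for ⟨μ⟩, ⟨σ²⟩, ⟨δμ²⟩, ⟨δ(σ²)²⟩ assume K_i, w_ij, ν_j
mutually independent; they are validated against a 10⁵-neuron sampling
oracle. Discretization errors ε = |x_∞ − x_binned|/|x_binned| are computed
by *direct evaluation* of the ensemble formulas with substituted weight
moments (1-bin: variance 0, ⟨w⁴⟩ = ⟨w⟩⁴; 2-bin: variance kept,
⟨w⁴⟩ = ⟨w⟩⁴ + 6⟨w⟩²⟨δw²⟩ + ⟨δw²⟩²), never from transcribed closed forms —
the closed forms are recovered as tested identities instead: ε₁(⟨μ⟩) and
all three vanishing 2-bin errors are exactly zero, ε₁(⟨σ²⟩) = j, and for
k → ∞, ε₁(⟨δμ²⟩) → 0 while ε₁(⟨δ(σ²)²⟩) → j(2 + j). The rate-heterogeneity
ratio is f = ⟨δν²⟩/⟨ν⟩², the only dimensionally consistent definition that
reproduces those limits; the tests enforce them. Rate statistics for
per-projection error tables are intended to come from a reference-network
simulation, but can be supplied analytically. The per-pair aggregate is an
unweighted mean over projections with nonzero connectivity. τ_s enters in
ms and is converted internally; absolute units cancel in every ε.

## Desk-scale experiment and synthetic data

The full-scale validation experiment (77k neurons, 15 biological minutes,
five realizations) is cluster-scale. The package's experiment runs on a
bundled two-population E-I network: 400 excitatory and 100 inhibitory LIF
neurons with the microcircuit neuron parameters and 10% weight CV, fixed
in-degrees K_E = 160, K_I = 40, g = −5 (inhibition-dominated recurrence),
and K_ext = 900 Poisson inputs at 8 s⁻¹. This operating point was chosen
once, before any validation measurements, to yield sustained asynchronous
irregular activity (≈ 5–6 spikes/s, ISI CV ≈ 0.8) — the regime in which the
mean-field assumptions hold and the weight-resolution question is
meaningful. The acceptance experiment simulates 100 s of biological time
with a 1 s discarded transient, five baseline realizations (every random
component redrawn), and moment-preserving twins; the pass rule is
KS ≤ baseline mean + 2·std (the band multiplier is a parameter; 1·std is
the stricter alternative).

What this desk-scale experiment shows: the twin machinery, the statistics,
and the baseline logic behave correctly, and the qualitative ordering
(2-bin within baseline; mean-only weights narrowing the FR distribution
under fixed in-degrees) emerges as the theory predicts. What it does not
show: quantitative agreement with full-scale cortical-microcircuit
statistics — small networks have larger finite-size correlations, coarser
CC lattices, and in-degrees an order of magnitude below the regime where
the diffusion approximation is most accurate.

Synthetic generators carry their ground truth: periodic trains (CV = 0),
homogeneous Poisson trains (CV → 1, CC → 0), and correlated pairs built as
a single interaction process — a common mother train of rate c·ν injected
into both children plus independent trains of rate (1 − c)·ν, giving
zero-lag count correlation exactly c for superposed Poisson counts at any
bin size. All generators are deterministic given their seed.

## Known limitations

* Continuous-time (off-grid) spike handling is not implemented; grid
  constraints inflate synchrony at first order in h, identically in
  reference and twins.
* No self-consistent rate solver: the theory takes rates as measured
  inputs and predicts input statistics, not output rates; CV/CC are not
  predicted.
* Long-tailed weight distributions, plasticity, and non-uniform
  (e.g. quantile or k-means) binning are out of scope.
* The fixed-total-number rule scaled to desk size keeps per-neuron
  in-degrees unrealistically dense; scaled networks are for property tests
  only.
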