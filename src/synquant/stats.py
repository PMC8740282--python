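"""Spike-train statistics and distribution comparison.

The validation layer characterizes network activity by three per-population
distributions — time-averaged single-neuron firing rates (FR), coefficients
of variation of the interspike intervals (ISI CV), and zero-lag pairwise
spike-count correlation coefficients (CC) — and compares them between
networks via the two-sample Kolmogorov-Smirnov statistic.

All statistics are computed over the observation window only; activity
before the startup transient is discarded.  FR and CC are intrinsically
discrete: FR in steps of 1/D (D the observation duration) and CC on a
lattice whose spacing depends only on the two spike counts and the number
of count bins — for homogeneous low-rate populations this lattice is
visible as an oscillatory pattern in the CC histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

__all__ = [
    "SpikeTrainSet",
    "StatisticDistribution",
    "firing_rates",
    "isi_cv",
    "spike_count_vectors",
    "correlation_coefficients",
    "cc_discretization_level",
    "freedman_diaconis_edges",
    "ks_score",
    "surrogate_randomize",
]


@dataclass
class SpikeTrainSet:
    """Per-neuron spike times within an observation window.

    ``trains[i]`` is the sorted array of spike times (ms) of neuron ``i``
    inside ``[t_start, t_stop)``; ``population[i]`` is its population label.
    """

    trains: list
    t_start: float
    t_stop: float
    population: np.ndarray

    def __post_init__(self) -> None:
        if not self.t_stop > self.t_start:
            raise ValueError("need t_stop > t_start")
        self.population = np.asarray(self.population, dtype=object)
        if len(self.population) != len(self.trains):
            raise ValueError("one population label per neuron required")

    @classmethod
    def from_record(cls, record, population_labels) -> "SpikeTrainSet":
        """Extract the observed spike trains from a simulator record."""
        return cls(
            trains=record.spike_trains(observed_only=True),
            t_start=record.transient,
            t_stop=record.duration,
            population=population_labels,
        )

    @property
    def duration(self) -> float:
        """Observation duration D in ms."""
        return self.t_stop - self.t_start

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def population_names(self) -> list:
        seen = dict.fromkeys(self.population)
        return list(seen)

    def neurons_of(self, name: str) -> np.ndarray:
        return np.nonzero(self.population == name)[0]


@dataclass
class StatisticDistribution:
    """Samples of one statistic for one population, with shared histogram."""

    statistic: str  # FR | CV | CC
    population: str
    samples: np.ndarray
    edges: np.ndarray | None = None
    counts: np.ndarray | None = field(default=None, repr=False)

    def histogram(self, edges=None):
        e = self.edges if edges is None else np.asarray(edges)
        counts, _ = np.histogram(self.samples, bins=e)
        return counts, e


def firing_rates(trains: SpikeTrainSet) -> np.ndarray:
    """Time-averaged rate N_i / D per neuron, in 1/s (zeros included)."""
    d_s = trains.duration * 1e-3
    return np.array([len(t) for t in trains.trains]) / d_s


def isi_cv(trains: SpikeTrainSet, min_spikes: int = 3):
    """ISI coefficient of variation per eligible neuron.

    CV_i = sigma_ISI / mu_ISI with the population-std convention (ddof=0).
    Neurons with fewer than ``min_spikes`` spikes (fewer than two ISIs)
    carry no irregularity information and are excluded; their indices are
    returned alongside the values.

    Returns
    -------
    (cv_values, neuron_indices, excluded_indices)
    """
    values, kept, excluded = [], [], []
    for i, t in enumerate(trains.trains):
        if len(t) < min_spikes:
            excluded.append(i)
            continue
        isi = np.diff(t)
        mu = isi.mean()
        values.append(isi.std() / mu)
        kept.append(i)
    if not kept:
        warnings.warn("no neuron has enough spikes for a CV estimate", stacklevel=2)
    return np.asarray(values), np.asarray(kept, int), np.asarray(excluded, int)


def spike_count_vectors(trains: SpikeTrainSet, bin_size: float) -> np.ndarray:
    """Spike counts per neuron in contiguous bins of width ``bin_size`` (ms).

    The vectors have length M = floor(D / bin_size); a trailing partial bin
    is dropped.
    """
    m = int(trains.duration // bin_size)
    if m < 1:
        raise ValueError("bin_size exceeds the observation duration")
    out = np.zeros((trains.n_neurons, m), dtype=np.int64)
    t_end = trains.t_start + m * bin_size
    for i, t in enumerate(trains.trains):
        idx = ((t[t < t_end] - trains.t_start) / bin_size).astype(np.int64)
        np.clip(idx, 0, m - 1, out=idx)
        out[i] = np.bincount(idx, minlength=m)
    return out


def coincidence_cc(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Zero-lag CC from the coincidence count G = x_i . x_j.

    Algebraically identical to the Pearson correlation of the count vectors
    for binary vectors (counts 0/1); used as the lattice / cross-check form.
    """
    m = len(x_i)
    n_i, n_j = x_i.sum(), x_j.sum()
    g = float(np.dot(x_i, x_j))
    denom = np.sqrt(n_i * n_j * (1 - n_i / m) * (1 - n_j / m))
    return (g - n_i * n_j / m) / denom


def correlation_coefficients(
    trains: SpikeTrainSet,
    bin_size: float,
    sample_size: int = 200,
    populations=None,
):
    """Pairwise zero-lag Pearson CCs of spike-count vectors, per population.

    For each population the ``sample_size`` lowest-id neurons are selected
    (all neurons if the population is smaller, with a warning) and the CC is
    computed for every unordered pair.  Pairs involving a zero-variance
    count vector (silent or strictly periodic-at-bin neurons) are undefined
    and excluded; their number is reported.

    Returns
    -------
    (samples, n_excluded) : dict population -> CC array, dict -> int
    """
    counts = spike_count_vectors(trains, bin_size)
    names = populations if populations is not None else trains.population_names()
    samples, n_excluded = {}, {}
    for name in names:
        ids = trains.neurons_of(name)
        if len(ids) < 2:
            raise ValueError(f"population {name!r} has fewer than 2 neurons")
        if len(ids) > sample_size:
            ids = ids[:sample_size]
        elif len(ids) < sample_size:
            warnings.warn(
                f"population {name!r} smaller than sample_size={sample_size}; "
                "using all neurons",
                stacklevel=2,
            )
        x = counts[ids].astype(float)
        sd = x.std(axis=1)
        ok = sd > 0
        n_exc_neurons = int((~ok).sum())
        x = x[ok]
        if len(x) < 2:
            samples[name] = np.empty(0)
            n_excluded[name] = n_exc_neurons
            continue
        cc = np.corrcoef(x)
        iu = np.triu_indices(len(x), k=1)
        samples[name] = cc[iu]
        k = len(ids)
        n_excluded[name] = k * (k - 1) // 2 - len(samples[name])
    return samples, n_excluded


def cc_discretization_level(n_i: int, n_j: int, m: int) -> float:
    """Lattice spacing of attainable CC values for given spike counts.

    Incrementing the coincidence count by one changes the CC by exactly
    1 / sqrt(n_i n_j (1 - n_i/m)(1 - n_j/m)); for n << m this is
    approximately 1/sqrt(n_i n_j).
    """
    if not (0 < n_i < m and 0 < n_j < m):
        raise ValueError("spike counts must satisfy 0 < n < M")
    return 1.0 / np.sqrt(n_i * n_j * (1 - n_i / m) * (1 - n_j / m))


def freedman_diaconis_edges(reference_samples, fallback_bins: int = 10) -> np.ndarray:
    """Histogram edges with the Freedman-Diaconis width 2*IQR/n^(1/3).

    Edges span the reference sample range; the same edges are reused for
    every distribution compared against that reference, so histogram shape
    differences are not confounded by binning.  Quartiles use linear
    interpolation.  A zero IQR (heavily discrete data) falls back to
    ``fallback_bins`` equal bins over the range, with a warning.
    """
    x = np.asarray(reference_samples, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least two reference samples")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    lo, hi = x.min(), x.max()
    if hi == lo:
        hi = lo + 1.0
    if iqr <= 0:
        warnings.warn("zero IQR; falling back to equal-width bins", stacklevel=2)
        return np.linspace(lo, hi, fallback_bins + 1)
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    n_bins = max(int(np.ceil((hi - lo) / width)), 1)
    return lo + width * np.arange(n_bins + 1)


def ks_score(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic on raw samples.

    The maximum vertical distance between the two empirical CDFs; 0 for
    identical samples, 1 for disjoint supports.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS score requires two non-empty samples")
    return float(ks_2samp(a, b, method="asymp").statistic)


def surrogate_randomize(
    trains: SpikeTrainSet, rng: np.random.Generator
) -> SpikeTrainSet:
    """Null-hypothesis surrogate: spike times i.i.d. uniform in the window.

    Every neuron keeps its exact spike count, so the FR distribution is
    preserved; millisecond-scale correlations and ISI structure are
    destroyed (long surrogate trains have Poisson-like CV near 1 and CC
    near 0).
    """
    new = [
        np.sort(rng.uniform(trains.t_start, trains.t_stop, size=len(t)))
        for t in trains.trains
    ]
    return SpikeTrainSet(
        trains=new,
        t_start=trains.t_start,
        t_stop=trains.t_stop,
        population=trains.population.copy(),
    )
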