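"""Construction of multi-population random networks.

Populations are concatenated into a single global index space (0-based, in
the order they are listed in the spec).  Connectivity is population-pair
specific and random with replacement, so multiple synapses between the same
pair of neurons (multapses) occur, while self-connections (autapses) are
rejected and redrawn.  Two rules are supported:

* ``fixed_in_degree`` — every neuron of the target population receives
  exactly K_YX synapses from the source population (zero in-degree variance).
* ``fixed_total_number`` — exactly S_YX synapses are established between the
  pair; per-target in-degrees are then Binomial(S, 1/N_Y) with Fano factor
  1 − 1/N_Y.

Weights are drawn from the projection's normal reference distribution with
Dale clipping (wrong-signed draws set to zero); delays are normal,
left-clipped at the simulation resolution h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .weights import NormalWeightSpec, quantize

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "NetworkSpec",
    "SynapseTable",
    "total_synapse_number",
    "in_degree",
    "build_network",
    "build_fixed_in_degree",
    "build_fixed_total_number",
    "sample_weights",
    "sample_delays",
    "discretize_network",
    "scale_network",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One neuron population: size, external drive, initial conditions."""

    name: str
    size: int
    external_in_degree: int = 0
    v0_mean: float = -65.0
    v0_std: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population {self.name!r} must have size >= 1")
        if self.external_in_degree < 0 or self.v0_std < 0:
            raise ValueError("external_in_degree and v0_std must be >= 0")


@dataclass(frozen=True)
class ConnectionSpec:
    """One projection between an ordered pair of populations.

    At least one of ``connection_probability``, ``total_synapses``,
    ``in_degree`` must be given; the builder resolves whichever its rule
    needs (probabilities are converted through ``total_synapse_number``).
    """

    source: str
    target: str
    weight_spec: NormalWeightSpec
    delay_mean: float
    delay_std: float
    connection_probability: float | None = None
    total_synapses: int | None = None
    in_degree: int | None = None

    def __post_init__(self) -> None:
        if (
            self.connection_probability is None
            and self.total_synapses is None
            and self.in_degree is None
        ):
            raise ValueError(
                f"{self.source}->{self.target}: need one of connection_probability,"
                " total_synapses, in_degree"
            )

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class NetworkSpec:
    populations: list
    connections: list
    rule: str = "fixed_in_degree"
    scale: float = 1.0
    seed: int = 0
    scaled: bool = False  # provenance flag set by scale_network

    def __post_init__(self) -> None:
        if self.rule not in ("fixed_in_degree", "fixed_total_number"):
            raise ValueError(f"unknown connectivity rule {self.rule!r}")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def population_slices(self) -> dict:
        """Global-id slice of each population, concatenation order."""
        out, start = {}, 0
        for p in self.populations:
            out[p.name] = slice(start, start + p.size)
            start += p.size
        return out

    def population_labels(self) -> np.ndarray:
        """Per-neuron population name, length n_neurons."""
        return np.concatenate(
            [np.full(p.size, p.name, dtype=object) for p in self.populations]
        )


@dataclass
class SynapseTable:
    """Explicit synapse list: (source_id, target_id, weight, delay, projection)."""

    source_id: np.ndarray
    target_id: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    projection: np.ndarray

    def __len__(self) -> int:
        return len(self.source_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_id": self.source_id,
                "target_id": self.target_id,
                "weight_pA": self.weight,
                "delay_ms": self.delay,
                "projection": self.projection,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SynapseTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            source_id=df["source_id"].to_numpy(np.int64),
            target_id=df["target_id"].to_numpy(np.int64),
            weight=df["weight_pA"].to_numpy(float),
            delay=df["delay_ms"].to_numpy(float),
            projection=df["projection"].to_numpy(object),
        )

    @classmethod
    def concatenate(cls, tables) -> "SynapseTable":
        return cls(
            source_id=np.concatenate([t.source_id for t in tables]),
            target_id=np.concatenate([t.target_id for t in tables]),
            weight=np.concatenate([t.weight for t in tables]),
            delay=np.concatenate([t.delay for t in tables]),
            projection=np.concatenate([t.projection for t in tables]),
        )


def spec_to_dict(spec: NetworkSpec) -> dict:
    """JSON-ready representation of a network specification."""
    return {
        "rule": spec.rule,
        "scale": spec.scale,
        "seed": spec.seed,
        "scaled": spec.scaled,
        "populations": [
            {
                "name": p.name,
                "N": p.size,
                "K_ext": p.external_in_degree,
                "V0_mean": p.v0_mean,
                "V0_std": p.v0_std,
            }
            for p in spec.populations
        ],
        "connections": [
            {
                "source": c.source,
                "target": c.target,
                "C": c.connection_probability,
                "S": c.total_synapses,
                "K": c.in_degree,
                "weight_mean": c.weight_spec.mean,
                "weight_std": c.weight_spec.std,
                "delay_mean": c.delay_mean,
                "delay_std": c.delay_std,
            }
            for c in spec.connections
        ],
    }


def spec_from_dict(d: dict) -> NetworkSpec:
    populations = [
        PopulationSpec(
            name=p["name"],
            size=p["N"],
            external_in_degree=p["K_ext"],
            v0_mean=p["V0_mean"],
            v0_std=p["V0_std"],
        )
        for p in d["populations"]
    ]
    connections = [
        ConnectionSpec(
            source=c["source"],
            target=c["target"],
            connection_probability=c.get("C"),
            total_synapses=c.get("S"),
            in_degree=c.get("K"),
            weight_spec=NormalWeightSpec(c["weight_mean"], c["weight_std"]),
            delay_mean=c["delay_mean"],
            delay_std=c["delay_std"],
        )
        for c in d["connections"]
    ]
    return NetworkSpec(
        populations=populations,
        connections=connections,
        rule=d["rule"],
        scale=d.get("scale", 1.0),
        seed=d.get("seed", 0),
        scaled=d.get("scaled", False),
    )


def save_spec(spec: NetworkSpec, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(spec_to_dict(spec), fh, indent=1)


def load_spec(path) -> NetworkSpec:
    import json

    with open(path) as fh:
        return spec_from_dict(json.load(fh))


def total_synapse_number(c: float, n_source: int, n_target: int) -> int:
    """Synapse count realizing pairwise connection probability ``c``.

    Inverts the probability that a given (source, target) pair is hit at
    least once when synapses are placed uniformly with replacement:
    S = log(1−c) / log((N_t·N_s − 1)/(N_t·N_s)), rounded half-to-even.
    """
    if not 0 <= c < 1:
        raise ValueError(f"connection probability must be in [0, 1), got {c}")
    if n_source < 1 or n_target < 1 or n_source * n_target < 2:
        raise ValueError("need n_source*n_target >= 2")
    if c == 0:
        return 0
    pairs = n_source * n_target
    return int(np.rint(math.log(1 - c) / math.log((pairs - 1) / pairs)))


def in_degree(total_synapses: int, n_target: int) -> int:
    """Per-target in-degree: ceil(S / N_target).

    Rounding up guarantees at least one synapse for any nonzero S.
    """
    if total_synapses < 0 or n_target < 1:
        raise ValueError("need total_synapses >= 0 and n_target >= 1")
    return -(-total_synapses // n_target)


def sample_weights(
    weight_spec: NormalWeightSpec, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal weight draws with Dale clipping (wrong-signed draws -> 0)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    w = rng.normal(weight_spec.mean, weight_spec.std, size=count)
    if weight_spec.excitatory:
        w[w < 0] = 0.0
    else:
        w[w > 0] = 0.0
    return w


def sample_delays(
    delay_mean: float,
    delay_std: float,
    count: int,
    h: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Normal delay draws left-clipped at the simulation resolution h."""
    if delay_mean < h:
        raise ValueError(f"delay_mean {delay_mean} below resolution {h}")
    d = rng.normal(delay_mean, delay_std, size=count)
    return np.maximum(d, h)


def _reject_autapses(
    sources: np.ndarray,
    targets: np.ndarray,
    draw_sources,
    same_population: bool,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Redraw source ids until no draw lands on its own target."""
    if not same_population:
        return sources
    for _ in range(max_rounds):
        bad = sources == targets
        if not bad.any():
            return sources
        sources = sources.copy()
        sources[bad] = draw_sources(int(bad.sum()))
    raise RuntimeError("autapse rejection did not converge")


def _resolved_count(conn: ConnectionSpec, n_source: int, n_target: int, rule: str):
    """(in-degree, total) resolved from whichever fields are present."""
    s = conn.total_synapses
    if s is None and conn.connection_probability is not None:
        s = total_synapse_number(conn.connection_probability, n_source, n_target)
    if rule == "fixed_in_degree":
        k = conn.in_degree
        if k is None:
            if s is None:
                raise ValueError(f"{conn.label}: cannot resolve in-degree")
            k = in_degree(s, n_target)
        return k, None
    if s is None:
        if conn.in_degree is None:
            raise ValueError(f"{conn.label}: cannot resolve synapse count")
        s = conn.in_degree * n_target
    return None, s


def _build_projection(
    conn: ConnectionSpec,
    src_slice: slice,
    tgt_slice: slice,
    rule: str,
    h: float,
    rng: np.random.Generator,
) -> SynapseTable | None:
    n_source = src_slice.stop - src_slice.start
    n_target = tgt_slice.stop - tgt_slice.start
    same = src_slice == tgt_slice
    if same and n_source == 1:
        k, s = _resolved_count(conn, n_source, n_target, rule)
        if (k or 0) >= 1 or (s or 0) >= 1:
            raise ValueError(
                f"{conn.label}: single-neuron self-projection admits only autapses"
            )
        return None

    def draw_sources(n):
        return rng.integers(src_slice.start, src_slice.stop, size=n)

    k, s = _resolved_count(conn, n_source, n_target, rule)
    if rule == "fixed_in_degree":
        if k == 0:
            return None
        targets = np.repeat(np.arange(tgt_slice.start, tgt_slice.stop), k)
        sources = draw_sources(n_target * k)
    else:
        if s == 0:
            return None
        sources = draw_sources(s)
        targets = rng.integers(tgt_slice.start, tgt_slice.stop, size=s)
    sources = _reject_autapses(sources, targets, draw_sources, same)
    n_syn = len(sources)
    weights = sample_weights(conn.weight_spec, n_syn, rng)
    delays = sample_delays(conn.delay_mean, conn.delay_std, n_syn, h, rng)
    return SynapseTable(
        source_id=sources.astype(np.int64),
        target_id=targets.astype(np.int64),
        weight=weights,
        delay=delays,
        projection=np.full(n_syn, conn.label, dtype=object),
    )


def build_network(
    spec: NetworkSpec, rng: np.random.Generator | None = None, h: float = 0.1
) -> SynapseTable:
    """Draw one realization of the connectivity, weights, and delays.

    One independent RNG substream per projection (spawned from the spec
    seed) makes the realization reproducible regardless of projection
    evaluation order.
    """
    slices = spec.population_slices()
    if rng is None:
        streams = np.random.SeedSequence(spec.seed).spawn(len(spec.connections))
        rngs = [np.random.default_rng(s) for s in streams]
    else:
        rngs = [rng] * len(spec.connections)
    tables = []
    for conn, r in zip(spec.connections, rngs):
        t = _build_projection(
            conn, slices[conn.source], slices[conn.target], spec.rule, h, r
        )
        if t is not None:
            tables.append(t)
    if not tables:
        empty = np.empty(0)
        return SynapseTable(
            empty.astype(np.int64), empty.astype(np.int64), empty, empty,
            np.empty(0, dtype=object),
        )
    return SynapseTable.concatenate(tables)


def build_fixed_in_degree(
    spec: NetworkSpec, rng: np.random.Generator | None = None, h: float = 0.1
) -> SynapseTable:
    """Build under the fixed in-degree rule (every target gets exactly K)."""
    return build_network(replace(spec, rule="fixed_in_degree"), rng, h)


def build_fixed_total_number(
    spec: NetworkSpec, rng: np.random.Generator | None = None, h: float = 0.1
) -> SynapseTable:
    """Build under the fixed total number rule (exactly S synapses per pair)."""
    return build_network(replace(spec, rule="fixed_total_number"), rng, h)


def discretize_network(table: SynapseTable, grids: dict) -> SynapseTable:
    """Twin network: same topology and delays, weights quantized per projection.

    ``grids`` maps each projection label occurring in the table to its
    :class:`DiscretizationGrid`.  Row order is preserved; every weight is
    replaced one-by-one by its discrete counterpart.
    """
    labels = np.unique(table.projection)
    missing = [l for l in labels if l not in grids]
    if missing:
        raise KeyError(f"no discretization grid for projections {missing}")
    new_w = np.empty_like(table.weight)
    for label in labels:
        m = table.projection == label
        new_w[m] = quantize(table.weight[m], grids[label])
    return SynapseTable(
        source_id=table.source_id.copy(),
        target_id=table.target_id.copy(),
        weight=new_w,
        delay=table.delay.copy(),
        projection=table.projection.copy(),
    )


def scale_network(spec: NetworkSpec, factor: float) -> NetworkSpec:
    """Downscale population sizes and synapse counts for desk-scale testing.

    Sizes and total synapse numbers are multiplied by ``factor`` and rounded
    (in-degrees via ceiling so no projection silently vanishes); external
    in-degrees are left unchanged.  The returned spec carries a provenance
    flag — scaled networks support property tests only and are not claimed
    to reproduce full-scale statistics.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    if factor == 1:
        return spec
    new_pops = []
    for p in spec.populations:
        n = int(round(p.size * factor))
        if n < 1:
            raise ValueError(f"scaling by {factor} empties population {p.name!r}")
        new_pops.append(replace(p, size=n))
    new_conns = []
    for c in spec.connections:
        kwargs = {}
        if c.in_degree is not None:
            kwargs["in_degree"] = math.ceil(c.in_degree * factor)
        if c.total_synapses is not None:
            kwargs["total_synapses"] = int(round(c.total_synapses * factor))
        new_conns.append(replace(c, **kwargs))
    return replace(
        spec,
        populations=new_pops,
        connections=new_conns,
        scale=spec.scale * factor,
        scaled=True,
    )
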