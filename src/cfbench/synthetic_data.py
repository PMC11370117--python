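"""Simulated BCR heavy-chain repertoires with known clonal ground truth.

The generator mirrors the structure of lineage-based repertoire simulation:
germline V/J segments are recombined into naive clone ancestors with random
junctional insertions, each clone is expanded along a random lineage tree
whose nodes are subclones with copy numbers, and somatic hypermutation is
imposed edge by edge with a 5-mer context-dependent targeting model
(substitutions only, no indels).  Everything is parametric, so no external
germline database or experimental download is required; a loader hook
(:func:`ancestors_from_repertoire`) accepts an existing partitioned
repertoire as seed material instead.

All randomness flows from a single seed through named streams (per clone,
per edge), so adding clones does not perturb earlier clones' draws and an
identical :class:`SimulationConfig` yields byte-identical AIRR output.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .airr_io import Rearrangement, Repertoire
from .clonal_inference import ClonalPartition

NUCLEOTIDES = "ACGT"

_W = set("AT")
_R = set("AG")
_S = set("CG")
_Y = set("CT")


class ConfigError(ValueError):
    """Inconsistent or unsatisfiable simulation configuration."""


def _stream(seed: int, *tags) -> np.random.Generator:
    """Named random stream: a Generator keyed by (seed, tags).

    Uses CRC32 of the tag repr so streams are stable across processes and
    independent of PYTHONHASHSEED.
    """
    key = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        key.append(zlib.crc32(repr(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# Targeting model
# ---------------------------------------------------------------------------


@dataclass
class TargetingModel:
    """5-mer mutability and substitution preferences for SHM.

    ``mutability`` maps each 5-mer (central base = mutating site) to a
    non-negative relative rate; ``substitution`` maps a 5-mer to a probability
    distribution over the three alternative central bases.  The default model
    is flat with classical AID hotspots (WRC targeting the C, GYW targeting
    the G) at 5x and coldspots (SYC / GRS) at 0.3x; a full empirical 5-mer
    table can be loaded from TSV instead.
    """

    mutability: dict[str, float]
    substitution: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        rates = np.array(list(self.mutability.values()), dtype=float)
        if (rates < 0).any():
            raise ValueError("mutability rates must be non-negative")
        self._mean_rate = float(rates.mean()) if len(rates) else 1.0

    def normalized_mutability(self, fivemer: str) -> float:
        """Relative rate scaled so the average over all 5-mers is 1."""
        return self.mutability.get(fivemer, 1.0) / self._mean_rate

    def substitution_row(self, fivemer: str) -> dict[str, float]:
        row = self.substitution.get(fivemer)
        if row is None:
            center = fivemer[2]
            alts = [b for b in NUCLEOTIDES if b != center]
            row = {b: 1.0 / 3.0 for b in alts}
        return row

    @classmethod
    def flat(cls) -> "TargetingModel":
        mut = {"".join(km): 1.0 for km in itertools.product(NUCLEOTIDES, repeat=5)}
        return cls(mutability=mut, substitution={})

    @classmethod
    def with_hotspots(cls, hot: float = 5.0, cold: float = 0.3) -> "TargetingModel":
        mut = {}
        for km in itertools.product(NUCLEOTIDES, repeat=5):
            k = "".join(km)
            rate = 1.0
            # WRC: mutating C preceded by W,R; GYW is its reverse-complement face.
            if k[2] == "C" and k[0] in _W and k[1] in _R:
                rate = hot
            elif k[2] == "G" and k[3] in _Y and k[4] in _W:
                rate = hot
            elif k[2] == "C" and k[0] in _S and k[1] in _Y:
                rate = cold
            elif k[2] == "G" and k[3] in _R and k[4] in _S:
                rate = cold
            mut[k] = rate
        return cls(mutability=mut, substitution={})

    @classmethod
    def from_tsv(cls, mutability_path: str | Path, substitution_path: Optional[str | Path] = None) -> "TargetingModel":
        """Load a 5-mer model: 2-column TSV (5-mer, rate) and optionally a
        4-column TSV (5-mer, then probabilities for the 3 alternative bases in
        alphabetical order)."""
        mut: dict[str, float] = {}
        for line in Path(mutability_path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            k, v = line.split("\t")[:2]
            mut[k.strip().upper()] = float(v)
        sub: dict[str, dict[str, float]] = {}
        if substitution_path is not None:
            for line in Path(substitution_path).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                k = parts[0].strip().upper()
                alts = [b for b in NUCLEOTIDES if b != k[2]]
                probs = [float(x) for x in parts[1:4]]
                total = sum(probs)
                sub[k] = {b: p / total for b, p in zip(alts, probs)}
        return cls(mutability=mut, substitution=sub)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    ``clone_size_distribution`` is a dict: ``{"type": "powerlaw", "exponent": a}``,
    ``{"type": "geometric", "p": p}`` or ``{"type": "fixed", "k": k}``; sizes
    count rearrangement records per clone.  ``per_sample_mixing`` maps a clone
    index to per-sample proportions, overriding ``default_mixing`` for that
    clone; proportions are realized deterministically by largest-remainder
    allocation so a stated split is exact.
    """

    seed: int = 0
    n_clones: int = 100
    clone_size_distribution: dict = field(default_factory=lambda: {"type": "geometric", "p": 0.2})
    singleton_fraction: float = 0.3
    n_v_segments: int = 20
    n_j_segments: int = 6
    v_segment_length: int = 294
    j_segment_length: int = 48
    junction_insertion_length_distribution: dict = field(default_factory=lambda: {"type": "poisson", "lam": 39})
    mutation_rate_per_site: float = 0.005
    max_tree_depth: int = 10
    copy_number_p: float = 0.5
    emit_light_chain: bool = False
    n_lc_v_segments: int = 10
    n_lc_j_segments: int = 4
    lc_discordance_rate: float = 0.0
    n_samples: int = 1
    default_mixing: Optional[Sequence[float]] = None
    per_sample_mixing: Optional[dict[int, Sequence[float]]] = None
    ensure_distinct_keys: bool = True
    collision_rate: float = 0.0
    targeting_model: Optional[TargetingModel] = None
    sample_prefix: str = "S"

    def validate(self) -> None:
        if self.n_clones < 1 or self.n_v_segments < 1 or self.n_j_segments < 1:
            raise ConfigError("n_clones, n_v_segments, n_j_segments must be >= 1")
        if not (0.0 <= self.singleton_fraction <= 1.0):
            raise ConfigError("singleton_fraction must be in [0, 1]")
        if not (0.0 <= self.mutation_rate_per_site <= 1.0):
            raise ConfigError("mutation_rate_per_site must be in [0, 1]")
        if self.v_segment_length < 10 or self.j_segment_length < 6:
            raise ConfigError("segment lengths too short to carry anchors and divergence")
        for mix in self._all_mixings():
            if len(mix) != self.n_samples:
                raise ConfigError("mixing proportions must have one entry per sample")
            if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigError("mixing proportions must be non-negative and sum to 1")

    def _all_mixings(self):
        if self.default_mixing is not None:
            yield self.default_mixing
        if self.per_sample_mixing:
            yield from self.per_sample_mixing.values()

    def mixing_for(self, clone_index: int) -> Sequence[float]:
        if self.per_sample_mixing and clone_index in self.per_sample_mixing:
            return self.per_sample_mixing[clone_index]
        if self.default_mixing is not None:
            return self.default_mixing
        return [1.0] + [0.0] * (self.n_samples - 1)

    def model(self) -> TargetingModel:
        return self.targeting_model if self.targeting_model is not None else TargetingModel.with_hotspots()


# ---------------------------------------------------------------------------
# Germline catalogue and naive rearrangement
# ---------------------------------------------------------------------------


@dataclass
class GermlineCatalogue:
    v_segments: dict[str, str]
    j_segments: dict[str, str]


def _random_divergent_segments(rng: np.random.Generator, n: int, length: int, prefix: str,
                               suffix: str = "", prefix_nt: str = "", min_dist: int = 3) -> dict[str, str]:
    """Random segments pairwise Hamming >= min_dist, with fixed anchor ends."""
    core_len = length - len(suffix) - len(prefix_nt)
    if core_len < min_dist:
        raise ConfigError("segment length too short to enforce divergence")
    segments: dict[str, str] = {}
    chosen: list[str] = []
    for i in range(1, n + 1):
        for _attempt in range(1000):
            core = "".join(rng.choice(list(NUCLEOTIDES), size=core_len))
            if all(sum(a != b for a, b in zip(core, c)) >= min_dist for c in chosen):
                chosen.append(core)
                segments[f"{prefix}-{i}"] = prefix_nt + core + suffix
                break
        else:
            raise ConfigError("could not generate divergent segments; increase segment length")
    return segments


def generate_germline_set(config: SimulationConfig, seed: Optional[int] = None) -> GermlineCatalogue:
    """Synthetic germline V and J segment catalogue.

    V segments end in the Cys104 anchor codon TGT; J segments start with the
    Trp118 anchor TGG.  Any two V (or two J) segments differ at >= 3 positions
    so gene-level assignment and VJ partitioning are well defined.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng_v = _stream(seed, "germline", "V")
    rng_j = _stream(seed, "germline", "J")
    v = _random_divergent_segments(rng_v, config.n_v_segments, config.v_segment_length,
                                   "SIMV", suffix="TGT")
    j = _random_divergent_segments(rng_j, config.n_j_segments, config.j_segment_length,
                                   "SIMJ", prefix_nt="TGG")
    return GermlineCatalogue(v_segments=v, j_segments=j)


def _draw_insertion_length(dist: dict, rng: np.random.Generator) -> int:
    kind = dist.get("type", "poisson")
    if kind == "poisson":
        n = int(rng.poisson(dist.get("lam", 39)))
    elif kind == "uniform":
        n = int(rng.integers(dist.get("low", 0), dist.get("high", 48) + 1))
    elif kind == "fixed":
        n = int(dist.get("k", 39))
    else:
        raise ConfigError(f"unknown insertion length distribution: {kind!r}")
    # pad to a multiple of 3 so the junction (6 nt of anchors + insert) stays in frame
    return n + (-n) % 3


@dataclass
class NaiveRearrangement:
    """A clone's unmutated common ancestor."""

    sequence: str
    v_call: str
    j_call: str
    v_length: int          # full V segment length incl. the Cys anchor codon
    insert_length: int
    j_length: int

    @property
    def junction_start(self) -> int:
        return self.v_length - 3

    @property
    def junction_end(self) -> int:
        return self.v_length + self.insert_length + 3

    def junction_of(self, sequence: str) -> str:
        return sequence[self.junction_start:self.junction_end]


def simulate_naive_rearrangement(catalogue: GermlineCatalogue, config: SimulationConfig,
                                 seed: Optional[int] = None, *,
                                 rng: Optional[np.random.Generator] = None) -> NaiveRearrangement:
    """VDJ recombination: V segment + junctional insertion + J segment.

    V/J usage is uniform over the catalogue; the junction runs from the Cys
    anchor at the V end to the Trp anchor at the J start and its length is a
    multiple of 3 (insertions frame-padded).
    """
    if not catalogue.v_segments or not catalogue.j_segments:
        raise ConfigError("empty germline catalogue")
    if rng is None:
        rng = _stream(config.seed if seed is None else seed, "naive")
    v_name = list(catalogue.v_segments)[int(rng.integers(len(catalogue.v_segments)))]
    j_name = list(catalogue.j_segments)[int(rng.integers(len(catalogue.j_segments)))]
    v_seq = catalogue.v_segments[v_name]
    j_seq = catalogue.j_segments[j_name]
    ins_len = _draw_insertion_length(config.junction_insertion_length_distribution, rng)
    insert = "".join(rng.choice(list(NUCLEOTIDES), size=ins_len))
    return NaiveRearrangement(
        sequence=v_seq + insert + j_seq,
        v_call=v_name,
        j_call=j_name,
        v_length=len(v_seq),
        insert_length=ins_len,
        j_length=len(j_seq),
    )


# ---------------------------------------------------------------------------
# Lineage tree and hypermutation
# ---------------------------------------------------------------------------


@dataclass
class LineageTree:
    """Rooted subclone tree; node 0 is the unmutated ancestor."""

    parents: list[Optional[int]]             # parents[0] is None
    copy_number: list[int] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(p, c) for c, p in enumerate(self.parents) if p is not None]

    def depth(self, node: int) -> int:
        d = 0
        while self.parents[node] is not None:
            node = self.parents[node]
            d += 1
        return d


def sample_tree_topology(n_nodes: int, seed: Optional[int] = None, *,
                         max_depth: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None) -> LineageTree:
    """Random recursive tree over ``n_nodes`` subclones.

    Node i attaches to a uniformly random earlier node (optionally restricted
    to nodes above ``max_depth``); node 0 is the root placeholder for the
    unmutated ancestor.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if rng is None:
        rng = _stream(0 if seed is None else seed, "tree")
    parents: list[Optional[int]] = [None]
    depths = [0]
    for _i in range(1, n_nodes):
        candidates = list(range(len(parents)))
        if max_depth is not None:
            candidates = [c for c in candidates if depths[c] < max_depth] or [0]
        p = int(candidates[int(rng.integers(len(candidates)))])
        parents.append(p)
        depths.append(depths[p] + 1)
    return LineageTree(parents=parents)


def mutate_lineage(ancestor: str, tree: LineageTree, model: TargetingModel, rate: float,
                   seed: Optional[int] = None, *,
                   rng: Optional[np.random.Generator] = None) -> dict[int, str]:
    """Impose SHM along the tree: node -> sequence, root unchanged.

    On each edge every site mutates independently with probability
    ``rate x normalized 5-mer mutability`` of its context in the parent
    sequence; the substitution is drawn from the model's row for that 5-mer.
    Substitutions only, so all node sequences keep the ancestor's length.
    """
    if not ancestor:
        raise ValueError("empty ancestor sequence")
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rng is None:
        rng = _stream(0 if seed is None else seed, "mutate")
    sequences: dict[int, str] = {0: ancestor}
    # children in index order guarantees parents are processed first
    for child, parent in enumerate(tree.parents):
        if parent is None:
            continue
        parent_seq = sequences[parent]
        padded = "NN" + parent_seq + "NN"
        probs = np.array(
            [min(1.0, rate * model.normalized_mutability(padded[i:i + 5]))
             for i in range(len(parent_seq))]
        )
        hits = np.flatnonzero(rng.random(len(parent_seq)) < probs)
        seq = list(parent_seq)
        for i in hits:
            ctx = padded[i:i + 5]
            row = model.substitution_row(ctx)
            alts = sorted(row)
            p = np.array([row[a] for a in alts])
            seq[i] = alts[int(rng.choice(len(alts), p=p / p.sum()))]
        sequences[child] = "".join(seq)
    return sequences


# ---------------------------------------------------------------------------
# Whole-repertoire simulation
# ---------------------------------------------------------------------------


def _draw_clone_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    dist = config.clone_size_distribution
    kind = dist.get("type", "geometric")
    sizes = []
    for _ in range(config.n_clones):
        if kind == "geometric":
            s = int(rng.geometric(dist.get("p", 0.2)))
        elif kind == "powerlaw":
            s = int(np.floor(rng.pareto(dist.get("exponent", 2.0)) + 1))
        elif kind == "fixed":
            s = int(dist.get("k", 1))
        else:
            raise ConfigError(f"unknown clone size distribution: {kind!r}")
        sizes.append(max(1, s))
    # force the configured fraction of clones to be singletons (deterministic choice)
    n_singletons = int(round(config.singleton_fraction * config.n_clones))
    order = rng.permutation(config.n_clones)
    for idx in order[:n_singletons]:
        sizes[idx] = 1
    return sizes


def _largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Deterministic integer allocation of ``total`` by proportions."""
    raw = [p * total for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    remainder = total - sum(counts)
    frac_order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in frac_order[:remainder]:
        counts[i] += 1
    return counts


def _node_copy_numbers(size: int, p: float, rng: np.random.Generator) -> list[int]:
    """Split ``size`` records over subclone nodes with geometric copy numbers."""
    counts: list[int] = []
    remaining = size
    while remaining > 0:
        c = min(int(rng.geometric(p)), remaining)
        counts.append(c)
        remaining -= c
    return counts


def ancestors_from_repertoire(rep: Repertoire, fraction: float = 0.1,
                              seed: int = 0) -> list[NaiveRearrangement]:
    """Loader hook: derive clone ancestors from an existing partitioned
    repertoire (one representative per sampled true clone), for reproducing a
    data-seeded simulation when real annotated data are available."""
    by_clone: dict[str, Rearrangement] = {}
    for r in rep.records:
        if r.clone_id_true and r.clone_id_true not in by_clone and r.sequence and r.junction:
            by_clone[r.clone_id_true] = r
    labels = sorted(by_clone)
    rng = _stream(seed, "reseed")
    n = max(1, int(round(fraction * len(labels))))
    picked = [labels[i] for i in sorted(rng.choice(len(labels), size=n, replace=False))]
    out = []
    for lab in picked:
        r = by_clone[lab]
        v_len = r.sequence.find(r.junction) + 3
        out.append(NaiveRearrangement(
            sequence=r.sequence, v_call=r.v_call, j_call=r.j_call,
            v_length=v_len, insert_length=len(r.junction) - 6,
            j_length=len(r.sequence) - (v_len - 3) - len(r.junction) + 3,
        ))
    return out


def simulate_repertoire(config: SimulationConfig) -> tuple[Repertoire, ClonalPartition]:
    """Generate a full annotated repertoire plus its true clonal partition.

    Per clone: a naive ancestor (distinct (V, J, junction length) triple
    unless ``collision_rate`` allows a collision), a random lineage tree with
    geometric node copy numbers, SHM along the edges, and deterministic
    allocation of members to samples.  Every record carries v/j mutation
    counts relative to its germline segments (junction excluded) and exactly
    one ``clone_id_true``.
    """
    config.validate()
    catalogue = generate_germline_set(config)
    model = config.model()
    sizes = _draw_clone_sizes(config, _stream(config.seed, "sizes"))

    used_keys: set[tuple[str, str, int]] = set()
    records: list[Rearrangement] = []
    assignment: dict[str, str] = {}

    lc_v_names = [f"SIMLV-{i}" for i in range(1, config.n_lc_v_segments + 1)]
    lc_j_names = [f"SIMLJ-{i}" for i in range(1, config.n_lc_j_segments + 1)]

    for ci in range(config.n_clones):
        rng_anc = _stream(config.seed, "clone", ci, "ancestor")
        ancestor = None
        for _attempt in range(200):
            cand = simulate_naive_rearrangement(catalogue, config, rng=rng_anc)
            key = (cand.v_call, cand.j_call, cand.junction_end - cand.junction_start)
            allow_collision = (not config.ensure_distinct_keys) or (
                config.collision_rate > 0 and rng_anc.random() < config.collision_rate
            )
            if key not in used_keys or allow_collision:
                used_keys.add(key)
                ancestor = cand
                break
        if ancestor is None:
            raise ConfigError(
                "could not draw a clone ancestor with a distinct (V, J, junction "
                "length) key; increase segment counts or junction length spread"
            )

        size = sizes[ci]
        copies = _node_copy_numbers(size, config.copy_number_p, _stream(config.seed, "clone", ci, "copies"))
        tree = sample_tree_topology(len(copies), max_depth=config.max_tree_depth,
                                    rng=_stream(config.seed, "clone", ci, "tree"))
        tree.copy_number = copies
        node_seqs = mutate_lineage(ancestor.sequence, tree, model, config.mutation_rate_per_site,
                                   rng=_stream(config.seed, "clone", ci, "shm"))

        rng_lc = _stream(config.seed, "clone", ci, "lc")
        clone_lc = (lc_v_names[int(rng_lc.integers(len(lc_v_names)))],
                    lc_j_names[int(rng_lc.integers(len(lc_j_names)))])

        # expand subclones to records, then split members over samples
        member_seqs: list[str] = []
        for node in range(tree.n_nodes):
            member_seqs.extend([node_seqs[node]] * copies[node])
        sample_counts = _largest_remainder(config.mixing_for(ci), size)
        sample_of: list[int] = []
        for si, cnt in enumerate(sample_counts):
            sample_of.extend([si] * cnt)

        clone_label = f"C{ci:04d}"
        v_germ = catalogue.v_segments[ancestor.v_call]
        j_germ = catalogue.j_segments[ancestor.j_call]
        v_core_len = ancestor.v_length - 3          # V outside the junction
        j_core_len = ancestor.j_length - 3          # J outside the junction
        for mi, seq in enumerate(member_seqs):
            junction = ancestor.junction_of(seq)
            junction_aa = str(Seq(junction).translate())
            v_mut = sum(a != b for a, b in zip(seq[:v_core_len], v_germ[:v_core_len]))
            j_mut = sum(a != b for a, b in zip(seq[ancestor.junction_end:], j_germ[3:]))
            sid = f"{clone_label}.{mi:03d}"
            lc_v, lc_j = clone_lc
            if config.emit_light_chain and config.lc_discordance_rate > 0:
                if rng_lc.random() < config.lc_discordance_rate:
                    lc_v = lc_v_names[int(rng_lc.integers(len(lc_v_names)))]
                    lc_j = lc_j_names[int(rng_lc.integers(len(lc_j_names)))]
            records.append(Rearrangement(
                sequence_id=sid,
                sample_id=f"{config.sample_prefix}{sample_of[mi] + 1}",
                sequence=seq,
                v_call=ancestor.v_call,
                j_call=ancestor.j_call,
                junction=junction,
                junction_aa=junction_aa,
                v_mutation_count=v_mut,
                v_alignment_length=v_core_len,
                j_mutation_count=j_mut,
                j_alignment_length=j_core_len,
                lc_v_call=lc_v if config.emit_light_chain else None,
                lc_j_call=lc_j if config.emit_light_chain else None,
                clone_id_true=clone_label,
            ))
            assignment[sid] = clone_label

    rep = Repertoire(records=records, provenance=f"cfbench-sim(seed={config.seed})")
    rep.validate()
    truth = ClonalPartition(approach_id="TRUE", assignment=assignment,
                            params={"seed": config.seed, "n_clones": config.n_clones})
    return rep, truth
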