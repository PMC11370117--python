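"""Repertoire outcome measures over a clonal partition.

CF count, singletons, mean/max CF size, dominant clones, D50, and Hill-based
diversity (Shannon and Gini-Simpson), plus the V/J mutation load.  The Hill
diversity of order alpha of a clonal frequency distribution f is

    D_alpha(f) = (sum_i f_i ** alpha) ** (1 / (1 - alpha)),

with f_i the fraction of repertoire records in CF i.  Its alpha -> 1 limit
gives exp(Shannon); alpha = 2 gives the inverse Simpson index, and the
Gini-Simpson index is 1 - 1/D_2 = 1 - sum f_i**2, the probability that two
randomly drawn sequences belong to different CFs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .airr_io import Repertoire
from .clonal_inference import ClonalPartition

#: A clone is dominant when its record frequency is strictly above 0.5%.
DOMINANT_FREQUENCY = 0.005


@dataclass
class ClonalFrequencies:
    """Clone sizes and the induced frequency distribution.

    By default sizes count rearrangement records (rows); pass
    ``distinct_sequences=True`` to :meth:`from_partition` to count distinct
    nucleotide sequences instead.
    """

    sizes: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0 or not self.sizes:
            raise ValueError("empty partition has no frequency distribution")
        if sum(self.sizes.values()) != self.total:
            raise ValueError("clone sizes must sum to total")

    @classmethod
    def from_partition(cls, partition: ClonalPartition,
                       rep: Repertoire | None = None,
                       distinct_sequences: bool = False) -> "ClonalFrequencies":
        if distinct_sequences:
            if rep is None:
                raise ValueError("distinct_sequences requires the repertoire")
            seq_of = {r.sequence_id: r.sequence for r in rep.records}
            per_clone: dict[str, set] = {}
            for sid, lab in partition.assignment.items():
                per_clone.setdefault(lab, set()).add(seq_of[sid])
            sizes = {lab: len(s) for lab, s in per_clone.items()}
        else:
            sizes = partition.sizes()
        return cls(sizes=sizes, total=sum(sizes.values()))

    @property
    def frequencies(self) -> np.ndarray:
        return np.array(list(self.sizes.values()), dtype=float) / self.total


@dataclass
class OutcomeMeasures:
    n_cf: int
    n_singletons: int
    mean_size: float
    max_size: int
    n_dominant: int
    d50: int
    shannon: float
    gini_simpson: float

    def as_dict(self) -> dict:
        return {
            "n_cf": self.n_cf, "n_singletons": self.n_singletons,
            "mean_size": self.mean_size, "max_size": self.max_size,
            "n_dominant": self.n_dominant, "d50": self.d50,
            "shannon": self.shannon, "gini_simpson": self.gini_simpson,
        }


def hill_diversity(f: ClonalFrequencies, alpha: float) -> float:
    """Hill number of order alpha (alpha >= 0, alpha != 1)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 1:
        raise ValueError("alpha = 1 is the Shannon limit; use shannon_index")
    freqs = f.frequencies
    return float(np.sum(freqs ** alpha) ** (1.0 / (1.0 - alpha)))


def shannon_index(f: ClonalFrequencies, base: str = "ln") -> float:
    """Shannon entropy of the clonal frequencies, -sum f_i log f_i.

    Natural-log units by default (matching ln-based Hill diversity, with
    maximum ln(n_cf) at uniform frequencies); ``base='log2'`` reports bits.
    """
    freqs = f.frequencies
    h = float(-np.sum(freqs * np.log(freqs)))
    h = max(h, 0.0)
    return h / math.log(2) if base == "log2" else h


def gini_simpson(f: ClonalFrequencies) -> float:
    """1 - sum f_i^2: probability two random records are in different CFs."""
    freqs = f.frequencies
    return float(1.0 - np.sum(freqs ** 2))


def dominant_clones(f: ClonalFrequencies, freq_threshold: float = DOMINANT_FREQUENCY) -> set[str]:
    """Clone labels with frequency strictly above the threshold (default 0.5%)."""
    if not (0.0 < freq_threshold < 1.0):
        raise ValueError("freq_threshold must lie in (0, 1)")
    return {lab for lab, s in f.sizes.items() if s / f.total > freq_threshold}


def d50(f: ClonalFrequencies) -> int:
    """Smallest number of (largest) CFs covering >= 50% of records.

    Size ties are broken by label order, which cannot change the result.
    """
    sizes = sorted(f.sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    cum = 0
    for k, (_lab, s) in enumerate(sizes, start=1):
        cum += s
        if 2 * cum >= f.total:
            return k
    return len(sizes)


def count_singletons(partition: ClonalPartition) -> int:
    """Number of CFs consisting of exactly one sequence."""
    return sum(1 for s in partition.sizes().values() if s == 1)


def mutation_load(rep: Repertoire) -> float:
    """Mean percentage of mutated V/J nucleotides over all records.

    Per record: 100 x (v_mutation_count + j_mutation_count) /
    (v_alignment_length + j_alignment_length).  Junction mutations are
    excluded by construction — the junction has no reliable germline
    reference.  Records missing counts are skipped with a warning.
    """
    loads = []
    skipped = 0
    for r in rep.records:
        if None in (r.v_mutation_count, r.j_mutation_count,
                    r.v_alignment_length, r.j_alignment_length):
            skipped += 1
            continue
        denom = r.v_alignment_length + r.j_alignment_length
        loads.append(100.0 * (r.v_mutation_count + r.j_mutation_count) / denom)
    if skipped:
        warnings.warn(f"mutation_load: skipped {skipped} record(s) without mutation counts")
    if not loads:
        raise ValueError("no record carries mutation counts and alignment lengths")
    return float(np.mean(loads))


def summarize(partition: ClonalPartition, rep: Repertoire | None = None) -> OutcomeMeasures:
    """All outcome measures computed from one ClonalFrequencies object."""
    f = ClonalFrequencies.from_partition(partition)
    return OutcomeMeasures(
        n_cf=len(f.sizes),
        n_singletons=count_singletons(partition),
        mean_size=f.total / len(f.sizes),
        max_size=max(f.sizes.values()),
        n_dominant=len(dominant_clones(f)),
        d50=d50(f),
        shannon=shannon_index(f),
        gini_simpson=gini_simpson(f),
    )
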