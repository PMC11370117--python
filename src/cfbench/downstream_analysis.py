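"""Downstream analyses: shared clonal families and light-chain concordance.

Shared CFs: after merging the samples of a dataset (keeping each sequence's
sample annotation) and partitioning the merged repertoire, a CF is shared
when it contains sequences from two or more samples.  Similarity thresholds
are deliberately NOT loosened for shared-CF detection.

Light-chain concordance: for repertoires with paired light chains, a
heavy-chain CF is concordant when all its members pair to the same
light-chain V/J genes (gene level, allele-stripped); singletons are
concordant by definition.  The concordance fraction measures how much
incorporating the light chain would split heavy-chain-defined CFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .airr_io import Rearrangement, Repertoire, strip_allele
from .clonal_inference import ClonalPartition
from .repertoire_metrics import DOMINANT_FREQUENCY


@dataclass
class SharedCloneReport:
    n_cf_total: int
    n_shared: int
    shared_fraction: float
    per_pair_counts: dict[tuple[str, str], int]
    n_shared_dominant: int


@dataclass
class ConcordanceReport:
    n_cf: int                      # evaluable CFs (denominator)
    n_concordant: int
    concordance: float
    n_unevaluable: int = 0
    unevaluable: list[str] = field(default_factory=list)


def merge_samples(reps: list[Repertoire]) -> Repertoire:
    """Concatenate repertoires, keeping per-record sample annotation.

    Sample ids must be pairwise disjoint across inputs; sequence-id
    collisions across inputs are resolved by prefixing with the sample id,
    never by dropping records.
    """
    seen_samples: set[str] = set()
    for rep in reps:
        overlap = seen_samples & rep.sample_ids
        if overlap:
            raise ValueError(f"colliding sample_ids across repertoires: {sorted(overlap)}")
        seen_samples |= rep.sample_ids
    seen_ids: set[str] = set()
    needs_prefix = False
    for rep in reps:
        for r in rep.records:
            if r.sequence_id in seen_ids:
                needs_prefix = True
            seen_ids.add(r.sequence_id)
    records: list[Rearrangement] = []
    for rep in reps:
        for r in rep.records:
            if needs_prefix:
                r = Rearrangement(**{**r.__dict__,
                                     "sequence_id": f"{r.sample_id}:{r.sequence_id}"})
            records.append(r)
    merged = Repertoire(records=records,
                        provenance="merged(" + ",".join(sorted(seen_samples)) + ")")
    merged.validate()
    return merged


def shared_clones(merged_partition: ClonalPartition, merged_rep: Repertoire,
                  dominant_threshold: float = DOMINANT_FREQUENCY) -> SharedCloneReport:
    """Count CFs whose members span two or more samples.

    Per-pair counts cover, for each unordered sample pair, the CFs containing
    both samples.  Shared-dominant CFs additionally exceed the dominant
    frequency threshold on the merged repertoire.
    """
    if len(merged_rep.sample_ids) < 2:
        raise ValueError("shared-clone analysis requires >= 2 samples in the merged repertoire")
    sample_of = {r.sequence_id: r.sample_id for r in merged_rep.records}
    members = merged_partition.clone_members()
    total_records = len(merged_partition.assignment)
    per_pair: dict[tuple[str, str], int] = {}
    n_shared = 0
    n_shared_dominant = 0
    for _label, sids in members.items():
        samples = sorted({sample_of[s] for s in sids})
        if len(samples) < 2:
            continue
        n_shared += 1
        if len(sids) / total_records > dominant_threshold:
            n_shared_dominant += 1
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                pair = (samples[i], samples[j])
                per_pair[pair] = per_pair.get(pair, 0) + 1
    n_total = len(members)
    return SharedCloneReport(
        n_cf_total=n_total,
        n_shared=n_shared,
        shared_fraction=n_shared / n_total,
        per_pair_counts=per_pair,
        n_shared_dominant=n_shared_dominant,
    )


def lc_concordance(rep: Repertoire, partition: ClonalPartition) -> ConcordanceReport:
    """Fraction of CFs whose members all pair to the same light-chain V/J.

    A CF containing any record without light-chain calls is unevaluable and
    excluded from the denominator (reported, not counted discordant).
    Singletons are concordant by definition.
    """
    lc_of: dict[str, tuple[str, str] | None] = {}
    for r in rep.records:
        if r.lc_v_call and r.lc_j_call:
            lc_of[r.sequence_id] = (strip_allele(r.lc_v_call), strip_allele(r.lc_j_call))
        else:
            lc_of[r.sequence_id] = None
    n_concordant = 0
    n_evaluable = 0
    unevaluable: list[str] = []
    for label, sids in partition.clone_members().items():
        pairs = {lc_of.get(s) for s in sids}
        if None in pairs:
            unevaluable.append(label)
            continue
        n_evaluable += 1
        if len(pairs) == 1:
            n_concordant += 1
    if n_evaluable == 0:
        raise ValueError("no CF with complete light-chain annotation")
    return ConcordanceReport(
        n_cf=n_evaluable,
        n_concordant=n_concordant,
        concordance=n_concordant / n_evaluable,
        n_unevaluable=len(unevaluable),
        unevaluable=unevaluable,
    )
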