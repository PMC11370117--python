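"""Clonal-family inference approaches.

Seven ways of grouping BCR heavy-chain sequences into clonal families (CFs):

====  =======================================================================
A1    identical junction amino-acid sequence, no VJ partitioning
A2    identical V gene + J gene + junction AA ("subclone" definition)
A3    VJ partition, junction AA Hamming distance <= 1 (absolute threshold)
A4    VJ partition, junction AA normalized Hamming <= 0.15 (relative)
A5    VJ partition, junction NT normalized Hamming <= 0.15 (relative)
A6    VJ partition, junction NT, per-sample threshold from the bimodal
      distance-to-nearest distribution (KDE valley)
A10   alignment-free: cosine distance on tf-idf weighted k-mer vectors of the
      full sequence, threshold calibrated on a negation repertoire from a
      different individual
====  =======================================================================

Threshold approaches build, per VJ/junction-length group, a fully connected
graph whose edges are sequence pairs at distance <= threshold, and take
connected components (single linkage) as CFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.metrics.pairwise import cosine_distances

from .airr_io import Rearrangement, Repertoire, strip_allele

APPROACH_IDS = ("A1", "A2", "A3", "A4", "A5", "A6", "A10")

#: A6 falls back to this relative NT threshold when the distance-to-nearest
#: distribution is not bimodal.
FALLBACK_THRESHOLD = 0.15

DENSITY_GRID_SIZE = 512


class InferenceError(RuntimeError):
    """Input unusable for the requested approach."""


@dataclass
class ClonalPartition:
    """Inferred (or true) assignment of sequence ids to CF labels.

    Labels are opaque; only the induced set partition carries meaning.
    ``params`` records the resolved parameters that produced the partition.
    """

    approach_id: str
    assignment: dict[str, str]
    params: dict = field(default_factory=dict)

    def clone_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, label in self.assignment.items():
            out.setdefault(label, []).append(sid)
        return out

    def sizes(self) -> dict[str, int]:
        return {label: len(m) for label, m in self.clone_members().items()}

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass(frozen=True)
class PartitionKey:
    """VJ-partitioning key: gene-level V and J names plus junction length."""

    v_gene: str
    j_gene: str
    junction_length: int


@dataclass
class ThresholdFit:
    """Result of distance-to-nearest threshold detection (approach A6)."""

    nearest_distances: list[float]
    bandwidth: float
    density_grid: tuple[np.ndarray, np.ndarray]
    threshold: float
    bimodal: bool


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def hamming(a: str, b: str) -> int:
    """Count of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def normalized_hamming(a: str, b: str) -> float:
    """Hamming distance divided by length; in [0, 1]."""
    if len(a) == 0:
        raise ValueError("zero-length strings")
    return hamming(a, b) / len(a)


def _pairwise_hamming_matrix(strings: Sequence[str]) -> np.ndarray:
    """Dense pairwise Hamming distances for equal-length strings."""
    arr = np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(strings), len(strings[0]))
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


# ---------------------------------------------------------------------------
# VJ partitioning and threshold clustering
# ---------------------------------------------------------------------------


def _junction_of(rec: Rearrangement, alphabet: str) -> Optional[str]:
    if alphabet == "AA":
        return rec.junction_aa or None
    if alphabet == "NT":
        return rec.junction or None
    raise ValueError(f"alphabet must be 'NT' or 'AA', got {alphabet!r}")


def partition_by_vj(rep: Repertoire, alphabet: str = "NT") -> dict[PartitionKey, list[Rearrangement]]:
    """Exhaustive disjoint grouping by (V gene, J gene, junction length).

    Gene names are allele-stripped; junction length is measured in the chosen
    alphabet.  Records missing a required field are silently excluded here;
    callers that must account for them track skipped ids themselves.
    """
    groups: dict[PartitionKey, list[Rearrangement]] = {}
    for rec in rep.records:
        jx = _junction_of(rec, alphabet)
        if jx is None or not rec.v_call or not rec.j_call:
            continue
        key = PartitionKey(strip_allele(rec.v_call), strip_allele(rec.j_call), len(jx))
        groups.setdefault(key, []).append(rec)
    return groups


def cluster_by_threshold(records: Sequence[Rearrangement],
                         distance: Callable[[str, str], float],
                         threshold: float,
                         alphabet: str = "NT") -> list[list[Rearrangement]]:
    """Single-linkage clusters: connected components of the graph whose edges
    are record pairs with junction distance <= threshold.

    Records are assumed to share a PartitionKey (equal-length junctions), so
    Hamming distances are defined for every pair.
    """
    n = len(records)
    if n == 0:
        return []
    if n == 1:
        return [[records[0]]]
    strings = [_junction_of(r, alphabet) for r in records]
    if distance in (hamming, normalized_hamming):
        dm = _pairwise_hamming_matrix(strings).astype(float)
        if distance is normalized_hamming:
            dm /= len(strings[0])
    else:
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = distance(strings[i], strings[j])
    adj = csr_matrix(dm <= threshold)
    _n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[Rearrangement]] = {}
    for rec, lab in zip(records, labels):
        clusters.setdefault(int(lab), []).append(rec)
    return [clusters[k] for k in sorted(clusters)]


def _aa_ready(rep: Repertoire) -> tuple[list[Rearrangement], list[str]]:
    """Records usable by AA-based approaches, plus skipped ids.

    A junction whose nucleotide length is not a multiple of 3 has no defined
    translation; such records are excluded from AA approaches.
    """
    usable, skipped = [], []
    for r in rep.records:
        if r.junction_aa and (not r.junction or len(r.junction) % 3 == 0):
            usable.append(r)
        else:
            skipped.append(r.sequence_id)
    return usable, skipped


# ---------------------------------------------------------------------------
# Exact-match approaches
# ---------------------------------------------------------------------------


def _partition_from_groups(approach_id: str, groups: Sequence[Sequence[Rearrangement]],
                           params: dict) -> ClonalPartition:
    assignment = {}
    for gi, group in enumerate(groups):
        label = f"{approach_id}_{gi}"
        for rec in group:
            assignment[rec.sequence_id] = label
    return ClonalPartition(approach_id=approach_id, assignment=assignment, params=params)


def infer_A1(rep: Repertoire) -> ClonalPartition:
    """One CF per distinct junction AA sequence; no VJ partitioning."""
    usable, skipped = _aa_ready(rep)
    groups: dict[str, list[Rearrangement]] = {}
    for rec in usable:
        groups.setdefault(rec.junction_aa, []).append(rec)
    return _partition_from_groups("A1", [groups[k] for k in sorted(groups)],
                                  {"skipped_ids": skipped})


def infer_A2(rep: Repertoire) -> ClonalPartition:
    """Subclones: exact match on (V gene, J gene, junction AA)."""
    usable, skipped = _aa_ready(rep)
    groups: dict[tuple, list[Rearrangement]] = {}
    for rec in usable:
        key = (strip_allele(rec.v_call), strip_allele(rec.j_call), rec.junction_aa)
        groups.setdefault(key, []).append(rec)
    return _partition_from_groups("A2", [groups[k] for k in sorted(groups)],
                                  {"skipped_ids": skipped})


# ---------------------------------------------------------------------------
# Fixed-threshold approaches (A3, A4, A5)
# ---------------------------------------------------------------------------


def infer_fixed_threshold(rep: Repertoire, alphabet: str, mode: str, threshold: float,
                          approach_id: Optional[str] = None) -> ClonalPartition:
    """Threshold clustering within VJ/junction-length partitions.

    ``mode='absolute'`` uses plain Hamming distance (units of the alphabet),
    ``mode='relative'`` the length-normalized Hamming distance.  Clusters
    never cross PartitionKey boundaries.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if mode not in ("absolute", "relative"):
        raise ValueError(f"mode must be 'absolute' or 'relative', got {mode!r}")
    dist = hamming if mode == "absolute" else normalized_hamming
    if alphabet == "AA":
        usable, skipped = _aa_ready(rep)
        sub = Repertoire(records=usable)
    else:
        sub, skipped = rep, []
    groups = partition_by_vj(sub, alphabet)
    clusters: list[list[Rearrangement]] = []
    for key in sorted(groups, key=lambda k: (k.v_gene, k.j_gene, k.junction_length)):
        clusters.extend(cluster_by_threshold(groups[key], dist, threshold, alphabet))
    aid = approach_id or "fixed"
    return _partition_from_groups(aid, clusters, {
        "alphabet": alphabet, "mode": mode, "threshold": threshold,
        "skipped_ids": skipped,
    })


def infer_A3(rep: Repertoire, threshold: float = 1.0) -> ClonalPartition:
    """Absolute junction AA Hamming threshold (default <= 1 AA)."""
    return infer_fixed_threshold(rep, "AA", "absolute", threshold, "A3")


def infer_A4(rep: Repertoire, threshold: float = 0.15) -> ClonalPartition:
    """Relative junction AA Hamming threshold (default <= 15%)."""
    return infer_fixed_threshold(rep, "AA", "relative", threshold, "A4")


def infer_A5(rep: Repertoire, threshold: float = 0.15) -> ClonalPartition:
    """Relative junction NT Hamming threshold (default <= 15%)."""
    return infer_fixed_threshold(rep, "NT", "relative", threshold, "A5")


# ---------------------------------------------------------------------------
# A6: sample-based threshold from the distance-to-nearest distribution
# ---------------------------------------------------------------------------


def nearest_distances(rep: Repertoire, alphabet: str = "NT") -> list[float]:
    """Per-record normalized Hamming distance to the nearest *non-identical*
    junction within its VJ/junction-length group.

    Records whose group holds no non-identical junction contribute nothing
    (excluding zero-distance duplicates prevents a spurious density spike at
    0 that would masquerade as the within-clone mode).
    """
    groups = partition_by_vj(rep, alphabet)
    out: list[float] = []
    for key, records in groups.items():
        if len(records) < 2:
            continue
        strings = [_junction_of(r, alphabet) for r in records]
        dm = _pairwise_hamming_matrix(strings).astype(float) / key.junction_length
        for i in range(len(records)):
            row = dm[i]
            nonzero = row[row > 0]
            if len(nonzero):
                out.append(float(nonzero.min()))
    return out


def fit_threshold_from_distances(distances: Sequence[float]) -> ThresholdFit:
    """Valley of the smoothed distance-to-nearest density.

    Gaussian KDE (Silverman bandwidth) on a 512-point grid over [0, 1]; the
    threshold is the grid minimum between the two highest local maxima.
    Grid endpoints count as candidate maxima because clipping at 0 can put
    the within-clone mode on the boundary.  Unimodal (or degenerate) input
    returns ``bimodal=False`` with the documented fallback threshold 0.15.
    """
    distances = sorted(float(d) for d in distances)
    grid = np.linspace(0.0, 1.0, DENSITY_GRID_SIZE)
    if len(distances) < 2 or np.std(distances) < 1e-12:
        density = np.zeros_like(grid)
        return ThresholdFit(distances, 0.0, (grid, density), FALLBACK_THRESHOLD, False)
    kde = gaussian_kde(distances, bw_method="silverman")
    density = kde(grid)
    d = density
    # modes must be prominent (5% of peak height): KDE ripple in a unimodal
    # tail is not a second mode.  Pad so boundary modes (clipping at 0) count.
    padded = np.concatenate([[-np.inf], d, [-np.inf]])
    maxima, _props = find_peaks(padded, prominence=0.05 * float(d.max()))
    maxima = maxima - 1
    bw = float(kde.factor * np.std(distances, ddof=1))
    if len(maxima) < 2:
        return ThresholdFit(distances, bw, (grid, density), FALLBACK_THRESHOLD, False)
    top_two = sorted(sorted(maxima, key=lambda i: -d[i])[:2])
    lo, hi = top_two
    valley = lo + int(np.argmin(d[lo:hi + 1]))
    threshold = float(grid[valley])
    threshold = min(max(threshold, min(distances)), max(distances))
    return ThresholdFit(distances, bw, (grid, density), threshold, True)


def fit_sample_threshold(rep: Repertoire, alphabet: str = "NT") -> ThresholdFit:
    """Distance-to-nearest threshold detection for one sample (A6 step 1)."""
    groups = partition_by_vj(rep, alphabet)
    if not any(len(g) >= 2 for g in groups.values()):
        raise InferenceError(
            "no VJ group with >= 2 records; sample-based threshold detection "
            "is undefined — use a fixed-threshold approach instead"
        )
    return fit_threshold_from_distances(nearest_distances(rep, alphabet))


def infer_A6(rep: Repertoire, threshold: Optional[float] = None) -> ClonalPartition:
    """Relative NT threshold clustering at the fitted per-sample threshold."""
    if threshold is None:
        fit = fit_sample_threshold(rep)
        threshold = fit.threshold
        extra = {"bimodal": fit.bimodal, "fitted": True}
    else:
        extra = {"bimodal": None, "fitted": False}
    part = infer_fixed_threshold(rep, "NT", "relative", threshold, "A6")
    part.params.update(extra)
    return part


# ---------------------------------------------------------------------------
# A10: alignment-free tf-idf k-mer clustering with negation thresholding
# ---------------------------------------------------------------------------


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        counts[km] = counts.get(km, 0) + 1
    return counts


def kmer_tfidf(rep: Repertoire, k: int = 4) -> tuple[dict[str, np.ndarray], list[str], list[str]]:
    """tf-idf weighted k-mer vectors over the full receptor sequence.

    tf = raw k-mer count within the sequence; idf = ln(N / document
    frequency) over the repertoire; weight = tf x idf.  Returns
    (vectors keyed by sequence_id, k-mer vocabulary, skipped sequence ids).
    A k-mer present in every sequence gets idf 0 and contributes nothing to
    any distance.
    """
    docs: dict[str, dict[str, int]] = {}
    skipped: list[str] = []
    for rec in rep.records:
        if len(rec.sequence) < k:
            skipped.append(rec.sequence_id)
            continue
        docs[rec.sequence_id] = _kmer_counts(rec.sequence, k)
    n_docs = len(docs)
    if n_docs == 0:
        return {}, [], skipped
    df: dict[str, int] = {}
    for counts in docs.values():
        for km in counts:
            df[km] = df.get(km, 0) + 1
    vocab = sorted(df)
    idf = np.array([np.log(n_docs / df[km]) for km in vocab])
    index = {km: i for i, km in enumerate(vocab)}
    vectors = {}
    for sid, counts in docs.items():
        v = np.zeros(len(vocab))
        for km, c in counts.items():
            v[index[km]] = c
        vectors[sid] = v * idf
    return vectors, vocab, skipped


def _tfidf_matrix(reps: Sequence[Repertoire], k: int) -> tuple[csr_matrix, list[str], list[int], list[str]]:
    """Sparse tf-idf matrix over the concatenated repertoires.

    idf is computed over the pooled document set so repertoire and negation
    sequences live in one comparable vector space.  Returns (matrix, ids,
    block sizes, skipped ids).
    """
    ids: list[str] = []
    blocks: list[int] = []
    skipped: list[str] = []
    all_counts: list[dict[str, int]] = []
    for rep in reps:
        n0 = len(ids)
        for rec in rep.records:
            if len(rec.sequence) < k:
                skipped.append(rec.sequence_id)
                continue
            ids.append(rec.sequence_id)
            all_counts.append(_kmer_counts(rec.sequence, k))
        blocks.append(len(ids) - n0)
    n_docs = len(all_counts)
    df: dict[str, int] = {}
    for counts in all_counts:
        for km in counts:
            df[km] = df.get(km, 0) + 1
    vocab = {km: i for i, km in enumerate(sorted(df))}
    idf = np.zeros(len(vocab))
    for km, i in vocab.items():
        idf[i] = np.log(n_docs / df[km])
    rows, cols, vals = [], [], []
    for ri, counts in enumerate(all_counts):
        for km, c in counts.items():
            ci = vocab[km]
            rows.append(ri)
            cols.append(ci)
            vals.append(c * idf[ci])
    mat = coo_matrix((vals, (rows, cols)), shape=(n_docs, len(vocab))).tocsr()
    return mat, ids, blocks, skipped


def infer_A10(rep: Repertoire, negation: Repertoire, k: int = 4,
              negation_fraction: float = 0.10) -> ClonalPartition:
    """Alignment-free clustering with automatic negation-based threshold.

    Cosine distances on tf-idf k-mer vectors of the full sequence (no VJ
    partitioning, unequal lengths allowed).  The clonal threshold is the
    ``negation_fraction`` quantile of each repertoire sequence's distance to
    its nearest negation sequence — the negation repertoire must come from a
    different sample or individual, so distances below that quantile are very
    unlikely between unrelated clones.
    """
    if negation is None or len(negation) == 0:
        raise InferenceError(
            "A10 requires a non-empty negation repertoire from a different "
            "individual; none was provided"
        )
    mat, ids, blocks, skipped = _tfidf_matrix([rep, negation], k)
    n_rep, n_neg = blocks
    if n_rep == 0:
        return ClonalPartition("A10", {}, {"skipped_ids": skipped})
    if n_neg == 0:
        raise InferenceError("negation repertoire contains no usable sequences")
    rep_mat = mat[:n_rep]
    neg_mat = mat[n_rep:]
    to_neg = cosine_distances(rep_mat, neg_mat)
    nearest_neg = to_neg.min(axis=1)
    threshold = float(np.quantile(nearest_neg, negation_fraction))
    within = cosine_distances(rep_mat)
    adj = csr_matrix(within <= threshold)
    _nc, labels = connected_components(adj, directed=False)
    assignment = {ids[i]: f"A10_{int(labels[i])}" for i in range(n_rep)}
    return ClonalPartition("A10", assignment, {
        "k": k, "negation_fraction": negation_fraction,
        "threshold": threshold, "skipped_ids": skipped,
    })


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------


def infer(approach_id: str, rep: Repertoire, config: Optional[dict] = None) -> ClonalPartition:
    """Run one approach with its default parameters unless overridden.

    ``config`` keys: ``threshold`` (A3–A6), ``k`` and ``negation_fraction``
    and ``negation`` (A10).  The resolved parameters are recorded in the
    returned partition.
    """
    config = dict(config or {})
    if approach_id == "A1":
        return infer_A1(rep)
    if approach_id == "A2":
        return infer_A2(rep)
    if approach_id == "A3":
        return infer_A3(rep, threshold=config.get("threshold", 1.0))
    if approach_id == "A4":
        return infer_A4(rep, threshold=config.get("threshold", 0.15))
    if approach_id == "A5":
        return infer_A5(rep, threshold=config.get("threshold", 0.15))
    if approach_id == "A6":
        return infer_A6(rep, threshold=config.get("threshold"))
    if approach_id == "A10":
        negation = config.get("negation")
        if negation is None:
            raise InferenceError("A10 requires a 'negation' repertoire in config")
        return infer_A10(rep, negation, k=config.get("k", 4),
                         negation_fraction=config.get("negation_fraction", 0.10))
    raise ValueError(
        f"unknown approach {approach_id!r}; supported: {', '.join(APPROACH_IDS)}"
    )


def true_partition(rep: Repertoire) -> ClonalPartition:
    """Ground-truth partition read off ``clone_id_true``."""
    assignment = {}
    for r in rep.records:
        if r.clone_id_true is None:
            raise ValueError(f"record {r.sequence_id} lacks clone_id_true")
        assignment[r.sequence_id] = r.clone_id_true
    return ClonalPartition("TRUE", assignment, {})
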