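"""Edge-based scoring of an inferred partition against ground truth.

Every clonal family is viewed as a clique over its member sequences.  Over
the universe of all C(n,2) unordered sequence pairs, a pair co-clustered in
both truth and inference is a true-positive edge; co-clustered only in the
inference, false positive; only in the truth, false negative; in neither,
true negative.  Performance measures:

    sensitivity = TP / (TP + FN)          precision = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN) Jaccard    = TP / (TP + FN + FP)
    accuracy    = (TP + TN) / C(n,2)      specificity = TN / (TN + FP)

Accuracy and specificity are dominated by the huge TN count and reported
only for completeness.  Ratios with zero denominators are reported as
``None`` (undefined), never silently as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .airr_io import Repertoire
from .clonal_inference import ClonalPartition, infer
from .repertoire_metrics import OutcomeMeasures, summarize


@dataclass
class EdgeConfusion:
    tp: int
    fp: int
    tn: int
    fn: int
    n_records: int

    def __post_init__(self) -> None:
        n = self.n_records
        assert self.tp + self.fp + self.tn + self.fn == n * (n - 1) // 2, \
            "edge counts must partition the C(n,2) pair universe"


@dataclass
class PerformanceReport:
    sensitivity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    jaccard: Optional[float]
    accuracy: Optional[float]
    specificity: Optional[float]

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "precision": self.precision,
            "f1": self.f1, "jaccard": self.jaccard,
            "accuracy": self.accuracy, "specificity": self.specificity,
        }


def clone_edges(partition: ClonalPartition) -> set[frozenset]:
    """Clique expansion: every unordered within-clone pair is one edge.

    Singleton clones contribute no edges.  Intended for small partitions and
    as the reference definition; :func:`edge_confusion` counts edges without
    materializing them.
    """
    edges: set[frozenset] = set()
    for members in partition.clone_members().values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.add(frozenset((members[i], members[j])))
    return edges


def _c2(n: int) -> int:
    return n * (n - 1) // 2


def edge_confusion(truth: ClonalPartition, inferred: ClonalPartition) -> EdgeConfusion:
    """TP/FP/TN/FN edge counts between two partitions of the same records.

    Counted via the contingency table of (true clone, inferred clone) joint
    sizes n_ij: TP = sum C(n_ij,2), truth edges = sum C(a_i,2), inferred
    edges = sum C(b_j,2), and TN closes the C(n,2) universe algebraically.
    """
    t_ids = set(truth.assignment)
    i_ids = set(inferred.assignment)
    if t_ids != i_ids:
        diff = sorted(t_ids.symmetric_difference(i_ids))
        raise ValueError(f"partitions cover different records; symmetric difference: {diff[:10]}"
                         + ("..." if len(diff) > 10 else ""))
    n = len(t_ids)
    joint: dict[tuple[str, str], int] = {}
    a: dict[str, int] = {}
    b: dict[str, int] = {}
    for sid in truth.assignment:
        tl = truth.assignment[sid]
        il = inferred.assignment[sid]
        joint[(tl, il)] = joint.get((tl, il), 0) + 1
        a[tl] = a.get(tl, 0) + 1
        b[il] = b.get(il, 0) + 1
    tp = sum(_c2(v) for v in joint.values())
    truth_edges = sum(_c2(v) for v in a.values())
    inferred_edges = sum(_c2(v) for v in b.values())
    fn = truth_edges - tp
    fp = inferred_edges - tp
    tn = _c2(n) - tp - fp - fn
    return EdgeConfusion(tp=tp, fp=fp, tn=tn, fn=fn, n_records=n)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def performance(c: EdgeConfusion) -> PerformanceReport:
    """All six measures from one confusion; 0/0 cases are ``None``."""
    total = c.tp + c.fp + c.tn + c.fn
    return PerformanceReport(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        jaccard=_ratio(c.tp, c.tp + c.fn + c.fp),
        accuracy=_ratio(c.tp + c.tn, total),
        specificity=_ratio(c.tn, c.tn + c.fp),
    )


@dataclass
class ApproachEvaluation:
    approach_id: str
    confusion: Optional[EdgeConfusion]
    performance: Optional[PerformanceReport]
    outcomes: Optional[OutcomeMeasures]
    error: Optional[str] = None


def evaluate_approaches(rep: Repertoire, truth: ClonalPartition,
                        approaches: list[str],
                        configs: Optional[dict[str, dict]] = None
                        ) -> list[ApproachEvaluation]:
    """One evaluation row per requested approach; failures recorded per row.

    When an approach skips records (e.g. untranslatable junctions in AA
    approaches) the truth is restricted to the records the approach analyzed
    so the edge universes match.
    """
    configs = configs or {}
    rows: list[ApproachEvaluation] = []
    for aid in approaches:
        try:
            part = infer(aid, rep, configs.get(aid, {}))
            t = truth
            if set(part.assignment) != set(truth.assignment):
                t = ClonalPartition("TRUE", {
                    sid: lab for sid, lab in truth.assignment.items()
                    if sid in part.assignment
                }, dict(truth.params))
            conf = edge_confusion(t, part)
            rows.append(ApproachEvaluation(aid, conf, performance(conf), summarize(part)))
        except Exception as exc:  # crash isolation: record, keep going
            rows.append(ApproachEvaluation(aid, None, None, None, error=str(exc)))
    return rows
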