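import numpy as np
import pytest

from cfbench import (Repertoire, cluster_by_threshold, fit_threshold_from_distances,
                     hamming, infer, infer_A1, infer_A2, infer_A6, infer_A10,
                     infer_fixed_threshold, kmer_tfidf, normalized_hamming,
                     partition_by_vj, fit_sample_threshold)
from cfbench.clonal_inference import FALLBACK_THRESHOLD, InferenceError
from cfbench.synthetic_data import _stream

from conftest import make_record, make_repertoire, partitions_equal


@pytest.mark.parametrize("a,b,expected", [
    ("ACGT", "ACGT", 0),
    ("ACGT", "ACGA", 1),
    ("CARDYW", "CARNNW", 2),
])
def test_hamming(a, b, expected):
    assert hamming(a, b) == expected == hamming(b, a)


def test_hamming_unequal_lengths_raise():
    with pytest.raises(ValueError):
        hamming("ACG", "ACGT")
    with pytest.raises(ValueError):
        normalized_hamming("", "")


@pytest.mark.parametrize("a,b,expected", [
    ("ACGT", "ACGA", 0.25),
    ("ACGT", "ACGT", 0.0),
    ("AAAA", "TTTT", 1.0),
])
def test_normalized_hamming(a, b, expected):
    assert normalized_hamming(a, b) == expected


def test_partition_by_vj_keys():
    rep = Repertoire(records=[
        make_record("a", "CARDYWAAAAA", v="IGHV1-69*01"),
        make_record("b", "CARNNWAAAAA", v="IGHV1-69*02"),   # same gene after stripping
        make_record("c", "CARDYWAAAAAAAA", v="IGHV1-69*01"),  # longer junction
        make_record("d", "CARDYWAAAAA", v="IGHV3-23*01"),   # other V gene
    ])
    groups = partition_by_vj(rep, "AA")
    by_key = {(k.v_gene, k.junction_length): [r.sequence_id for r in v]
              for k, v in groups.items()}
    assert by_key[("IGHV1-69", 11)] == ["a", "b"]
    assert by_key[("IGHV1-69", 14)] == ["c"]
    assert by_key[("IGHV3-23", 11)] == ["d"]


def test_cluster_by_threshold_examples():
    recs = make_repertoire(["CARDYW", "CARDFW", "CARNNW"]).records
    comps = cluster_by_threshold(recs, hamming, 1, "AA")
    as_sets = {frozenset(r.junction_aa for r in c) for c in comps}
    assert as_sets == {frozenset({"CARDYW", "CARDFW"}), frozenset({"CARNNW"})}


def test_cluster_by_threshold_chaining():
    recs = make_repertoire(["AAAA", "AAAB", "AABB"]).records
    comps = cluster_by_threshold(recs, hamming, 1, "AA")
    assert len(comps) == 1 and len(comps[0]) == 3  # single linkage chains


def test_cluster_below_all_distances_gives_singletons():
    recs = make_repertoire(["AAAA", "CCCC", "GGGG"]).records
    comps = cluster_by_threshold(recs, hamming, 0, "AA")
    assert len(comps) == 3


def _brute_force_components(strings, threshold):
    """Transitive closure of the thresholded distance relation."""
    n = len(strings)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sum(a != b for a, b in zip(strings[i], strings[j])) <= threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


@pytest.mark.parametrize("seed", range(5))
def test_cluster_matches_transitive_closure_oracle(seed):
    rng = _stream(seed, "closure")
    strings = ["".join(rng.choice(list("ACGT"), size=9)) for _ in range(120)]
    recs = make_repertoire(strings).records
    for thr in (0, 1, 2):
        comps = cluster_by_threshold(recs, hamming, thr, "AA")
        got = {frozenset(recs.index(r) for r in c) for c in comps}
        assert got == _brute_force_components(strings, thr)


def test_A1_groups_by_junction_only():
    rep = Repertoire(records=[
        make_record("a", "CARDYW", v="IGHV1-69*01"),
        make_record("b", "CARDYW", v="IGHV3-23*01"),  # different V, same junction
        make_record("c", "CARNNW"),
        make_record("d", "CARDFW"),
        make_record("e", "CARNNW"),
    ])
    part = infer_A1(rep)
    assert len(set(part.assignment.values())) == 3
    assert part.assignment["a"] == part.assignment["b"]
    assert infer_A1(Repertoire()).assignment == {}


def test_A2_refines_A1():
    rep = Repertoire(records=[
        make_record("a", "CARDYW", v="IGHV1-69*01"),
        make_record("b", "CARDYW", v="IGHV3-23*01"),
        make_record("c", "CARDYW", v="IGHV1-69*02"),
    ])
    a1, a2 = infer_A1(rep), infer_A2(rep)
    assert a1.assignment["a"] == a1.assignment["b"]
    assert a2.assignment["a"] != a2.assignment["b"]   # split by V gene
    assert a2.assignment["a"] == a2.assignment["c"]   # allele-stripped equality
    # refinement: every A2 cluster sits inside one A1 cluster
    for members in a2.clone_members().values():
        assert len({a1.assignment[s] for s in members}) == 1


def test_A4_threshold_boundary():
    """20-aa junctions: 3 mismatches (0.15) link, 4 (0.20) do not."""
    base = "CARDYWAAAAAAAAAAAAAW"
    three = "CARNNWAAAAAAAAAAAAAF"
    four = "CNRNNWAAAAAAAAAAAAAF"
    assert hamming(base, three) == 3 and hamming(base, four) == 4
    rep = make_repertoire([base, three])
    part = infer("A4", rep, {})
    assert part.assignment["seq0"] == part.assignment["seq1"]
    rep2 = make_repertoire([base, four])
    part2 = infer("A4", rep2, {})
    assert part2.assignment["seq0"] != part2.assignment["seq1"]


def test_A3_at_zero_equals_A2(mutated_simulation):
    _cfg, rep, _truth = mutated_simulation
    assert partitions_equal(infer_fixed_threshold(rep, "AA", "absolute", 0), infer_A2(rep))


def test_threshold_monotonicity(mutated_simulation):
    _cfg, rep, _truth = mutated_simulation
    n_cfs = [len(set(infer_fixed_threshold(rep, "NT", "relative", t).assignment.values()))
             for t in (0, 0.05, 0.10, 0.15, 0.25, 0.5)]
    assert all(a >= b for a, b in zip(n_cfs, n_cfs[1:]))


def test_partitions_never_cross_vj_keys(mutated_simulation):
    _cfg, rep, _truth = mutated_simulation
    part = infer("A5", rep, {})
    key_of = {r.sequence_id: (r.v_call, r.j_call, len(r.junction)) for r in rep.records}
    for members in part.clone_members().values():
        assert len({key_of[s] for s in members}) == 1


def test_order_invariance(mutated_simulation):
    _cfg, rep, _truth = mutated_simulation
    rng = _stream(0, "shuffle")
    shuffled = Repertoire(records=[rep.records[i] for i in rng.permutation(len(rep))])
    for aid in ("A1", "A2", "A3", "A4", "A5", "A6"):
        assert partitions_equal(infer(aid, rep, {}), infer(aid, shuffled, {})), aid


def test_valley_detection_bimodal():
    """Seeded bimodal distance-to-nearest mixtures put the threshold in the valley."""
    hits = 0
    for seed in range(20):
        rng = _stream(seed, "valley")
        d = np.clip(np.concatenate([rng.normal(0.03, 0.01, 200),
                                    rng.normal(0.30, 0.05, 200)]), 0, 1)
        fit = fit_threshold_from_distances(d)
        assert fit.bimodal
        if 0.08 < fit.threshold < 0.25:
            hits += 1
    assert hits >= 19


def test_valley_fallback_on_degenerate_input():
    fit = fit_threshold_from_distances([0.1] * 50)
    assert not fit.bimodal and fit.threshold == FALLBACK_THRESHOLD


def test_fit_sample_threshold_requires_group():
    rep = Repertoire(records=[make_record("a", "CARDYW")])
    with pytest.raises(InferenceError):
        fit_sample_threshold(rep)


def test_A6_forced_threshold_equals_A5(mutated_simulation):
    _cfg, rep, _truth = mutated_simulation
    assert partitions_equal(infer_A6(rep, threshold=0.15), infer("A5", rep, {}))


def test_A6_identical_sequences_single_cf():
    rep = make_repertoire(["CARDYW"] * 5)
    part = infer_A6(rep)
    assert len(set(part.assignment.values())) == 1


def test_kmer_tfidf_hand_computed():
    rep = Repertoire(records=[
        make_record("s1", "CA", junction="ACGT"),
        make_record("s2", "CA", junction="ACGA"),
        make_record("s3", "CA", junction="TTTT"),
    ])
    for r, seq in zip(rep.records, ("ACGT", "ACGA", "TTTT")):
        r.sequence = seq
    vectors, vocab, skipped = kmer_tfidf(rep, k=2)
    assert skipped == []
    idx = {km: i for i, km in enumerate(vocab)}
    ln15, ln3 = np.log(1.5), np.log(3.0)
    v1 = vectors["s1"]
    assert v1[idx["AC"]] == pytest.approx(ln15)
    assert v1[idx["CG"]] == pytest.approx(ln15)
    assert v1[idx["GT"]] == pytest.approx(ln3)
    assert vectors["s3"][idx["TT"]] == pytest.approx(3 * ln3)
    # ubiquitous k-mer would have idf 0
    assert np.allclose(vectors["s1"][idx["GA"]], 0.0)


def test_kmer_tfidf_identical_sequences_identical_vectors():
    rep = Repertoire(records=[make_record("a", "CA"), make_record("b", "CA")])
    for r in rep.records:
        r.sequence = "ACGTACGT"
    vectors, _, _ = kmer_tfidf(rep, k=3)
    assert np.array_equal(vectors["a"], vectors["b"])


def _with_sequences(junctions, prefix="sA"):
    rep = make_repertoire(junctions)
    for i, r in enumerate(rep.records):
        r.sequence_id = f"{prefix}{i}"
        r.sequence = r.junction * 10
    return Repertoire(records=rep.records)


def test_A10_identical_sequences_cocluster():
    rep = _with_sequences(["CARDYW", "CARDYW", "CARNNW"])
    neg = _with_sequences(["GGGGGG", "SSSSSS"], prefix="n")
    part = infer_A10(rep, neg)
    assert part.assignment["sA0"] == part.assignment["sA1"]


def test_A10_requires_negation():
    rep = _with_sequences(["CARDYW"])
    with pytest.raises(InferenceError):
        infer("A10", rep, {})
    with pytest.raises(InferenceError):
        infer_A10(rep, Repertoire())


def test_A10_degenerate_negation_collapses_threshold():
    rep = _with_sequences(["CARDYW", "CARDFW", "CARNNW", "CGGGGW"])
    neg = _with_sequences(["CARDYW", "CARDFW", "CARNNW", "CGGGGW"], prefix="n")
    part = infer_A10(rep, neg)
    assert part.params["threshold"] == pytest.approx(0.0, abs=1e-12)


def test_A10_disjoint_kmers_never_linked():
    """Sequences sharing no k-mer are at cosine distance 1, so they stay
    unlinked whenever the calibrated threshold is below 1."""
    rep = _with_sequences(["AAAAAA", "GGGGGG"])
    neg = _with_sequences(["AAATAA", "GGGTGG"], prefix="n")  # close to rep members
    part = infer_A10(rep, neg)
    assert part.params["threshold"] < 1.0
    assert part.assignment["sA0"] != part.assignment["sA1"]


def test_dispatcher_defaults_and_errors(mutated_simulation):
    _cfg, rep, _truth = mutated_simulation
    assert infer("A3", rep, {}).params["threshold"] == 1.0
    assert infer("A4", rep, {}).params["threshold"] == 0.15
    with pytest.raises(ValueError, match="A1"):
        infer("A99", rep, {})
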