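import pytest

from cfbench import Rearrangement, Repertoire, SimulationConfig, simulate_repertoire


def make_record(sid, junction_aa="CARDYW", v="IGHV1-69*01", j="IGHJ4*02",
                junction=None, sample="S1", **kw):
    if junction is None:
        junction = "".join({"C": "TGT", "A": "GCT", "R": "CGT", "D": "GAT",
                            "Y": "TAT", "W": "TGG", "F": "TTT", "N": "AAT",
                            "G": "GGT", "S": "TCT"}.get(aa, "GCT") for aa in junction_aa)
    return Rearrangement(sequence_id=sid, v_call=v, j_call=j, junction=junction,
                         junction_aa=junction_aa, sample_id=sample, **kw)


def make_repertoire(junctions_aa, v="IGHV1-69*01", j="IGHJ4*02", **kw):
    """Repertoire of records sharing V/J, one per junction AA string."""
    return Repertoire(records=[
        make_record(f"seq{i}", aa, v=v, j=j, **kw) for i, aa in enumerate(junctions_aa)
    ])


def partitions_equal(p1, p2):
    """Set-partition equality, ignoring label names."""
    def blocks(p):
        groups = {}
        for sid, lab in p.assignment.items():
            groups.setdefault(lab, set()).add(sid)
        return frozenset(frozenset(g) for g in groups.values())
    return blocks(p1) == blocks(p2)


@pytest.fixture(scope="session")
def mutated_simulation():
    """A mid-sized simulated repertoire with mutations, shared across tests."""
    cfg = SimulationConfig(seed=11, n_clones=30,
                           clone_size_distribution={"type": "geometric", "p": 0.25},
                           singleton_fraction=0.2, mutation_rate_per_site=0.01)
    rep, truth = simulate_repertoire(cfg)
    return cfg, rep, truth
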