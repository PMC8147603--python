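import networkx as nx
import numpy as np
import pytest

from beemito.haplonet import (
    build_network,
    code_indels,
    connection_limit,
    pairwise_steps,
    parsimony_probability,
)
from beemito.io_formats import MtSequence
from beemito.repeat_typing import call_haplotypes


class TestIndelCoding:
    def test_shared_gap_is_one_character(self):
        m = code_indels({"h1": "AC--GT", "h2": "ACTTGT", "h3": "AC--GT"})
        assert m.characters == [(2, 4)]
        assert m.states["h1"] == (1,) and m.states["h2"] == (0,) and m.states["h3"] == (1,)

    def test_gapless_alignment_has_no_characters(self):
        assert code_indels({"h1": "ACGT", "h2": "ACGA"}).characters == []

    def test_nested_runs_give_missing_state(self):
        # runs (2,4) and (1,5): the (1,5) carrier is missing for (2,4)
        m = code_indels({"a": "A----A", "b": "AA--AA"[:6], "c": "AATTAA"})
        assert set(m.characters) == {(1, 5), (2, 4)}
        i24 = m.characters.index((2, 4))
        assert m.states["a"][i24] is None
        assert m.states["b"][i24] == 1
        assert m.states["c"][i24] == 0

    def test_uninformative_characters_dropped(self):
        # every haplotype shares the gap: no 0-carrier, so no character
        m = code_indels({"h1": "A--T", "h2": "A--T"})
        assert m.characters == []


class TestPairwiseSteps:
    def test_identical_is_zero(self):
        assert pairwise_steps("ACGT", "ACGT") == 0

    def test_substitution_plus_shared_gap(self):
        assert pairwise_steps("AC--GA", "AC--GT") == 1

    def test_subs_plus_indel_state(self):
        # 2 substitutions counted on sequence, 1 indel character difference
        assert pairwise_steps("AAGGT", "AATGC", (1,), (0,)) == 3

    def test_ambiguous_bases_never_count(self):
        assert pairwise_steps("ACNT", "ACGT") == 0
        assert pairwise_steps("ACRT", "ACGT") == 0

    def test_missing_indel_state_skipped(self):
        assert pairwise_steps("ACGT", "ACGT", (None,), (1,)) == 0


class TestConnectionLimit:
    def test_monotone_in_confidence(self):
        limits = [connection_limit(100, c) for c in (0.90, 0.95, 0.99)]
        assert limits == sorted(limits, reverse=True)

    def test_monotone_in_length(self):
        grid = [50, 100, 200, 400, 800]
        limits = [connection_limit(m, 0.95) for m in grid]
        assert limits == sorted(limits)

    def test_conf_validation(self):
        with pytest.raises(ValueError):
            connection_limit(100, 1.5)

    def test_probability_decreases_with_steps(self):
        probs = [parsimony_probability(j, 200) for j in range(1, 10)]
        assert probs == sorted(probs, reverse=True)

    def test_matches_monte_carlo_oracle_small(self):
        # lighter version of the acceptance check: 2e4 replicates
        m, conf = 100, 0.95
        rng = np.random.default_rng(5)
        mc = _mc_connection_limit(m, conf, rng, n_rep=20000)
        assert abs(connection_limit(m, conf) - mc) <= 1


def _mc_connection_limit(m, conf, rng, n_rep):
    """Monte-Carlo oracle: Poisson mutations on an m-site sequence; estimate
    P(no superimposed hits | j observed differences) and take the largest j
    still at or above conf."""
    j = 0
    while True:
        jj = j + 1
        lam = -m * np.log1p(-jj / m)
        total = rng.poisson(lam, size=n_rep)
        good = cond = 0
        for n_mut in total:
            occupied = len(set(rng.integers(0, m, size=n_mut).tolist()))
            if occupied == jj:
                cond += 1
                good += n_mut == jj
        if cond == 0 or good / cond < conf:
            return j
        j = jj


class TestBuildNetwork:
    def _hset(self, seq_by_id):
        return call_haplotypes(
            [MtSequence(k, v) for k, v in seq_by_id.items()]
        )

    def test_chain_without_medians(self):
        hset = self._hset({"a": "AAAA", "b": "AAAT", "c": "AATT"})
        g = build_network(hset, limit=5)
        assert sum(1 for _, d in g.nodes(data=True) if d["inferred"]) == 0
        degrees = sorted(d for _, d in g.degree())
        assert degrees == [1, 1, 2]

    def test_median_count_equals_distance_minus_one(self):
        hset = self._hset({"a": "AAAA", "b": "TTTA"})
        g = build_network(hset, limit=5)
        medians = [n for n, d in g.nodes(data=True) if d["inferred"]]
        assert len(medians) == 2  # distance 3 -> 2 inferred nodes
        assert nx.shortest_path_length(g, "H1", "H2") == 3

    def test_distance_beyond_limit_leaves_components(self):
        hset = self._hset({"a": "AAAA", "b": "TTTT"})
        g = build_network(hset, limit=3)
        assert nx.number_connected_components(g) == 2
        assert g.number_of_edges() == 0

    def test_no_shortcut_when_path_exists(self):
        # d(A,B)=1, d(B,C)=1, d(A,C)=2: A-C must reuse the A-B-C path
        hset = self._hset({"a": "AAAA", "b": "AAAT", "c": "AATT"})
        g = build_network(hset, limit=5)
        assert g.number_of_edges() == 2

    def test_permutation_invariance(self, rng):
        pool = {
            "AAAAAA": 5,
            "AAAAAT": 4,
            "AAAATT": 3,
            "AATTTT": 2,
            "GAAAAA": 1,
        }
        seqs = [
            MtSequence(f"s{i}", s)
            for i, s in enumerate(
                [s for s, k in pool.items() for _ in range(k)]
            )
        ]
        ref = None
        for perm in range(5):
            order = rng.permutation(len(seqs))
            hset = call_haplotypes([seqs[i] for i in order])
            g = build_network(hset, limit=6)
            seq_of = {n: d.get("sequence") for n, d in g.nodes(data=True) if not d["inferred"]}
            degrees = tuple(sorted((seq_of[n], g.degree(n)) for n in seq_of))
            comps = frozenset(
                frozenset(seq_of[n] for n in comp if n in seq_of)
                for comp in nx.connected_components(g)
            )
            if ref is None:
                ref = (degrees, comps)
            assert (degrees, comps) == ref

    def test_true_adjacency_recovered_from_known_tree(self, rng):
        # evolve haplotypes along a known star-like tree, <= limit steps/edge
        root = "".join(rng.choice(list("ACGT"), 60))
        children = {}
        pos = rng.choice(60, size=6, replace=False)
        for i in range(3):
            s = list(root)
            for p in pos[2 * i: 2 * i + 2]:
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            children[f"c{i}"] = "".join(s)
        hset = call_haplotypes(
            [MtSequence("root", root)] * 2
            + [MtSequence(f"k{i}", s) for i, s in enumerate(children.values())]
        )
        g = build_network(hset, limit=connection_limit(60))
        root_id = next(h.hap_id for h in hset if h.sequence == root)
        for child_seq in children.values():
            cid = next(h.hap_id for h in hset if h.sequence == child_seq)
            path = nx.shortest_path(g, root_id, cid)
            # direct connection through medians only (distance 2 -> 1 median)
            assert len(path) == 3
            assert g.nodes[path[1]]["inferred"]
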