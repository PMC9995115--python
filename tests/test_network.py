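"""k-mer similarity networks: edge rule, clusters, purity, random benchmark."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrshare.cohort import CohortConfig, PlantedClusterSpec, PlantedSharedSpec, generate_cohort
from tcrshare.network import (
    NetworkConfig,
    build_network,
    cluster_statistics,
    compare_to_random,
    kmer_set,
    shared_kmer_count,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA, min_size=3, max_size=18)


def brute_force_shared(a, b, k=3):
    return len({a[i : i + k] for i in range(len(a) - k + 1)} & {b[i : i + k] for i in range(len(b) - k + 1)})


class TestKmers:
    def test_basic_set(self):
        assert kmer_set("CASSL", 3) == {"CAS", "ASS", "SSL"}

    def test_duplicates_collapse(self):
        assert kmer_set("AAAA", 3) == {"AAA"}

    def test_too_short_is_empty(self):
        assert kmer_set("CA", 3) == set()

    def test_worked_pair(self):
        assert shared_kmer_count("CASSLSGTGELFF", "CASSLSGTGELFY") == 10

    def test_disjoint_alphabets(self):
        assert shared_kmer_count("AAAAAA", "CCCCCC") == 0

    @given(seqs, seqs)
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_and_bound(self, a, b):
        got = shared_kmer_count(a, b)
        assert got == brute_force_shared(a, b)
        assert got <= min(len(a), len(b)) - 2
        assert len(kmer_set(a, 3)) <= max(0, len(a) - 2)


class TestBuildNetwork:
    def test_similar_pair_connected(self):
        net = build_network([("CASSLSGTGELFF", "LEFT"), ("CASSLSGTGELFY", "RIGHT")])
        assert len(net.edges) == 1
        assert net.n_clusters == 1

    def test_pigeonhole_short_sequences_isolated(self):
        # length < tau + k - 1 = 10 cannot carry 8 shared 3-mers
        short = [("CASSLSGTF"[:9], "LEFT"), ("CASSLSGTF"[:9], "RIGHT"), ("WGQGTLVTF", "LEFT")]
        net = build_network(short)
        assert net.edges == []

    def test_adversarial_repeat_sequences(self):
        # long homopolymers have one distinct k-mer each: never ≥8 shared
        net = build_network([("A" * 30, "LEFT"), ("A" * 25, "RIGHT"), ("C" * 30, "LEFT")])
        assert net.edges == []

    def test_shared_label_merging(self):
        net = build_network([("CASSLSGTGELFF", "LEFT"), ("CASSLSGTGELFF", "RIGHT")])
        assert len(net.nodes) == 1
        assert net.labels[0] == frozenset({"LEFT", "RIGHT"})

    def test_determinism(self):
        pairs = [(s, "LEFT") for s in ("CASSLSGTGELFF", "CASSLSGTGELFY", "CAWSVQNTEAFFA")]
        a = build_network(pairs)
        b = build_network(list(reversed(pairs)))
        assert a.nodes == b.nodes and a.edges == b.edges and a.components == b.components

    def test_raising_tau_never_adds_edges(self):
        pairs = [("CASSLSGTGELFF", "LEFT"), ("CASSLSGTGELFY", "RIGHT"), ("CASSLSGTGELYY", "LEFT")]
        low = build_network(pairs, NetworkConfig(tau=6))
        high = build_network(pairs, NetworkConfig(tau=9))
        assert set(high.edges) <= set(low.edges)
        assert high.n_clusters >= low.n_clusters

    def test_empty_input(self):
        net = build_network([])
        assert net.nodes == [] and net.edges == []


class TestClusterStats:
    def _net(self):
        fam = ["CASSLSGTGELFF", "CASSLSGTGELFY", "CASSLSGTGELFW", "CASSLSGTGELFH"]
        labels = ["LEFT", "LEFT", "LEFT", "RIGHT"]
        return build_network(list(zip(fam, labels)))

    def test_purity_three_quarters(self):
        stats = cluster_statistics(self._net(), top_c=1)
        assert stats[0].purity == pytest.approx(0.75)
        assert stats[0].top_label == "LEFT"

    def test_fully_connected_edge_count(self):
        stats = cluster_statistics(self._net(), top_c=1)
        assert stats[0].n_sequences == 4
        assert stats[0].n_connections == 6  # C(4,2): members differ at ≤2 positions

    def test_singleton_cluster_purity_one(self):
        net = build_network([("CASSLSGTGELFF", "LEFT"), ("WGQGTLVTGQPQH", "RIGHT")])
        stats = cluster_statistics(net, top_c=5)
        assert all(s.purity == 1.0 and s.n_sequences == 1 for s in stats)

    def test_sequence_mode_uses_count_mass(self):
        fam = ["CASSLSGTGELFF", "CASSLSGTGELFY"]
        net = build_network([(fam[0], "LEFT"), (fam[1], "LEFT")], weights={fam[0]: 9, fam[1]: 1})
        stats = cluster_statistics(net, top_c=1, purity_mode="sequence")
        assert stats[0].purity == pytest.approx(0.9)


@pytest.fixture(scope="module")
def antigen_net(trb_model):
    cfg = CohortConfig(
        n_patients=1, compartments=("SF_LEFT", "SF_RIGHT"), subsets=("TREG",),
        visits=1, repertoire_size=250,
        planted_shared=(PlantedSharedSpec(15, rank_band=(1, 50)),),
        planted_clusters=(PlantedClusterSpec(5, 8),), seed=11,
    )
    reps, truth = generate_cohort(cfg, trb_model)
    pairs = [(c.junction_aa, "LEFT") for c in reps[0].clonotypes if c.productive]
    pairs += [(c.junction_aa, "RIGHT") for c in reps[1].clonotypes if c.productive]
    return build_network(pairs), truth


class TestPlantedRecovery:
    def test_families_recovered_as_single_components(self, antigen_net):
        net, truth = antigen_net
        node_comp = dict(zip(net.nodes, net.components))
        recovered = 0
        for members in truth.cluster_families.values():
            comps = {node_comp[m] for m in members if m in node_comp}
            recovered += int(len(comps) == 1 and all(m in node_comp for m in members))
        assert recovered >= 0.9 * len(truth.cluster_families)

    def test_planted_families_dominate_top_clusters(self, antigen_net):
        net, truth = antigen_net
        stats = cluster_statistics(net, top_c=5)
        family_sizes = sorted((len(set(m)) for m in truth.cluster_families.values()), reverse=True)
        assert stats[0].n_sequences >= family_sizes[-1]
        # mixed left/right/shared families cannot be pure
        assert np.median([s.purity for s in stats]) < 0.8


class TestRandomComparison:
    def test_single_replicate_flagged(self, trb_model):
        net = build_network([("CASSLSGTGELFF", "LEFT"), ("CASSLSGTGELFY", "RIGHT")])
        stats = cluster_statistics(net, top_c=1)
        comp = compare_to_random(stats, trb_model, (30, 30), NetworkConfig(n_random=1, seed=0))
        assert comp.flag == "FEW_RANDOM_REPLICATES"
        assert len(comp.random_stats) >= 1

    def test_replicate_count_honored(self, trb_model):
        net = build_network([("CASSLSGTGELFF", "LEFT"), ("CASSLSGTGELFY", "RIGHT")])
        stats = cluster_statistics(net, top_c=1)
        comp = compare_to_random(stats, trb_model, (40, 40), NetworkConfig(n_random=4, top_c=3, seed=1))
        assert set(comp.random_stats["replicate"]) == {0, 1, 2, 3}
        assert len(comp.random_stats) == 4 * 3
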