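"""Dedup, pairwise identity, greedy clustering, conservation calling."""

import random

import pytest

from sorfpipe import clustering
from tests.conftest import make_record

# 20-residue base peptide used to build controlled-identity variants
BASE = "MKVLAEGHIRNDQSTWYFPC"


def mutate(seq, positions, to="G"):
    out = list(seq)
    for p in positions:
        out[p] = to if out[p] != to else "A"
    return "".join(out)


class TestDedup:
    def test_identical_sequences_collapse(self):
        a = make_record("MKVL", "a", nt_seq="ATGAAAGTTCTTTAA")
        b = make_record("MKVL", "b", nt_seq="ATGAAAGTTCTTTAA", species="spY")
        unique, removed = clustering.dedup_identical([a, b])
        assert len(unique) == 1 and removed == 1

    def test_near_duplicates_kept(self):
        a = make_record("MKVL", "a", nt_seq="ATGAAAGTTCTTTAA")
        b = make_record("MKVL", "b", nt_seq="ATGAAAGTGCTTTAA")
        unique, removed = clustering.dedup_identical([a, b])
        assert len(unique) == 2 and removed == 0

    def test_annotation_source_preferred(self):
        a = make_record("MKVL", "a", nt_seq="X")
        b = make_record("MKVL", "b", nt_seq="X", source="annotation")
        b.feature_id = "m1"
        (survivor,), _ = clustering.dedup_identical([a, b])
        assert survivor.source == "annotation"

    def test_empty_input(self):
        assert clustering.dedup_identical([]) == ([], 0)


class TestPairwiseIdentity:
    def test_identical(self):
        assert clustering.pairwise_identity(BASE, BASE) == pytest.approx(1.0)

    def test_five_substitutions_in_twenty(self):
        variant = mutate(BASE, [2, 6, 10, 14, 18])
        assert clustering.pairwise_identity(BASE, variant) == pytest.approx(0.75)

    def test_disjoint_alphabets_give_zero(self):
        assert clustering.pairwise_identity("KKKK", "DDDD") == pytest.approx(0.0)

    def test_denominator_is_shorter_sequence(self):
        # identical prefix: all 10 shorter residues match
        assert clustering.pairwise_identity(BASE[:10], BASE) == pytest.approx(1.0)


class TestGreedyCluster:
    def test_similar_join_dissimilar_split(self):
        a = make_record(BASE, "a")
        a_prime = make_record(mutate(BASE, [2, 6, 10, 14, 18]), "b")  # 75% to a
        b = make_record("GGGGGGGGGGGGGGGGGGGG", "c")  # unrelated
        clusters = clustering.greedy_cluster([a, a_prime, b])
        member_sets = sorted(tuple(sorted(m.rid for m in c.members))
                             for c in clusters)
        assert len(clusters) == 2
        assert any(len(s) == 2 for s in member_sets)

    def test_boundary_identity_joins(self):
        # exactly 14/20 = 0.70 identity to the representative
        variant = mutate(BASE, [1, 4, 7, 10, 13, 16])
        clusters = clustering.greedy_cluster([make_record(BASE, "a"),
                                              make_record(variant, "b")])
        assert len(clusters) == 1
        assert clusters[0].identities[clusters[0].members[1].rid] == pytest.approx(0.70)

    def test_singleton(self):
        clusters = clustering.greedy_cluster([make_record(BASE, "a")])
        assert len(clusters) == 1
        assert clusters[0].representative.rid == clusters[0].members[0].rid

    def test_representative_is_longest_member(self):
        long = make_record(BASE + "MKVL", "long")
        short = make_record(BASE + "MKV", "short")
        clusters = clustering.greedy_cluster([short, long])
        assert all(c.representative.aa_seq == max((m.aa_seq for m in c.members),
                                                  key=len) for c in clusters)

    def test_order_invariance(self):
        rng = random.Random(5)
        records = [make_record(BASE, "a"),
                   make_record(mutate(BASE, [2, 6, 10]), "b"),
                   make_record("GGGGGGGGGGGGGGGGGGGG", "c"),
                   make_record(mutate(BASE, [1, 3, 5, 7]), "d"),
                   make_record("WWWWYYYYFFFFHHHHRRRR", "e")]
        reference = None
        for _ in range(5):
            rng.shuffle(records)
            clusters = clustering.greedy_cluster(list(records))
            snapshot = sorted(tuple(sorted(m.rid for m in c.members))
                              for c in clusters)
            if reference is None:
                reference = snapshot
            assert snapshot == reference

    def test_lower_threshold_never_more_clusters(self):
        rng = random.Random(11)
        records = [make_record("".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                                       for _ in range(rng.randint(10, 30))),
                               f"r{i}") for i in range(30)]
        counts = [len(clustering.greedy_cluster(records, thr))
                  for thr in (0.9, 0.7, 0.5, 0.3)]
        assert counts == sorted(counts, reverse=True)

    def test_partition_and_member_identity_contract(self):
        rng = random.Random(13)
        records = []
        for i in range(10):
            records.append(make_record(BASE, f"base{i}" ))
        for i in range(20):
            records.append(make_record(
                "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                        for _ in range(rng.randint(10, 40))), f"rnd{i}"))
        # distinct rids required for the partition check
        clusters = clustering.greedy_cluster(records)
        clustering.validate_clusters(clusters)
        assert sum(len(c.members) for c in clusters) == len(records)


class TestConservation:
    def _cluster(self, species, cid="c0"):
        members = [make_record(BASE, f"{cid}_m{i}", species=sp)
                   for i, sp in enumerate(species)]
        c = clustering.SorfCluster(cid, members[0], members,
                                   {m.rid: 1.0 for m in members})
        return c

    def test_two_species_is_conserved(self):
        (c,) = clustering.call_conserved([self._cluster(["spX", "spY"])])
        assert c.conserved

    def test_single_species_not_conserved(self):
        (c,) = clustering.call_conserved([self._cluster(["spX", "spX", "spX"])])
        assert not c.conserved

    def test_singleton_not_conserved(self):
        (c,) = clustering.call_conserved([self._cluster(["spX"])])
        assert not c.conserved

    def test_breadth_histogram(self):
        clusters = clustering.call_conserved(
            [self._cluster(["spX", "spY"]), self._cluster(["spX"], cid="c1")])
        per_cluster, bins = clustering.conservation_breadth(clusters, 4)
        assert per_cluster == {"c0": 2}  # only the conserved cluster counted
        assert bins["<=1/2"] == 1 and sum(bins.values()) == 1

    def test_no_conserved_clusters_empty_histogram(self):
        clusters = clustering.call_conserved([self._cluster(["spX"])])
        per_cluster, bins = clustering.conservation_breadth(clusters, 4)
        assert per_cluster == {} and sum(bins.values()) == 0
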