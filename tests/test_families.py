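"""k-mer similarity graph, MCL clustering and cross-group family summaries."""

from __future__ import annotations

import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import rand_score

from nlscan.families import (
    EUK_ARCHAEA_SHARED_DIFFERENT,
    PROKARYOTE_SHARED_DIFFERENT,
    SHARED_SAME_MOTIF,
    SimilarityGraph,
    family_motif_transition,
    group_sharing,
    mcl,
    pairwise_similarity,
)
from nlscan.proteome import ProteinRecord, StrainMetadata
from nlscan.simulate import generate_family_fixture

from conftest import STD


def prot(pid: str, seq: str, strain: str = "s") -> ProteinRecord:
    return ProteinRecord(pid, strain, seq)


def cosine_oracle(a: str, b: str, k: int = 3) -> float:
    """Hand-rolled k-mer tally + cosine, independent of the production path."""
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    dot = sum(ca[x] * cb[x] for x in ca)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb) if na and nb else 0.0


class TestSimilarity:
    def test_identical_sequences_weight_one(self):
        g = pairwise_similarity([prot("a", "MKVRRK" * 5), prot("b", "MKVRRK" * 5)])
        assert g.weight("a", "b") == pytest.approx(1.0)

    def test_disjoint_alphabets_no_edge(self):
        g = pairwise_similarity([prot("a", "A" * 30), prot("b", "G" * 30)])
        assert g.weight("a", "b") == 0.0
        assert not g.graph.has_edge("a", "b")

    def test_weights_match_kmer_cosine_oracle(self):
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list(STD), size=50)) for _ in range(6)]
        records = [prot(f"p{i}", s) for i, s in enumerate(seqs)]
        g = pairwise_similarity(records, threshold=0.0)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = cosine_oracle(seqs[i], seqs[j])
                got = g.weight(f"p{i}", f"p{j}")
                if expect > 0:
                    assert got == pytest.approx(expect, abs=1e-12)

    def test_short_sequence_kept_without_edges(self):
        g = pairwise_similarity([prot("a", "MK"), prot("b", "MKVRRK" * 5)])
        assert "a" in g.graph
        assert g.graph.degree("a") == 0

    def test_single_protein_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity([prot("a", "MKV")])


class TestMCL:
    @staticmethod
    def graph(edges) -> SimilarityGraph:
        g = nx.Graph()
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        return SimilarityGraph(graph=g)

    def test_two_disconnected_cliques(self):
        g = self.graph(
            [("a1", "a2", 0.9), ("a2", "a3", 0.9), ("a1", "a3", 0.9), ("b1", "b2", 0.9)]
        )
        part = mcl(g)
        assert set(part.families.values()) == {
            frozenset({"a1", "a2", "a3"}),
            frozenset({"b1", "b2"}),
        }

    def test_single_node_is_orphan(self):
        g = nx.Graph()
        g.add_node("only")
        part = mcl(SimilarityGraph(graph=g))
        assert part.families == {"F0001": frozenset({"only"})}
        assert part.orphans == {"F0001"}

    def test_planted_families_recovered_with_rand_one(self):
        proteins, _, truth = generate_family_fixture(seed=41)
        part = mcl(pairwise_similarity(proteins))
        ids = sorted(p.protein_id for p in proteins)
        planted_label = {
            pid: fam for fam, members in truth.families.items() for pid in members
        }
        assert rand_score(
            [planted_label[i] for i in ids], [part.assignment[i] for i in ids]
        ) == 1.0

    def test_output_is_partition(self):
        proteins, _, _ = generate_family_fixture(seed=8)
        part = mcl(pairwise_similarity(proteins))
        all_members = [pid for mem in part.families.values() for pid in mem]
        assert sorted(all_members) == sorted(p.protein_id for p in proteins)
        assert set(part.assignment) == set(all_members)

    def test_disjoint_union_equals_union_of_parts(self):
        g1 = self.graph([("a1", "a2", 0.8), ("a2", "a3", 0.7)])
        g2 = self.graph([("z1", "z2", 0.9)])
        both = self.graph(
            [("a1", "a2", 0.8), ("a2", "a3", 0.7), ("z1", "z2", 0.9)]
        )
        fams = lambda part: set(part.families.values())
        assert fams(mcl(both)) == fams(mcl(g1)) | fams(mcl(g2))

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl(self.graph([("a", "b", 0.5)]), inflation=1.0)


META = [
    StrainMetadata("bacteria-01", "bacteria", 4_000_000, 4000),
    StrainMetadata("planctomycetes-01", "planctomycetes", 7_000_000, 6000),
    StrainMetadata("archaea-01", "archaea", 3_000_000, 3000),
    StrainMetadata("fungi-01", "fungi", 30_000_000, 11000),
]


class TestGroupSharing:
    def test_planted_sharing_design_recovered(self):
        designs = (
            ("bacteria", "planctomycetes"),
            ("bacteria", "bacteria"),
            ("planctomycetes", "fungi", "fungi"),
        )
        proteins, meta, truth = generate_family_fixture(seed=4, family_designs=designs)
        part = mcl(pairwise_similarity(proteins))
        summary = group_sharing(part, proteins, meta)
        combos = {
            tuple(sorted(c)): v for c, v in summary.combination_counts.items()
        }
        assert combos == {
            ("bacteria", "planctomycetes"): (1, 2),
            ("bacteria",): (1, 2),
            ("fungi", "planctomycetes"): (1, 3),
        }

    def test_orphans_excluded(self):
        proteins = [
            prot("a1", "MKVRRKGHA" * 10, "bacteria-01"),
            prot("a2", "MKVRRKGHA" * 10, "planctomycetes-01"),
            prot("solo", "WWYYFFCCHH" * 10, "fungi-01"),
        ]
        part = mcl(pairwise_similarity(proteins))
        summary = group_sharing(part, proteins, META)
        assert frozenset({"fungi"}) not in summary.combination_counts
        assert summary.combination_counts[frozenset({"bacteria", "planctomycetes"})] == (1, 2)


class TestMotifTransition:
    @staticmethod
    def _two_member_family(groups: tuple[str, str]):
        strains = {"bacteria": "bacteria-01", "planctomycetes": "planctomycetes-01",
                   "archaea": "archaea-01", "fungi": "fungi-01"}
        seq = "MKVHGA" * 20
        proteins = [
            prot("m1", seq, strains[groups[0]]),
            prot("m2", seq, strains[groups[1]]),
        ]
        part = mcl(pairwise_similarity(proteins))
        assert len(part.non_orphan_families()) == 1
        return proteins, part

    COMPOSITE = {"PRRRK": 8.0, "KR.{10}KKKL": 21.0}

    def test_same_motif_across_groups(self):
        proteins, part = self._two_member_family(("bacteria", "planctomycetes"))
        hits = {"m1": {"PRRRK"}, "m2": {"PRRRK"}}
        df = family_motif_transition(part, hits, proteins, META, self.COMPOSITE)
        assert list(df["category"]) == [SHARED_SAME_MOTIF]
        assert df.loc[0, "complexity_min"] == df.loc[0, "complexity_max"] == 8.0

    def test_prokaryote_turnover_with_complexity_increase(self):
        proteins, part = self._two_member_family(("bacteria", "planctomycetes"))
        hits = {"m1": {"PRRRK"}, "m2": {"KR.{10}KKKL"}}
        df = family_motif_transition(part, hits, proteins, META, self.COMPOSITE)
        assert list(df["category"]) == [PROKARYOTE_SHARED_DIFFERENT]
        assert df.loc[0, "complexity_max"] > df.loc[0, "complexity_min"]

    def test_eukaryote_reach_classified_separately(self):
        proteins, part = self._two_member_family(("planctomycetes", "fungi"))
        hits = {"m1": {"PRRRK"}, "m2": {"KR.{10}KKKL"}}
        df = family_motif_transition(part, hits, proteins, META, self.COMPOSITE)
        assert list(df["category"]) == [EUK_ARCHAEA_SHARED_DIFFERENT]

    def test_single_group_family_excluded(self):
        strains = {"bacteria": "bacteria-01"}
        proteins = [
            prot("m1", "MKVHGA" * 20, "bacteria-01"),
            prot("m2", "MKVHGA" * 20, "bacteria-01"),
        ]
        part = mcl(pairwise_similarity(proteins))
        hits = {"m1": {"PRRRK"}, "m2": {"KR.{10}KKKL"}}
        df = family_motif_transition(part, hits, proteins, META, self.COMPOSITE)
        assert df.empty
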