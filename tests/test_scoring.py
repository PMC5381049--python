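"""Q-index normalization and the motif complexity score."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from nlscan.dialect import parse_motif
from nlscan.proteome import StrainMetadata
from nlscan.scan import AbundanceMatrix
from nlscan.scoring import (
    complexity,
    diversity_score,
    normalize_matrix,
    origin_score,
    q_index,
    q_profiles,
    score_table,
)


def make_matrix(counts: dict[str, dict[str, int]]) -> AbundanceMatrix:
    """counts[motif][strain] -> AbundanceMatrix with column-sum M (fine for
    scoring tests, which never rely on union semantics)."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    return AbundanceMatrix(counts=df, bearing_totals=df.sum(axis=0))


META = [
    StrainMetadata("b1", "bacteria", 4_000_000, 4000),
    StrainMetadata("b2", "bacteria", 5_000_000, 4500),
    StrainMetadata("pl1", "planctomycetes", 7_000_000, 6000),
    StrainMetadata("ar1", "archaea", 3_000_000, 3000),
    StrainMetadata("f1", "fungi", 30_000_000, 11000),
    StrainMetadata("f2", "fungi", 28_000_000, 10000),
]


class TestQIndex:
    def test_zero_abundance_gives_zero(self):
        assert q_index(0, 4000, 4_000_000) == 0.0

    def test_closed_form_spot_value(self):
        # log10(1000 * 1e6) = 9
        assert q_index(10, 1000, 10**6) == pytest.approx(10 / 9)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            q_index(5, 1, 1)
        with pytest.raises(ValueError):
            q_index(5, 0, 100)

    def test_linear_in_m(self):
        base = q_index(1, 5000, 6_000_000)
        for m in range(0, 40, 5):
            assert q_index(m, 5000, 6_000_000) == pytest.approx(m * base)

    def test_strictly_decreasing_in_n_and_g(self):
        gs = [10**6, 10**7, 10**8, 10**9]
        qs = [q_index(10, 4000, g) for g in gs]
        assert all(a > b for a, b in zip(qs, qs[1:]))
        ns = [1000, 5000, 20000, 100000]
        qs = [q_index(10, n, 10**7) for n in ns]
        assert all(a > b for a, b in zip(qs, qs[1:]))


class TestNormalize:
    def test_identical_counts_identical_metadata_identical_columns(self):
        a = make_matrix({"PRRRK": {"b1": 4, "b2": 4}})
        meta = [
            StrainMetadata("b1", "bacteria", 4_000_000, 4000),
            StrainMetadata("b2", "bacteria", 4_000_000, 4000),
        ]
        norm = normalize_matrix(a, meta)
        assert norm["b1"].equals(norm["b2"])

    def test_doubling_genome_changes_only_that_column(self):
        a = make_matrix({"PRRRK": {"b1": 4, "b2": 6}, "RKRKK": {"b1": 1, "b2": 2}})
        meta1 = [
            StrainMetadata("b1", "bacteria", 4_000_000, 4000),
            StrainMetadata("b2", "bacteria", 4_000_000, 4000),
        ]
        meta2 = [
            StrainMetadata("b1", "bacteria", 4_000_000, 4000),
            StrainMetadata("b2", "bacteria", 8_000_000, 4000),
        ]
        n1, n2 = normalize_matrix(a, meta1), normalize_matrix(a, meta2)
        assert n1["b1"].equals(n2["b1"])
        assert (n2["b2"] < n1["b2"]).all()

    def test_cell_matches_hand_recomputation(self):
        a = make_matrix({"PRRRK": {"b1": 7}})
        meta = [StrainMetadata("b1", "bacteria", 4_000_000, 4000)]
        norm = normalize_matrix(a, meta)
        assert norm.loc["PRRRK", "b1"] == pytest.approx(
            7 / math.log10(4000 * 4_000_000)
        )

    def test_missing_metadata_names_strain(self):
        a = make_matrix({"PRRRK": {"b1": 1, "mystery": 1}})
        with pytest.raises(ValueError, match="mystery"):
            normalize_matrix(a, [StrainMetadata("b1", "bacteria", 10**6, 1000)])

    def test_q_profiles_match_q_index(self):
        a = make_matrix({"PRRRK": {"b1": 3, "f1": 9}})
        meta = [META[0], META[4]]
        profiles = {p.strain_id: p for p in q_profiles(a, meta)}
        assert profiles["b1"].Q == pytest.approx(q_index(3, 4000, 4_000_000))
        assert profiles["f1"].Q == pytest.approx(q_index(9, 11000, 30_000_000))


class TestDiversity:
    @pytest.mark.parametrize(
        ("text", "score"),
        [
            ("PRRRK", 3.0),
            # RKRKK holds two residue types; the rule yields 2 for it
            ("RKRKK", 2.0),
            ("RPRRK", 3.0),
            ("KRPRP", 3.0),
            ("RKRRR", 2.0),
            ("P.KKKRK", 4.0),  # 3 residue types + 1 wildcard reward
        ],
    )
    def test_printed_values(self, text, score):
        assert diversity_score(parse_motif(text)) == score

    def test_wildcard_and_class_rewards(self):
        # 2 residue types + 2 wildcard elements + 2 class elements
        p = parse_motif("K[RK]{3,5}.{11,18}[RK]K.{2,3}K")
        assert diversity_score(p) == 2 + 2 * 1.0 + 2 * 0.5

    def test_data_independence(self):
        # diversity and length depend only on the pattern text
        p = parse_motif("KR.{10}KKKL")
        assert diversity_score(p) == 3 + 1.0


class TestOrigin:
    def test_bacteria_only_penalised(self):
        a = make_matrix({"QRKRQK": {m.strain_id: 0 for m in META} | {"b1": 3}})
        assert origin_score(parse_motif("QRKRQK"), a, META) == -5.0

    def test_archaea_only_penalised(self):
        a = make_matrix({"PRRRK": {m.strain_id: 0 for m in META} | {"ar1": 2}})
        assert origin_score(parse_motif("PRRRK"), a, META) == -5.0

    def test_absent_everywhere_is_control(self):
        a = make_matrix({"PRRRK": {m.strain_id: 0 for m in META}})
        assert origin_score(parse_motif("PRRRK"), a, META) == 0.0

    def test_planctomycete_only_is_control(self):
        a = make_matrix({"RRKGKEK": {m.strain_id: 0 for m in META} | {"pl1": 4}})
        assert origin_score(parse_motif("RRKGKEK"), a, META) == 0.0

    def test_bacteria_and_planctomycetes_is_control(self):
        a = make_matrix(
            {"PRRRK": {m.strain_id: 0 for m in META} | {"b1": 3, "pl1": 2}}
        )
        assert origin_score(parse_motif("PRRRK"), a, META) == 0.0

    def test_eukaryote_reward_uses_mean_over_all_fungi(self):
        # fungal counts 6 and 7.2 -> mean 6.6 -> 5 + 0.66 = 5.66
        a = make_matrix(
            {"PRRRK": {m.strain_id: 0 for m in META} | {"f1": 6, "f2": 7}}
        )
        assert origin_score(parse_motif("PRRRK"), a, META) == pytest.approx(
            5 + 6.5 / 10
        )

    def test_monotone_in_eukaryote_abundance(self):
        scores = []
        for count in (1, 5, 20, 80):
            a = make_matrix(
                {"PRRRK": {m.strain_id: 0 for m in META} | {"f1": count}}
            )
            scores.append(origin_score(parse_motif("PRRRK"), a, META))
        assert scores == sorted(scores)
        assert all(s >= 5.0 for s in scores)

    def test_unknown_motif_rejected(self):
        a = make_matrix({"PRRRK": {"b1": 1}})
        with pytest.raises(ValueError, match="RKRKK"):
            origin_score(parse_motif("RKRKK"), a, [META[0]])


class TestComplexity:
    def test_composite_is_sum_of_components(self):
        a = make_matrix({"PRRRK": {m.strain_id: 0 for m in META}})
        score = complexity(parse_motif("PRRRK"), a, META)
        assert score.composite == score.length_score + score.diversity_score
        assert score.origin_score == 0.0

    def test_eukaryote_mean_6_6_gives_13_66(self):
        # PRRRK: length 5 + diversity 3 + origin (5 + 6.6/10) = 13.66
        counts = {m.strain_id: 0 for m in META}
        counts["f1"], counts["f2"] = 6, 7  # mean 6.5
        a = make_matrix({"PRRRK": counts})
        score = complexity(parse_motif("PRRRK"), a, META)
        assert score.composite == pytest.approx(5 + 3 + 5.65)

    def test_score_table_sorted_and_deterministic(self, motifs):
        rng = np.random.default_rng(0)
        counts = {
            m.source_text: {meta.strain_id: int(rng.integers(0, 5)) for meta in META}
            for m in motifs
        }
        a = make_matrix(counts)
        t1 = score_table(motifs, a, META)
        t2 = score_table(motifs, a, META)
        assert t1.equals(t2)
        assert list(t1["composite"]) == sorted(t1["composite"])
        assert (
            t1["composite"] == t1["length"] + t1["diversity"] + t1["origin"]
        ).all()
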