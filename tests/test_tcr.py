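"""Rearrangement simulator: productivity rule, attempt bookkeeping,
clonotypes and repertoire statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq

from tecsuite.synthetic import LocusSpec, gen_germline_locus
from tecsuite.tcr import (
    GermlineLocus,
    Segment,
    clonotype,
    is_productive,
    rearrange_chain,
    saturation_stats,
    segment_usage,
    shannon_entropy,
    simulate_repertoire,
    simulate_thymocyte,
)


def oracle_is_productive(seq: str, v_len: int) -> bool:
    """Exhaustive scan over every ATG in the V portion and its frame."""
    for i in range(v_len - 2):
        if seq[i : i + 3] != "ATG":
            continue
        span = len(seq) - i
        if span < 3 or span % 3:
            continue
        protein = str(Seq(seq[i:]).translate())
        if "*" not in protein[:-1]:
            return True
    return False


class TestIsProductive:
    def test_stop_before_constant_end_fails(self):
        seq = "ATGAAATAA" + "AAA" * 5
        assert not is_productive(seq, "ATGAAA")

    def test_stop_free_orf_through_end_passes(self):
        seq = "ATGAAA" + "AAA" * 10
        assert is_productive(seq, "ATGAAA")

    def test_frame_must_reach_final_base(self):
        # ATG opens a stop-free frame but the span is not divisible by 3
        seq = "ATGAAAA"
        assert not is_productive(seq, "ATGA")

    def test_atg_outside_v_does_not_count(self):
        seq = "AAAAAA" + "ATGAAA"
        assert not is_productive(seq, "AAAAAA")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            is_productive("ATGNNN", "ATG")

    def test_agrees_with_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n = int(rng.integers(30, 300))
            seq = "".join(bases[rng.integers(0, 4, n)])
            v_len = int(rng.integers(3, n))
            assert is_productive(seq, seq[:v_len]) == oracle_is_productive(seq, v_len)


class TestRearrangeChain:
    def test_beta_uses_cassette_matching_attempt(self, locus):
        rng = np.random.default_rng(0)
        a1 = rearrange_chain("beta", locus, rng, attempt_index=1)
        a2 = rearrange_chain("beta", locus, rng, attempt_index=2)
        assert a1.segment_names["J"].startswith("TRBJ1")
        assert a1.segment_names["C"].startswith("TRBC1")
        assert a2.segment_names["J"].startswith("TRBJ2")
        assert a2.segment_names["C"].startswith("TRBC2")

    def test_zero_insertions_gives_exact_concatenation(self):
        segs = [
            Segment("V1", "beta", "V", None, "ATGAAA"),
            Segment("D1", "beta", "D", None, "GGG"),
            Segment("J1", "beta", "J", 1, "CCCTTT"),
            Segment("C1", "beta", "C", 1, "AAAGGG"),
            Segment("J2", "beta", "J", 2, "CCC"),
            Segment("C2", "beta", "C", 2, "AAA"),
        ]
        loc = GermlineLocus(segs)
        att = rearrange_chain("beta", loc, np.random.default_rng(0),
                              attempt_index=1, insertion_lambda=0.0)
        assert att.sequence == "ATGAAA" + "GGG" + "CCCTTT" + "AAAGGG"
        assert att.insertions == [0, 0]

    @pytest.mark.parametrize("chain,n_junctions", [("alpha", 1), ("beta", 2)])
    def test_mean_insertions_per_attempt(self, locus, chain, n_junctions):
        rng = np.random.default_rng(1)
        total = sum(
            sum(rearrange_chain(chain, locus, rng).insertions) for _ in range(4000)
        )
        mean = total / 4000
        # Poisson(4) per junction; SE of the mean ~ 2/sqrt(4000*n_junctions)
        assert mean == pytest.approx(4.0 * n_junctions, abs=0.25)

    def test_missing_segment_class_raises(self):
        loc = GermlineLocus([Segment("V1", "alpha", "V", None, "ATG")])
        with pytest.raises(Exception, match="requires"):
            rearrange_chain("alpha", loc, np.random.default_rng(0))


class TestSimulateThymocyte:
    def test_atg_free_locus_records_four_beta_no_alpha(self, atg_free_locus):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cell = simulate_thymocyte(atg_free_locus, rng)
            assert not cell.productive_pair
            assert len(cell.beta_attempts) == 4
            assert len(cell.alpha_attempts) == 0

    def test_allelic_exclusion_ordering(self, locus):
        rng = np.random.default_rng(2)
        for _ in range(200):
            cell = simulate_thymocyte(locus, rng)
            if cell.alpha_attempts:
                assert cell.beta_productive
            if cell.beta_productive:
                # rearrangement stops at the first productive beta attempt
                assert cell.beta_attempts[-1].productive
            assert cell.productive_pair == (
                cell.beta_productive and cell.alpha_productive
            )

    def test_beta_success_matches_closed_form(self, locus):
        """P(beta valid) = 1-(1-p1)(1-p2)(1-p1)(1-p2) with per-cassette
        per-attempt rates measured from the same run."""
        rep = simulate_repertoire(locus, 20000, seed=3)
        att = [a for t in rep.thymocytes for a in t.beta_attempts]
        p = {}
        for cas in (1, 2):
            sub = [a for a in att if a.attempt_index == cas]
            p[cas] = np.mean([a.productive for a in sub])
        expected = 1 - (1 - p[1]) ** 2 * (1 - p[2]) ** 2
        observed = np.mean([t.beta_productive for t in rep.thymocytes])
        se = np.sqrt(expected * (1 - expected) / len(rep.thymocytes))
        assert abs(observed - expected) < 3 * se + 1e-9


class TestSimulateRepertoire:
    def test_n_zero_disallowed(self, locus):
        with pytest.raises(ValueError):
            simulate_repertoire(locus, 0)

    def test_fixed_seed_reproducible(self, locus):
        r1 = simulate_repertoire(locus, 200, seed=42)
        r2 = simulate_repertoire(locus, 200, seed=42)
        assert [t.clonotype_beta for t in r1.thymocytes] == [
            t.clonotype_beta for t in r2.thymocytes
        ]
        s1, s2 = r1.summary(), r2.summary()
        assert s1 == s2

    def test_productive_mode_reaches_target(self, locus):
        rep = simulate_repertoire(locus, 25, mode="productive", seed=0)
        assert len(rep.productive) == 25
        assert rep.n_attempted >= 25

    def test_productive_mode_guard_on_sterile_locus(self, atg_free_locus):
        with pytest.raises(RuntimeError, match="attempts"):
            simulate_repertoire(atg_free_locus, 5, mode="productive", seed=0,
                                max_attempts=200)


class TestClonotype:
    def test_unproductive_attempt_rejected(self, atg_free_locus):
        att = rearrange_chain("beta", atg_free_locus, np.random.default_rng(0))
        with pytest.raises(ValueError):
            clonotype(att)

    def test_zero_insertion_alpha_junction_translation(self):
        # V = ATG + 9 codons (30 nt, frame-aligned), J = 9 nt, C = 9 nt
        v = "ATG" + "AAA" * 9  # M KKKKKKKKK
        j = "TGGTGGTGG"  # WWW
        c = "GGG" * 3
        loc = GermlineLocus([
            Segment("V1", "alpha", "V", None, v),
            Segment("J1", "alpha", "J", None, j),
            Segment("C1", "alpha", "C", None, c),
        ])
        att = rearrange_chain("alpha", loc, np.random.default_rng(0),
                              insertion_lambda=0.0)
        assert att.productive
        # junction window: last 9 nt of V (KKK) + first 9 of J (WWW)
        assert clonotype(att, flank_nt=9) == "KKKWWW"

    def test_identical_segments_and_insertions_share_clonotype(self, locus):
        rep = simulate_repertoire(locus, 3000, seed=9)
        seen = {}
        for t in rep.productive:
            att = next(a for a in t.beta_attempts if a.productive)
            key = (tuple(sorted(att.segment_names.items())), att.sequence)
            if key in seen:
                assert seen[key] == t.clonotype_beta
            seen[key] = t.clonotype_beta

    def test_matches_translate_and_slice_oracle(self, locus):
        rep = simulate_repertoire(locus, 2000, seed=13)
        checked = 0
        for t in rep.productive:
            att = next(a for a in t.alpha_attempts if a.productive)
            start = max(att.v_length - 9, att.orf_start)
            start += -(start - att.orf_start) % 3
            end = min(att.j_start + 9, len(att.sequence))
            end -= (end - att.orf_start) % 3
            expected = str(Seq(att.sequence[start:end]).translate())
            assert clonotype(att, 9) == expected
            checked += 1
        assert checked > 20


class TestRepertoireStats:
    def test_entropy_hand_values(self):
        assert shannon_entropy([1, 1, 1, 1]) == pytest.approx(2.0)
        assert shannon_entropy([5]) == 0.0
        assert shannon_entropy([2, 1, 1]) == pytest.approx(1.5)

    def test_entropy_invariant_to_relabelling(self):
        assert shannon_entropy([3, 2, 7]) == pytest.approx(shannon_entropy([7, 3, 2]))

    def test_usage_proportions_sum_to_one(self, locus):
        rep = simulate_repertoire(locus, 2000, seed=4)
        usage = segment_usage(rep.productive, "beta")
        sums = usage.groupby("segtype")["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_saturation_table_shape_and_monotone_entropy(self, locus):
        rep = simulate_repertoire(locus, 4000, seed=4)
        n_prod = len(rep.productive)
        sizes = [10, n_prod // 4, n_prod]
        tab = saturation_stats(rep, sizes, n_seeds=3, seed=0)
        assert set(tab["size"]) == set(sizes)
        mean_h = tab[tab.chain == "beta"].groupby("size")["entropy"].mean()
        assert mean_h.loc[sizes[0]] <= mean_h.loc[sizes[-1]]

    def test_oversized_subsample_rejected(self, locus):
        rep = simulate_repertoire(locus, 100, seed=4)
        with pytest.raises(ValueError, match="exceed"):
            saturation_stats(rep, [10**6], n_seeds=1)

    def test_unconditional_mean_beta_insertions(self, locus):
        rep = simulate_repertoire(locus, 20000, seed=5)
        assert rep.summary()["mean_insertions_per_beta_attempt"] == pytest.approx(
            8.0, abs=0.15
        )
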