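import math

import numpy as np
import pytest
from helpers import brute_force_candidates, brute_force_rank_scores, random_dna

from epiguide.io import BedRecord
from epiguide.library_design import (DesignConfig, GuideScorecard, OligoRecord,
                                     PositionWeightScorer, assemble_library,
                                     build_oligo, build_scorecard,
                                     extract_candidates, load_domain_intervals,
                                     rank_guides, select_guides)
from epiguide.offtarget import GenomeIndex, OffTargetHit
from conftest import make_candidate


# ---------------------------------------------------------------------------
# Domain loading

class TestLoadDomainIntervals:
    def test_domain_inside_transcript_is_kept_and_annotated(self, toy_transcripts):
        domains = [BedRecord("chr1", 100, 160, "domX", "0", "+")]
        out = load_domain_intervals(domains, {"domX": "catalytic"}, toy_transcripts)
        assert len(out) == 1
        assert out[0].gene_id == "geneA"
        assert out[0].transcript_ids == ("geneA.t1",)
        assert out[0].category == "catalytic"

    def test_domain_without_transcript_overlap_is_dropped(self, toy_transcripts):
        domains = [BedRecord("chr1", 250, 300, "domY", "0", "+")]
        assert load_domain_intervals(domains, {}, toy_transcripts) == []

    def test_unmapped_domain_name_falls_back_to_other(self, toy_transcripts):
        domains = [BedRecord("chr1", 100, 160, "mystery", "0", "+")]
        out = load_domain_intervals(domains, {}, toy_transcripts)
        assert out[0].category == "other"

    def test_overlap_count_matches_bruteforce_intersection(self, toy_transcripts):
        domains = [
            BedRecord("chr1", 100, 160, "d1", "0", "+"),   # in geneA
            BedRecord("chr1", 450, 470, "d2", "0", "-"),   # in geneB
            BedRecord("chr1", 210, 390, "d3", "0", "+"),   # in the gap
        ]
        spans = [(50, 200), (400, 500)]
        expected = sum(any(d.start < e and s < d.end for s, e in spans)
                       for d in domains)
        out = load_domain_intervals(domains, {}, toy_transcripts)
        assert len(out) == expected == 2

    def test_unknown_chromosome_is_skipped_with_warning(self, toy_transcripts,
                                                        caplog):
        genome = GenomeIndex({"chr1": "A" * 600})
        domains = [BedRecord("chrUn", 10, 60, "dZ", "0", "+")]
        with caplog.at_level("WARNING", logger="epiguide"):
            out = load_domain_intervals(domains, {}, toy_transcripts, genome)
        assert out == [] and "chrUn" in caplog.text


# ---------------------------------------------------------------------------
# Candidate extraction

def _interval(chrom, start, end, gene="geneA", cat="catalytic"):
    from epiguide.library_design import DomainInterval

    return DomainInterval(gene, "dom1", cat, chrom, start, end, "+", ("t1",))


class TestExtractCandidates:
    def test_single_planted_pam_yields_one_candidate(self):
        seq = "ACTA" + "GATATCATATACGATATCAT" + "TGG" + "ATA"
        genome = GenomeIndex({"chr1": seq})
        cands = extract_candidates(genome, _interval("chr1", 4, 27))
        assert len(cands) == 1
        (c,) = cands
        assert c.context30 == seq
        assert c.protospacer == "GATATCATATACGATATCAT"
        assert c.guide23 == c.protospacer + "TGG"
        assert c.strand == "+" and c.cut_position == 4 + 17

    def test_homopolymer_run_excludes_candidate(self):
        seq = "A" * 21 + "GG" + "A" * 7
        genome = GenomeIndex({"chr1": seq})
        cfg = DesignConfig(require_genomic_5prime_G=False)
        assert extract_candidates(genome, _interval("chr1", 0, 30), cfg) == []

    def test_interval_shorter_than_23nt_is_empty_not_error(self):
        genome = GenomeIndex({"chr1": "ACGT" * 20})
        assert extract_candidates(genome, _interval("chr1", 10, 30)) == []

    def test_context_with_N_is_excluded(self):
        seq = "ACTN" + "GATATCATATACGATATCAT" + "TGG" + "ATA"
        genome = GenomeIndex({"chr1": seq})
        assert extract_candidates(genome, _interval("chr1", 4, 27)) == []

    @pytest.mark.parametrize("require_g", [True, False])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_window_scan_oracle(self, seed, require_g):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 260)
        genome = GenomeIndex({"chr1": seq})
        a, b = 30, 230
        cfg = DesignConfig(require_genomic_5prime_G=require_g)
        got = {(c.start, c.strand, c.protospacer)
               for c in extract_candidates(genome, _interval("chr1", a, b), cfg)}
        assert got == brute_force_candidates(seq, a, b, 8, require_g)

    def test_5prime_g_required_by_default(self):
        seq = "ACTA" + "AATATCATATACGATATCAT" + "TGG" + "ATA"
        genome = GenomeIndex({"chr1": seq})
        assert extract_candidates(genome, _interval("chr1", 4, 27)) == []
        cfg = DesignConfig(require_genomic_5prime_G=False)
        cands = extract_candidates(genome, _interval("chr1", 4, 27), cfg)
        assert [c.protospacer for c in cands] == ["AATATCATATACGATATCAT"]


# ---------------------------------------------------------------------------
# On-target scoring

class TestOnTargetScorer:
    def test_zero_weights_score_half(self):
        scorer = PositionWeightScorer({})
        assert scorer("A" * 30) == 0.5

    def test_deterministic_for_identical_context(self):
        scorer = PositionWeightScorer()
        ctx = "AAAA" + "G" * 20 + "AGG" + "AAA"
        assert scorer(ctx) == scorer(ctx)

    def test_single_weight_gives_logistic_closed_form(self):
        w = 1.7
        scorer = PositionWeightScorer({(0, "G"): w})
        ctx_g = "G" + "A" * 29
        ctx_t = "T" + "A" * 29
        assert scorer(ctx_g) == pytest.approx(1 / (1 + math.exp(-w)))
        assert scorer(ctx_t) == 0.5

    def test_context_with_N_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            PositionWeightScorer()("N" * 30)


# ---------------------------------------------------------------------------
# Scorecards and ranking

def _hit(ctx, cfd):
    return OffTargetHit("chr1", 0, "+", "A" * 23, 1, ctx, cfd)


class TestBuildScorecard:
    def test_no_hits_gives_zero_counts_and_cfd(self, candidate_factory):
        card = build_scorecard(candidate_factory(), [], on_target=0.7)
        assert card.criteria() == (0.7, 0, 0.0, 0, 0.0, 0, 0.0)

    def test_two_exonic_hits_max_cfd(self, candidate_factory):
        card = build_scorecard(candidate_factory(),
                               [_hit("exonic", 0.3), _hit("exonic", 0.6)], 0.5)
        assert card.n_exonic_ot == 2 and card.max_cfd_exonic == 0.6

    def test_mixed_hits_match_direct_tally(self, candidate_factory, rng):
        contexts = ["exonic", "intronic", "intergenic"]
        hits = [_hit(contexts[rng.integers(3)], float(rng.random()))
                for _ in range(5)]
        card = build_scorecard(candidate_factory(), hits, 0.5)
        for ctx, n_attr, m_attr in [("exonic", "n_exonic_ot", "max_cfd_exonic"),
                                    ("intronic", "n_intronic_ot", "max_cfd_intronic"),
                                    ("intergenic", "n_intergenic_ot",
                                     "max_cfd_intergenic")]:
            sub = [h.cfd for h in hits if h.context == ctx]
            assert getattr(card, n_attr) == len(sub)
            assert getattr(card, m_attr) == (max(sub) if sub else 0.0)

    def test_unannotated_hit_is_an_error(self, candidate_factory):
        bare = OffTargetHit("chr1", 0, "+", "A" * 23, 1)
        with pytest.raises(ValueError):
            build_scorecard(candidate_factory(), [bare], 0.5)


def _card(factory, on, ex=0, cfd_ex=0.0, ps=None):
    cand = factory(protospacer=ps) if ps else factory()
    return GuideScorecard(cand, on, n_exonic_ot=ex, max_cfd_exonic=cfd_ex)


class TestRankGuides:
    def test_singleton_gets_rank_one(self, candidate_factory):
        out = rank_guides([_card(candidate_factory, 0.9)])
        assert out[0].rank_score == 1.0

    def test_full_tie_averages_to_one_point_five(self, candidate_factory):
        cards = [_card(candidate_factory, 0.5, ps="G" + "A" * 19),
                 _card(candidate_factory, 0.5, ps="G" + "C" * 19)]
        out = rank_guides(cards)
        assert [c.rank_score for c in out] == [1.5, 1.5]

    def test_three_guide_example_matches_hand_computation(self, candidate_factory):
        a = _card(candidate_factory, 0.8, ps="GAAAAAAAAAAAAAAAAAAA")
        b = _card(candidate_factory, 0.6, ps="GCCCCCCCCCCCCCCCCCCC")
        c = _card(candidate_factory, 0.7, ex=5, cfd_ex=0.4,
                  ps="GTTTTTTTTTTTTTTTTTTT")
        out = rank_guides([a, b, c])
        assert out == [a, b, c]
        # on-target ranks (1, 3, 2); exonic count/cfd (1.5, 1.5, 3) each;
        # four remaining criteria fully tied at rank 2
        assert a.rank_score == pytest.approx((1 + 1.5 + 1.5 + 4 * 2) / 7)
        assert b.rank_score == pytest.approx((3 + 1.5 + 1.5 + 4 * 2) / 7)
        assert c.rank_score == pytest.approx((2 + 3 + 3 + 4 * 2) / 7)

    def _random_cards(self, factory, rng, n):
        cards = []
        for i in range(n):
            ps = "G" + "".join("ACGT"[j] for j in rng.integers(0, 4, 19))
            cards.append(GuideScorecard(
                factory(protospacer=ps),
                on_target_score=float(rng.choice([0.2, 0.5, 0.8, rng.random()])),
                n_exonic_ot=int(rng.integers(0, 4)),
                n_intronic_ot=int(rng.integers(0, 4)),
                n_intergenic_ot=int(rng.integers(0, 4)),
                max_cfd_exonic=float(rng.choice([0.0, 0.3, rng.random()])),
                max_cfd_intronic=float(rng.choice([0.0, 0.3])),
                max_cfd_intergenic=float(rng.choice([0.0, 0.5])),
            ))
        return cards

    def test_matches_bruteforce_mean_of_ranks(self, candidate_factory, rng):
        for _ in range(25):
            cards = self._random_cards(candidate_factory, rng,
                                       int(rng.integers(3, 31)))
            rank_guides(cards)
            expected = brute_force_rank_scores([c.criteria() for c in cards])
            got = [c.rank_score for c in cards]
            assert got == pytest.approx(expected)

    def test_rank_scores_invariant_under_input_permutation(self,
                                                           candidate_factory, rng):
        cards = self._random_cards(candidate_factory, rng, 12)
        rank_guides(cards)
        baseline = {c.candidate.protospacer: c.rank_score for c in cards}
        perm = list(cards)
        rng.shuffle(perm)
        rank_guides(perm)
        assert {c.candidate.protospacer: c.rank_score for c in perm} == baseline

    def test_improving_on_target_never_worsens_rank(self, candidate_factory, rng):
        cards = self._random_cards(candidate_factory, rng, 10)
        rank_guides(cards)
        before = cards[0].rank_score
        cards[0].on_target_score = min(1.0, cards[0].on_target_score + 0.3)
        rank_guides(cards)
        assert cards[0].rank_score <= before


# ---------------------------------------------------------------------------
# Selection

class TestSelectGuides:
    def _cards(self, factory, specs):
        out = []
        for i, (cat, rank) in enumerate(specs):
            ps = "G" + format(i, "019d").replace("0", "A").replace("1", "C") \
                .replace("2", "G").replace("3", "T").replace("4", "A") \
                .replace("5", "C").replace("6", "G").replace("7", "T") \
                .replace("8", "A").replace("9", "C")
            card = GuideScorecard(factory(protospacer=ps, category=cat), 0.5)
            card.rank_score = rank
            out.append(card)
        return out

    def test_priority_category_fills_first(self, candidate_factory):
        specs = [("catalytic", r) for r in range(1, 7)] + \
                [("other", r) for r in range(1, 10)]
        cards = self._cards(candidate_factory, specs)
        sel = select_guides({"geneA": cards}, DesignConfig(guides_per_gene_k=11))
        cats = [c.candidate.category for c in sel["geneA"]]
        assert cats.count("catalytic") == 6 and cats.count("other") == 5
        other_ranks = [c.rank_score for c in sel["geneA"]
                       if c.candidate.category == "other"]
        assert other_ranks == [1, 2, 3, 4, 5]

    def test_small_gene_keeps_all_candidates(self, candidate_factory):
        cards = self._cards(candidate_factory, [("reader", r) for r in range(4)])
        sel = select_guides({"geneA": cards}, DesignConfig(guides_per_gene_k=11))
        assert len(sel["geneA"]) == 4

    def test_matches_bruteforce_sort_oracle(self, candidate_factory, rng):
        cats = ["catalytic", "reader", "dna_binding", "protein_interaction",
                "other"]
        specs = [(cats[rng.integers(5)], float(rng.integers(1, 8)))
                 for _ in range(30)]
        cards = self._cards(candidate_factory, specs)
        cfg = DesignConfig(guides_per_gene_k=11)
        sel = select_guides({"g": cards}, cfg)["g"]
        prio = {c: i for i, c in enumerate(cfg.domain_priority)}
        expected = sorted(cards, key=lambda c: (
            prio[c.candidate.category], c.rank_score, -c.on_target_score,
            c.candidate.protospacer))[:11]
        assert sel == expected

    def test_selection_size_is_min_k_and_candidates(self, candidate_factory, rng):
        for n in (1, 5, 11, 20):
            cards = self._cards(candidate_factory,
                                [("other", i + 1) for i in range(n)])
            sel = select_guides({"g": cards}, DesignConfig(guides_per_gene_k=11))
            assert len(sel["g"]) == min(11, n)

    def test_unknown_category_is_an_error(self, candidate_factory):
        card = GuideScorecard(candidate_factory(category="bogus"), 0.5)
        card.rank_score = 1.0
        with pytest.raises(ValueError, match="bogus"):
            select_guides({"g": [card]}, DesignConfig())


# ---------------------------------------------------------------------------
# Oligos and assembly

class TestBuildOligo:
    def test_concatenation_layout(self, candidate_factory):
        cand = candidate_factory(protospacer="G" + "ATC" * 6 + "A")
        oligo = build_oligo(cand, DesignConfig(), guide_id="x")
        assert len(oligo.sequence) == 60
        assert oligo.sequence[20:40] == cand.protospacer
        assert oligo.sequence[:20] == DesignConfig().flank_left

    def test_substitution_mode_forces_leading_G(self, candidate_factory):
        cand = candidate_factory(protospacer="ATATCATATACGATATCATA")
        cfg = DesignConfig(require_genomic_5prime_G=False)
        oligo = build_oligo(cand, cfg, guide_id="x")
        assert oligo.sequence[20:40] == "G" + cand.protospacer[1:]

    def test_non_g_guide_is_error_when_substitution_disabled(self,
                                                             candidate_factory):
        cand = candidate_factory(protospacer="ATATCATATACGATATCATA")
        with pytest.raises(ValueError, match="does not start with G"):
            build_oligo(cand, DesignConfig(), guide_id="x")

    def test_batch_of_guides_all_satisfy_invariants(self, candidate_factory, rng):
        seen = set()
        for _ in range(10):
            ps = "G" + "".join("ACGT"[j] for j in rng.integers(0, 4, 19))
            oligo = build_oligo(candidate_factory(protospacer=ps),
                                DesignConfig(), guide_id=ps)
            # OligoRecord.__post_init__ enforces length/G/BsmBI invariants
            assert oligo.sequence not in seen
            seen.add(oligo.sequence)

    def test_bad_flank_is_config_error(self):
        with pytest.raises(ValueError, match="BsmBI"):
            DesignConfig(flank_left="A" * 20)
        with pytest.raises(ValueError, match="20 nt"):
            DesignConfig(flank_right="CGTCTC")


class TestAssembleLibrary:
    def _selection(self, factory, n):
        sel = {}
        for g in range(9):
            cards = []
            for i in range(n):
                ps = "G" + format(g * n + i, "019b").replace("0", "A") \
                    .replace("1", "C")
                cards.append(GuideScorecard(
                    factory(protospacer=ps, gene_id=f"gene{g}"), 0.5))
            sel[f"gene{g}"] = cards
        return sel

    def test_row_count_and_nontargeting_fraction(self, candidate_factory):
        sel = self._selection(candidate_factory, 10)  # 90 targeting
        nt = ["G" + format(i, "019b").replace("0", "T").replace("1", "G")
              for i in range(10)]
        table = assemble_library(sel, nt, {}, DesignConfig())
        assert len(table) == 100
        assert (table["role"] == "non_targeting").mean() == pytest.approx(0.10)

    def test_duplicate_protospacer_raises_listing_collision(self,
                                                            candidate_factory):
        sel = self._selection(candidate_factory, 2)
        dup = sel["gene0"][0].candidate.protospacer
        with pytest.raises(ValueError, match="duplicate protospacer"):
            assemble_library(sel, [dup], {}, DesignConfig())

    def test_row_count_conserves_per_gene_selections(self, candidate_factory):
        sel = self._selection(candidate_factory, 3)
        nt = ["G" + format(i, "019b").replace("0", "T").replace("1", "G")
              for i in range(4)]
        pc = {"Pcna": ["G" + "TC" * 9 + "A"]}
        table = assemble_library(sel, nt, pc, DesignConfig())
        assert len(table) == sum(len(v) for v in sel.values()) + len(nt) + 1
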