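"""Motif machinery: windows, word enrichment, IUPAC climb, PWM comparison."""

from math import comb

import numpy as np
import pytest

from bindxpress.binding import IntersectedPeak
from bindxpress.io_formats import PeakRecord
from bindxpress.motifs import (
    IUPAC_CODES, MotifCandidate, PwmModel, canonical_word,
    class_unique_motifs, dinucleotide_shuffle, extract_windows,
    fisher_enrichment_p, generalize_word, iupac_regex, matches_iupac,
    pwm_compare, pwm_from_iupac, read_meme_motifs, reverse_complement,
    word_enrichment, words_equivalent, write_meme_motifs,
)
from bindxpress.synthetic import plant_motif, sample_iupac_instance


def ipeak(chrom, center):
    return IntersectedPeak(
        source=PeakRecord(chrom=chrom, start=center - 5, end=center + 5)
    )


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestWindows:
    def test_center_window_coordinates(self):
        genome = {"c": "A" * 10_000}
        (w,) = extract_windows([ipeak("c", 1000)], genome)
        assert (w.start, w.end) == (750, 1251)
        assert len(w.sequence) == 501

    def test_boundary_clipping(self):
        genome = {"c": "A" * 10_000}
        (w,) = extract_windows([ipeak("c", 100)], genome)
        assert (w.start, w.end) == (0, 351)

    def test_sequence_equals_genome_substring(self, rng):
        genome = {"c": random_seq(rng, 5000)}
        (w,) = extract_windows([ipeak("c", 2500)], genome)
        assert w.sequence == genome["c"][w.start:w.end]

    def test_missing_chromosome_named_in_error(self):
        with pytest.raises(KeyError, match="cX"):
            extract_windows([ipeak("cX", 100)], {"c": "ACGT" * 100})


class TestWordEnrichment:
    def test_perfect_separation_exact_hypergeometric(self, rng):
        word = "TGCGA"
        pos = [random_seq(rng, 40).replace(word, "AAAAA") + word
               for _ in range(10)]
        neg = []
        while len(neg) < 10:
            s = random_seq(rng, 40)
            if word not in s and reverse_complement(word) not in s:
                neg.append(s)
        cands = {c.word: c for c in word_enrichment(pos, neg, 5, 5)}
        c = cands[canonical_word(word)]
        assert c.pos_with == 10 and c.neg_with == 0
        assert c.fisher_p == pytest.approx(1 / comb(20, 10))

    def test_no_signal_word_never_outranks_separator(self, rng):
        # a word present equally in both sets has p >= 0.5
        p_equal = fisher_enrichment_p(5, 10, 5, 10)
        p_perfect = fisher_enrichment_p(10, 10, 0, 10)
        assert p_equal >= 0.5 > p_perfect

    def test_counts_match_naive_scan(self, rng):
        pos = [random_seq(rng, 30) for _ in range(8)]
        neg = [random_seq(rng, 30) for _ in range(8)]
        cands = word_enrichment(pos, neg, 3, 4)
        by_word = {c.word: c for c in cands}
        # naive per-sequence presence on either strand
        for c in list(by_word.values())[:200]:
            pw = sum(
                1 for s in pos
                if c.word in s or reverse_complement(c.word) in s
            )
            nw = sum(
                1 for s in neg
                if c.word in s or reverse_complement(c.word) in s
            )
            assert (c.pos_with, c.neg_with) == (pw, nw)
            assert c.e_value == pytest.approx(c.fisher_p * len(by_word))

    def test_strand_symmetry(self, rng):
        pos = [random_seq(rng, 40) for _ in range(6)]
        neg = [random_seq(rng, 40) for _ in range(6)]
        a = word_enrichment(pos, neg, 3, 5)
        b = word_enrichment(
            [reverse_complement(s) for s in pos],
            [reverse_complement(s) for s in neg], 3, 5,
        )
        assert {(c.word, c.pos_with, c.neg_with) for c in a} == \
            {(c.word, c.pos_with, c.neg_with) for c in b}

    def test_fisher_p_monotone_in_pos_with(self):
        ps = [fisher_enrichment_p(k, 20, 3, 20) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_k_range_truncated_to_shortest_sequence(self, caplog):
        with caplog.at_level("WARNING"):
            cands = word_enrichment(["ACGTA"], ["TTTTT"], 3, 8)
        assert max(len(c.word) for c in cands) == 5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            word_enrichment([], ["ACGT"])


class TestGeneralizeWord:
    def test_fixed_point_returned_unchanged(self, rng):
        word = "TGACGT"
        pos = [random_seq(rng, 20) + word for _ in range(8)]
        neg = []
        while len(neg) < 8:
            s = random_seq(rng, 26)
            if word not in s and reverse_complement(s).find(word) < 0:
                neg.append(s)
        seed = next(
            c for c in word_enrichment(pos, neg, 6, 6)
            if c.word == canonical_word(word)
        )
        out = generalize_word(seed, pos, neg)
        # already perfectly separating: no degenerate code can improve it
        assert out.fisher_p == seed.fisher_p

    def test_mixed_final_base_becomes_y(self, rng):
        # positives split between ...T and ...C endings: the climb should
        # widen the last base to Y (C/T)
        stem = "TGACG"
        pos = [random_seq(rng, 20) + stem + ("T" if i % 2 else "C")
               for i in range(10)]
        neg = []
        while len(neg) < 10:
            s = random_seq(rng, 26)
            if stem not in s and stem not in reverse_complement(s):
                neg.append(s)
        seed_word = canonical_word(stem + "T")
        seed = next(
            c for c in word_enrichment(pos, neg, 6, 6)
            if c.word == seed_word
        )
        out = generalize_word(seed, pos, neg)
        assert words_equivalent(out.word, stem + "Y")
        assert out.pos_with == 10

    def test_p_never_increases(self, rng):
        pos = [random_seq(rng, 30) for _ in range(6)]
        neg = [random_seq(rng, 30) for _ in range(6)]
        for seed in word_enrichment(pos, neg, 4, 4)[:10]:
            out = generalize_word(seed, pos, neg)
            assert out.fisher_p <= seed.fisher_p


class TestPwmCompare:
    def test_identical_pwm_scores_one_forward(self, rng):
        m = pwm_from_iupac("TGACGTCA", name="q")
        (match,) = pwm_compare(m, [PwmModel("t", m.matrix)])
        assert match.score == pytest.approx(1.0)
        assert match.offset == 0 and match.orientation == "+"

    def test_reverse_complement_detected(self):
        q = pwm_from_iupac("TTGACA", name="q")
        t = q.reverse_complement()
        (match,) = pwm_compare(q, [PwmModel("t", t.matrix)])
        assert match.score == pytest.approx(1.0)
        assert match.orientation == "-"

    def test_matches_exhaustive_scan_oracle(self, rng):
        def rand_pwm(name, length):
            m = rng.dirichlet(np.ones(4), size=length)
            return PwmModel(name, tuple(map(tuple, m)))

        def corr(a, b):
            if a.std() == 0 or b.std() == 0:
                return 0.0
            return float(np.corrcoef(a, b)[0, 1])

        q = rand_pwm("q", 6)
        t = rand_pwm("t", 9)
        (match,) = pwm_compare(q, [t])
        best = -2.0
        for orient, tm in (("+", t.array),
                           ("-", t.reverse_complement().array)):
            for off in range(-2, 6):
                qs, ts = max(0, -off), max(0, off)
                n = min(6 - qs, 9 - ts)
                if n < 4:
                    continue
                score = float(np.mean(
                    [corr(q.array[qs + i], tm[ts + i]) for i in range(n)]
                ))
                best = max(best, score)
        assert match.score == pytest.approx(best)

    def test_short_target_skipped_with_warning(self, caplog):
        q = pwm_from_iupac("ACGTAC")
        short = pwm_from_iupac("ACG")
        with caplog.at_level("WARNING"):
            assert pwm_compare(q, [short]) == []

    def test_meme_round_trip(self, tmp_path):
        motifs = [pwm_from_iupac("TGACGTMA", name="m1"),
                  pwm_from_iupac("CACGTG", name="m2")]
        p = tmp_path / "lib.meme"
        write_meme_motifs(motifs, p)
        back = read_meme_motifs(p)
        assert [m.name for m in back] == ["m1", "m2"]
        assert np.allclose(back[0].array, motifs[0].array)


class TestClassUniqueness:
    def _cand(self, word, e):
        return MotifCandidate(word, 5, 10, 0, 10, e / 100, e)

    def test_unique_and_shared_partition(self):
        per_class = {
            "activated": [self._cand("TGACGTCA", 1e-4)],
            "repressed": [self._cand("CACGTG", 1e-3)],
            "unchanged": [self._cand("CACGTG", 1e-3)],
        }
        got = class_unique_motifs(per_class, e_threshold=0.05)
        assert [c.word for c in got["activated_unique"]] == ["TGACGTCA"]
        assert got["repressed_unique"] == [] and got["unchanged_unique"] == []

    def test_significant_everywhere_is_shared(self):
        per_class = {
            c: [self._cand("CACGTG", 1e-3)]
            for c in ("activated", "repressed", "unchanged")
        }
        got = class_unique_motifs(per_class, e_threshold=0.05)
        assert [c.word for c in got["shared"]] == ["CACGTG"]
        assert not got["activated_unique"]

    def test_motif_match_allows_flank_overhang(self):
        from bindxpress.motifs import motif_match

        # core sub-word, reverse-complement, and flank-extended rediscovery
        assert motif_match("TGACGT", "TGACGTMA")
        assert motif_match("ACGTCA", "TGACGTMA")
        assert motif_match("ACGTCAD", "TGACGTMA")  # rc = HTGACGT
        # words that disagree inside the pattern do not match
        assert not motif_match("TGAGGTCA", "TGACGTMA")
        assert not motif_match("CCCCCC", "TGACGTMA")

    def test_iupac_equivalence_spans_strands(self):
        # ACGTCA is the reverse complement of TGACGT: same motif
        assert words_equivalent("ACGTCA", "TGACGT")
        assert not words_equivalent("ACGTCA", "ACGTCC")


class TestIupacAndShuffle:
    def test_matches_iupac_subword_containment(self):
        assert matches_iupac("TGACGT", "TGACGTMA")
        assert matches_iupac("ACGTCA", "TGACGTMA")  # via reverse complement
        assert not matches_iupac("TGACGTMA", "TGACGT")

    def test_sampled_instance_obeys_code_sets(self, rng):
        for _ in range(50):
            inst = sample_iupac_instance("NRYSWA", rng)
            for c, pat in zip(inst, "NRYSWA"):
                assert c in IUPAC_CODES[pat]

    def test_plant_motif_window_and_degenerate_base(self, rng):
        seq = "A" * 2000
        out = plant_motif(seq, 1000, "TGACGR", rng)
        assert len(out) == len(seq)
        hit = iupac_regex("TGACGR").search(out[750:1251])
        assert hit is not None
        assert out[750 + hit.start() + 5] in "AG"
        diff = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert len(diff) <= 6 and all(750 <= i < 1251 for i in diff)

    def test_plant_motif_out_of_bounds_rejected(self, rng):
        with pytest.raises(Exception):
            plant_motif("ACGT" * 50, 10, "TGACGT", rng)

    def test_plant_histogram_reproducible(self):
        seq = "A" * 1000
        def run(seed):
            r = np.random.default_rng(seed)
            counts = []
            for _ in range(200):
                out = plant_motif(seq, 500, "TGACGTMA", r)
                counts.append(len(iupac_regex("TGACGTMA").findall(out)))
            return counts
        assert run(5) == run(5)

    def test_dinucleotide_shuffle_preserves_counts(self, rng):
        seq = random_seq(rng, 300)
        shuf = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            from collections import Counter
            return Counter(zip(s, s[1:]))
        assert dinucs(shuf) == dinucs(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
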