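"""Target-design tests: scaffold pairing, local alignment (vs an independent
aligner), co-target window scan (vs brute force), flank extraction and IUPAC
consensus."""

import numpy as np
import pytest
from Bio import Align

from polyamp import (
    DataError,
    HomoeologHit,
    SubgenomeSequence,
    align_pair,
    build_targets,
    consensus_target,
    cotarget_regions,
    extract_flanks,
    pair_scaffolds,
    read_hits_tsv,
)
from conftest import make_site


def _hit(a="sA", b="sB", length=400, identity=0.95, a_start=0, b_start=0):
    return HomoeologHit(
        a_scaffold=a, b_scaffold=b, alignment_length=length, identity=identity,
        a_start=a_start, a_end=a_start + length, b_start=b_start,
        b_end=b_start + length,
    )


class TestPairScaffolds:
    def test_short_hit_ineligible(self):
        hits = [_hit(length=340, identity=1.0), _hit(b="sB2", length=360, identity=0.8)]
        pairing, unpaired, _ = pair_scaffolds(hits, min_len=350)
        assert pairing["sA"].b_scaffold == "sB2"
        assert not unpaired

    def test_boundary_length_exactly_350_ineligible(self):
        pairing, unpaired, _ = pair_scaffolds([_hit(length=350)], min_len=350)
        assert not pairing and unpaired == ["sA"]

    def test_best_by_identity_times_length(self):
        hits = [
            _hit(b="long_weak", length=800, identity=0.5),   # score 400
            _hit(b="short_strong", length=450, identity=0.99),  # score 445.5
        ]
        pairing, _, _ = pair_scaffolds(hits)
        assert pairing["sA"].b_scaffold == "short_strong"

    def test_tie_breaks_lexicographically_and_flags(self):
        hits = [_hit(b="sB2"), _hit(b="sB1")]
        pairing, _, ties = pair_scaffolds(hits)
        assert pairing["sA"].b_scaffold == "sB1"
        assert ties == {"sA"}

    def test_output_is_a_function_and_stable(self):
        hits = [_hit(b=f"sB{i}", length=360 + i) for i in range(4)]
        pairing, _, _ = pair_scaffolds(hits)
        assert len(pairing) == 1
        again, _, _ = pair_scaffolds(list(pairing.values()))
        assert again["sA"].b_scaffold == pairing["sA"].b_scaffold


class TestAlignPair:
    def _random_seq(self, rng, n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def test_identical_sequences(self):
        rng = np.random.default_rng(1)
        seq = self._random_seq(rng, 400)
        hit = align_pair(seq, seq)
        assert hit.alignment_length == 400
        assert hit.identity == 1.0
        assert (hit.a_start, hit.a_end) == (0, 400)

    def test_five_interior_differences(self):
        rng = np.random.default_rng(2)
        a = self._random_seq(rng, 400)
        positions = rng.choice(np.arange(50, 350), size=5, replace=False)
        b = list(a)
        for p in positions:
            b[p] = "ACGT"["ACGT".index(a[p]) - 1]
        hit = align_pair(a, "".join(b))
        assert hit.alignment_length == 400
        assert hit.identity == pytest.approx(395 / 400)

    def test_disjoint_alphabets_no_extension(self):
        hit = align_pair("A" * 50, "T" * 50)
        assert hit.alignment_length <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            align_pair("", "ACGT")

    def test_score_matches_independent_aligner(self):
        """Smith-Waterman score must equal Biopython's PairwiseAligner under
        the same scoring (+1 match, -1 mismatch, -2 per gap position)."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = self._random_seq(rng, 80)
            b = list(a)
            # mutate and delete a few positions to force gaps
            for p in rng.choice(np.arange(5, 75), size=6, replace=False):
                b[p] = "ACGT"[rng.integers(0, 4)]
            del b[40]
            b = "".join(b)
            hit = align_pair(a, b)
            matches = round(hit.identity * hit.alignment_length)
            span_a = hit.a_end - hit.a_start
            span_b = hit.b_end - hit.b_start
            gaps = 2 * hit.alignment_length - span_a - span_b
            mismatches = hit.alignment_length - gaps - matches
            score = matches - mismatches - 2 * gaps
            assert score == aligner.score(a, b)


class TestCotargetRegions:
    def _pairing(self, offset=0):
        return {"sA": _hit(a="sA", b="sB", length=5000, b_start=offset)}

    def test_spec_window_example(self):
        snps_a = [make_site("sA", p) for p in (100, 150)]
        snps_b = [make_site("sB", p) for p in (120, 160)]
        regions = cotarget_regions(snps_a, snps_b, self._pairing(), window=100)
        assert len(regions) == 1
        assert [s.position for s in regions[0].snps_a] == [100, 150]
        assert [s.position for s in regions[0].snps_b] == [120, 160]

    def test_single_b_snp_is_not_enough(self):
        snps_a = [make_site("sA", p) for p in (100, 150)]
        snps_b = [make_site("sB", 120)]
        assert not cotarget_regions(snps_a, snps_b, self._pairing(), window=100)

    def test_window_zero_requires_coincidence(self):
        snps_a = [make_site("sA", p) for p in (100, 150)]
        snps_b = [make_site("sB", p) for p in (100, 150)]
        regions = cotarget_regions(snps_a, snps_b, self._pairing(), window=0)
        assert not regions  # only one SNP coincides with each anchor
        regions = cotarget_regions(snps_a, snps_b, self._pairing(), window=50)
        assert len(regions) == 1

    def test_unpaired_scaffold_skipped(self):
        snps_a = [make_site("ghost", p) for p in (100, 150)]
        snps_b = [make_site("sB", p) for p in (100, 150)]
        assert not cotarget_regions(snps_a, snps_b, self._pairing(), window=100)

    def test_offset_mapping(self):
        # B scaffold coordinates shifted by +1000 through the hit
        snps_a = [make_site("sA", p) for p in (100, 150)]
        snps_b = [make_site("sB", p) for p in (1120, 1160)]
        regions = cotarget_regions(snps_a, snps_b, self._pairing(offset=1000), window=100)
        assert len(regions) == 1

    def test_agrees_with_bruteforce_window_scan(self):
        rng = np.random.default_rng(7)
        pos_a = sorted(int(p) for p in rng.choice(np.arange(1, 3000), 60, replace=False))
        pos_b = sorted(int(p) for p in rng.choice(np.arange(1, 3000), 60, replace=False))
        snps_a = [make_site("sA", p) for p in pos_a]
        snps_b = [make_site("sB", p) for p in pos_b]
        window = 100
        regions = cotarget_regions(snps_a, snps_b, self._pairing(), window=window)
        # brute force: for every anchor, O(n^2) membership scan
        expected = set()
        for anchor in pos_a:
            in_a = tuple(p for p in pos_a if abs(p - anchor) <= window)
            in_b = tuple(p for p in pos_b if abs(p - anchor) <= window)
            if len(in_a) >= 2 and len(in_b) >= 2:
                expected.add((frozenset(in_a), frozenset(in_b)))
        got = {
            (
                frozenset(s.position for s in r.snps_a),
                frozenset(s.position for s in r.snps_b),
            )
            for r in regions
        }
        assert got == expected


class TestExtractFlanks:
    def _ref(self, n=5000):
        rng = np.random.default_rng(5)
        return SubgenomeSequence("sA", "A", "".join("ACGT"[i] for i in rng.integers(0, 4, n)))

    def test_interior_snp(self):
        ref = self._ref()
        ex = extract_flanks(ref, make_site("sA", 1500), flank=1000)
        assert len(ex.sequence) == 2001
        assert ex.snp_offset == 1000
        assert ex.sequence[ex.snp_offset] == ref.sequence[1499]

    def test_left_clipped(self):
        ref = self._ref()
        ex = extract_flanks(ref, make_site("sA", 10), flank=1000)
        # 9 upstream bases exist + SNP + 1000 downstream
        assert len(ex.sequence) == 1010
        assert ex.snp_offset == 9

    def test_flank_zero_is_single_base(self):
        ref = self._ref()
        ex = extract_flanks(ref, make_site("sA", 42), flank=0)
        assert ex.sequence == ref.sequence[41]

    def test_outside_scaffold_rejected(self):
        with pytest.raises(DataError):
            extract_flanks(self._ref(100), make_site("sA", 101), flank=10)


class TestConsensus:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACAT", "ACRT"),   # A/G -> R
            ("ACGT", "ACGT", "ACGT"),   # identity
            ("ACGT", "AC-T", "ACgT"),   # gap column -> lower-case non-gap base
        ],
    )
    def test_examples(self, a, b, expected):
        assert consensus_target(a, b) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            consensus_target("ACGT", "ACG")

    def test_ambiguity_count_equals_hamming_distance(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(50, 200))
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            cons = consensus_target(a, b)
            hamming = sum(x != y for x, y in zip(a, b))
            ambiguities = sum(c in "RYSWKM" for c in cons)
            assert ambiguities == hamming


class TestBuildTargets:
    def test_targets_respect_length_band(self):
        rng = np.random.default_rng(13)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        a_ref = {"sA": SubgenomeSequence("sA", "A", seq)}
        b_seq = list(seq)
        b_seq[1500] = "A" if seq[1500] != "A" else "C"
        b_ref = {"sB": SubgenomeSequence("sB", "B", "".join(b_seq))}
        pairing = {"sA": _hit(a="sA", b="sB", length=3000)}
        snps_a = [make_site("sA", p) for p in (1400, 1450, 2600)]
        snps_b = [make_site("sB", p) for p in (1420, 1460)]
        regions = cotarget_regions(snps_a, snps_b, pairing, window=100)
        targets = build_targets(regions, a_ref, b_ref, pairing)
        assert targets
        for t in targets:
            assert 300 <= t.length <= 450
            assert t.snps_a and t.snps_b
            assert len(t.consensus) == t.length


def test_read_hits_tsv_round_trip(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "sA\tsB\t97.5\t400\t10\t0\t1\t400\t501\t900\t1e-50\t700\n"
        "sA\tsB2\t90.0\t360\t36\t0\t1\t360\t360\t1\t1e-40\t500\n"
    )
    hits = read_hits_tsv(str(path))
    assert hits[0].identity == pytest.approx(0.975)
    assert (hits[0].a_start, hits[0].a_end) == (0, 400)
    assert (hits[0].b_start, hits[0].b_end) == (500, 900)
    assert hits[1].strand == "-"
    assert hits[1].b_start == 0 and hits[1].b_end == 360
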