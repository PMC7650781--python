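"""Allele-balance classification and heterozygote-correction tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyamp import (
    BandModel,
    CorrectionConfig,
    DataError,
    allele_balance,
    balance_histogram,
    classify_band,
    correct_heterozygotes,
    expected_tetraploid_het,
    het_rate,
)
from conftest import make_matrix, make_site


class TestAlleleBalance:
    @pytest.mark.parametrize("ad, expected", [((90, 10), 0.90), ((50, 50), 0.50), ((0, 80), 0.0)])
    def test_reference_fraction(self, ad, expected):
        site = make_site(calls={"a": ((0, 1), ad)})
        assert allele_balance(site, "a") == pytest.approx(expected)

    def test_missing_ad_unassessable(self):
        site = make_site(calls={"a": ((0, 1), None)})
        assert allele_balance(site, "a") is None

    def test_zero_depth_unassessable(self):
        site = make_site(calls={"a": ((0, 1), (0, 0))})
        assert allele_balance(site, "a") is None


class TestBandModel:
    @pytest.mark.parametrize(
        "balance, label",
        [
            (0.50, "true_het"),       # classic diploid het / tetraploid homoeolog
            (0.25, "paralog_low"),
            (0.75, "paralog_high"),
            (0.95, "homozygote_ref"),
            (0.05, "homozygote_alt"),
            (0.30, "true_het"),       # lower-inclusive boundaries
            (0.70, "true_het"),       # 0.70 is inside the 30-70% band
            (0.80, "homozygote_ref"),
            (0.20, "paralog_low"),
            (0.0, "homozygote_alt"),
            (1.0, "homozygote_ref"),
        ],
    )
    def test_classification(self, balance, label):
        assert classify_band(balance) == label

    def test_every_balance_gets_exactly_one_label(self):
        model = BandModel()
        for b in np.linspace(0, 1, 1001):
            assert model.classify(float(b)) in {
                "homozygote_alt", "paralog_low", "true_het",
                "paralog_high", "homozygote_ref",
            }

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            classify_band(1.5)


def _het_matrix(specs):
    """specs: list of (ref_depth, alt_depth) per het call, one accession."""
    sites = [
        make_site(position=100 + i, calls={"a": ((0, 1), ad)})
        for i, ad in enumerate(specs)
    ]
    return make_matrix(sites, ["a"])


class TestCorrectHeterozygotes:
    def test_low_minor_fraction_rescored_to_major_homozygote(self):
        matrix = _het_matrix([(90, 10)])
        out, changes = correct_heterozygotes(matrix, CorrectionConfig(cutoff=0.20))
        assert out.sites[0].per_sample["a"].genotype == (0, 0)
        assert changes[0].minor_fraction == pytest.approx(0.10)

    def test_minor_allele_can_be_reference(self):
        matrix = _het_matrix([(10, 90)])
        out, _ = correct_heterozygotes(matrix, CorrectionConfig(cutoff=0.20))
        assert out.sites[0].per_sample["a"].genotype == (1, 1)

    def test_at_cutoff_unchanged(self):
        matrix = _het_matrix([(75, 25)])
        out, changes = correct_heterozygotes(matrix, CorrectionConfig(cutoff=0.20))
        assert out.sites[0].per_sample["a"].genotype == (0, 1)
        assert not changes

    def test_cutoff_zero_is_identity(self):
        matrix = _het_matrix([(99, 1), (50, 50), (90, 10)])
        out, changes = correct_heterozygotes(matrix, CorrectionConfig(cutoff=0.0))
        assert not changes
        assert out.n_het_calls() == matrix.n_het_calls()

    def test_het_without_ad_passes_through(self):
        site = make_site(calls={"a": ((0, 1), None)})
        matrix = make_matrix([site], ["a"])
        out, changes = correct_heterozygotes(matrix, CorrectionConfig(cutoff=0.25))
        assert out.sites[0].per_sample["a"].genotype == (0, 1)
        assert not changes

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_monotone_in_cutoff(self, seed):
        """Correction never increases het calls, is idempotent, and stricter
        cutoffs leave no more hets than lenient ones, on random matrices."""
        rng = np.random.default_rng(seed)
        specs = [
            (int(rng.integers(0, 100)), int(rng.integers(0, 100)))
            for _ in range(20)
        ]
        specs = [(r, a) for r, a in specs if r + a > 0]
        matrix = _het_matrix(specs)
        baseline = matrix.n_het_calls()
        counts = []
        for cutoff in (0.15, 0.20, 0.25):
            out, changes = correct_heterozygotes(matrix, CorrectionConfig(cutoff=cutoff))
            assert out.n_het_calls() == baseline - len(changes) <= baseline
            again, changes2 = correct_heterozygotes(out, CorrectionConfig(cutoff=cutoff))
            assert not changes2
            assert again.n_het_calls() == out.n_het_calls()
            counts.append(out.n_het_calls())
        assert counts[0] >= counts[1] >= counts[2]


class TestHetRate:
    def test_two_of_twenty(self):
        calls = {f"s": None}
        sites = []
        for i in range(20):
            gt = (0, 1) if i < 2 else (0, 0)
            sites.append(make_site(position=100 + i, calls={"a": (gt, None)}))
        matrix = make_matrix(sites, ["a"])
        assert het_rate(matrix, "a") == 10.0

    def test_extremes(self):
        hom = make_matrix([make_site(calls={"a": ((0, 0), None)})], ["a"])
        assert het_rate(hom, "a") == 0.0
        het = make_matrix([make_site(calls={"a": ((0, 1), None)})], ["a"])
        assert het_rate(het, "a") == 100.0

    def test_missing_calls_excluded_from_denominator(self):
        sites = [
            make_site(position=1, calls={"a": ((0, 1), None)}),
            make_site(position=2, calls={"a": (None, None)}),
            make_site(position=3, calls={"a": ((1, 1), None)}),
        ]
        assert het_rate(make_matrix(sites, ["a"]), "a") == 50.0

    def test_no_calls_is_error(self):
        matrix = make_matrix([make_site(calls={"a": (None, None)})], ["a"])
        with pytest.raises(DataError):
            het_rate(matrix, "a")


class TestBalanceHistogram:
    def test_all_mass_in_one_bin(self):
        matrix = _het_matrix([(50, 50)] * 7)
        counts = balance_histogram(matrix, "a", bins=20)
        assert counts[10] == 7 and counts.sum() == 7

    def test_two_nonzero_bins(self):
        matrix = _het_matrix([(10, 90), (90, 10)])
        counts = balance_histogram(matrix, "a", bins=20)
        assert counts[2] == 1 and counts[18] == 1

    def test_empty_accession_is_error(self):
        matrix = make_matrix([make_site(calls={"a": ((0, 1), None)})], ["a"])
        with pytest.raises(DataError):
            balance_histogram(matrix, "a")


class TestBinomialErrorOracle:
    """On a selfed diploid panel with the default substitution-error profile
    and ~100x depth, spurious het calls appear at roughly the binomial rate
    of the minor allele crossing the caller's 5% fraction threshold, and the
    0.20 minor-fraction correction removes essentially all of them."""

    def test_uncorrected_rate_bounded_below_by_binomial_and_correction_clears(self):
        from scipy import stats

        from polyamp import SimConfig, run_pipeline, simulate_panel
        from polyamp.amplicon_pipeline import reference_base
        from polyamp.simulator import DEFAULT_OTHER_RATE, full_error_matrix

        config = SimConfig(
            seed=47, n_targets=3, n_diploid_a=3, n_diploid_b=3, n_tetraploid=0,
            reads_per_target_per_accession=100, paralog_fraction=0.0,
        )
        sim = simulate_panel(config)
        pipe = run_pipeline(sim.r1, sim.r2, sim.truth.panel, sim.truth.consensus_targets)

        # corrected het rate < 1% per accession at cutoff 0.20
        corrected, _ = correct_heterozygotes(pipe.matrix, CorrectionConfig(cutoff=0.20))
        for acc in sim.truth.genotype_matrix.accession_ids:
            try:
                rate = het_rate(corrected, acc)
            except DataError:
                continue
            assert rate < 1.0

        # binomial oracle: per covered reference column, the chance of a
        # spurious het is at least P(Bin(depth, max outgoing base rate) >= k)
        # with k the 5% alt-count threshold (rate without the end-of-read
        # inflation is a lower bound).
        err = full_error_matrix()
        p_max = {
            x: max(err[(x, y)] for y in "ACGT" if y != x) for x in "ACGT"
        }
        assert min(p_max.values()) == DEFAULT_OTHER_RATE
        called_het = {
            (s.scaffold_id, s.position, acc)
            for s in pipe.matrix.sites
            for acc, call in s.per_sample.items()
            if call.is_het
        }
        observed = 0
        expected_lb = 0.0
        var_lb = 0.0
        n_columns = 0
        for tid, target in sim.truth.targets.items():
            pile = pipe.pileups[tid]
            for accmeta in sim.truth.panel:
                acc = accmeta.accession_id
                hap = sim.truth.haplotypes[(acc, tid)][0][1]
                counts = pile.counts[acc]
                for pos0 in range(len(target.consensus)):
                    ref = reference_base(target.consensus[pos0])
                    if hap[pos0] != ref:
                        continue  # only truth-reference columns
                    depth = int(counts[pos0].sum())
                    if depth < 20:
                        continue
                    n_columns += 1
                    k = int(np.ceil(0.05 * depth))
                    p = stats.binom.sf(k - 1, depth, p_max[ref])
                    expected_lb += p
                    var_lb += p * (1 - p)
                    observed += (tid, pos0 + 1, acc) in called_het
        assert n_columns > 1000
        assert observed >= expected_lb - 3 * np.sqrt(var_lb)


class TestExpectedTetraploidHet:
    def test_parental_mean_matches_printed_estimate(self):
        # diploid parents at 3.3% and 9.0% -> expected tetraploid rate 6.2%
        assert expected_tetraploid_het([3.3, 9.0]) == 6.2

    def test_single_parent_identity(self):
        assert expected_tetraploid_het([7.5]) == 7.5

    def test_zero_rates(self):
        assert expected_tetraploid_het([0.0, 0.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            expected_tetraploid_het([])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            expected_tetraploid_het([101.0])
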