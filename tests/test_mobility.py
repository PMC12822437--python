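"""Mobile-transcript identification: allele counting, the beta-binomial
Bayes factor against a numerical-integration oracle, detection rules,
abundance/index arithmetic and condition classification."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from graftmobile.mobility import (
    AlleleCount,
    TranscriptEvidence,
    call_mobile,
    classify_condition_specificity,
    hypergeometric_overlap,
    identify_mobile_transcripts,
    informative_sites,
    log10_bayes_factor,
    mobile_abundance,
    mobile_index,
    phr_dependence,
    site_allele_counts,
)
from graftmobile.synthetic import CONDITIONS
from graftmobile.variants import ReferenceSNPSet


def make_ref():
    ref = ReferenceSNPSet()
    ref.add("chr1", 100, "G", "T")
    return ref


class TestSiteAlleleCounts:
    def test_foreign_allele_counted(self):
        counts, skipped = site_allele_counts(
            {("chr1", 100): {"G": 48, "T": 2}}, make_ref(), "a"
        )
        assert skipped == 0
        (c,) = counts
        assert (c.n_foreign, c.n_total, c.n_other) == (2, 50, 0)

    def test_pure_local_pileup(self):
        counts, _ = site_allele_counts({("chr1", 100): {"G": 50}}, make_ref(), "a")
        assert counts[0].n_foreign == 0

    def test_third_allele_goes_to_other(self):
        counts, _ = site_allele_counts(
            {("chr1", 100): {"G": 48, "C": 2}}, make_ref(), "a"
        )
        (c,) = counts
        assert (c.n_foreign, c.n_other) == (0, 2)

    def test_unknown_site_skipped_with_count(self):
        counts, skipped = site_allele_counts(
            {("chr9", 1): {"G": 10}}, make_ref(), "a"
        )
        assert counts == [] and skipped == 1

    def test_genotype_b_swaps_local_and_foreign(self):
        counts, _ = site_allele_counts(
            {("chr1", 100): {"G": 48, "T": 2}}, make_ref(), "b"
        )
        assert counts[0].n_foreign == 48


def oracle_log10_bf(kh, nh, km, nm, prior_error=(1.0, 1.0),
                    prior_mobile=(1.0, 1.0)):
    """Numerical-integration oracle: integrate the binomial likelihoods over
    the Beta priors directly (binomial coefficients cancel in the ratio).
    The likelihood peak is passed as a breakpoint so quadrature keeps
    accuracy on sharply peaked integrands."""
    def marginal(k, n, a, b):
        value, _ = integrate.quad(
            lambda t: t ** k * (1 - t) ** (n - k) * stats.beta.pdf(t, a, b),
            0, 1,
            points=[k / n] if n > 0 else None,
            limit=200, epsabs=1e-300, epsrel=1e-12,
        )
        return value

    m_homo = marginal(km, nm, *prior_error)
    m_het = marginal(kh, nh, *prior_mobile)
    m_shared = marginal(kh + km, nh + nm, *prior_error)
    return math.log10(m_homo * m_het / m_shared)


class TestBayesFactor:
    def test_no_foreign_reads_favors_shared_error(self):
        r = log10_bayes_factor((0, 50), (0, 200))
        assert r.defined and r.log10_bf < 0

    def test_clear_mobility_exceeds_threshold(self):
        r = log10_bayes_factor((20, 50), (1, 1000))
        assert r.log10_bf > 1

    def test_matched_rates_favor_shared_error_model(self):
        # equal empirical rates must not look like mobility: the marginal
        # likelihoods penalize the extra free rate, so the factor is below
        # the detection threshold (oracle value ~ -1.70)
        r = log10_bayes_factor((1, 200), (1, 200))
        assert r.log10_bf < 0
        assert r.log10_bf == pytest.approx(oracle_log10_bf(1, 200, 1, 200),
                                           abs=1e-6)

    @pytest.mark.parametrize(
        "kh,nh,km,nm",
        [(0, 50, 0, 200), (20, 50, 1, 1000), (1, 200, 1, 200),
         (5, 60, 2, 500), (0, 10, 3, 30), (7, 7, 0, 100)],
    )
    def test_matches_numerical_integration_oracle(self, kh, nh, km, nm):
        expected = oracle_log10_bf(kh, nh, km, nm)
        assert log10_bayes_factor((kh, nh), (km, nm)).log10_bf == pytest.approx(
            expected, abs=1e-6
        )

    def test_informative_priors_match_oracle(self):
        priors = ((1.0, 99.0), (2.0, 10.0))
        got = log10_bayes_factor((8, 40), (2, 400), *priors).log10_bf
        assert got == pytest.approx(oracle_log10_bf(8, 40, 2, 400, *priors),
                                    abs=1e-6)

    def test_monotone_in_heterograft_foreign_count(self):
        values = [
            log10_bayes_factor((k, 50), (2, 500)).log10_bf for k in range(0, 51)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_zero_heterograft_coverage_flagged(self):
        r = log10_bayes_factor((0, 0), (1, 100))
        assert not r.defined and math.isnan(r.log10_bf)


class TestInformativeSites:
    def test_strict_threshold(self):
        results = [
            log10_bayes_factor(
                AlleleCount(("c", 1), 20, 50), AlleleCount(("c", 1), 1, 1000)
            ),
            log10_bayes_factor(
                AlleleCount(("c", 2), 0, 50), AlleleCount(("c", 2), 0, 1000)
            ),
        ]
        sites = informative_sites(results, threshold=1.0)
        assert sites == {("c", 1)}
        # exactly at the threshold is excluded
        assert informative_sites(results, threshold=results[0].log10_bf) == set()

    def test_empty_input(self):
        assert informative_sites([]) == set()


class TestCallMobile:
    @pytest.mark.parametrize(
        "counts,expected",
        [({"r1": 4, "r2": 5, "r3": 0}, True),
         ({"r1": 4, "r2": 0, "r3": 0}, False),
         ({"r1": 3, "r2": 3, "r3": 3}, False),  # strict > 3
         ({"r1": 4, "r2": 4}, True)],
    )
    def test_detection_rule(self, counts, expected):
        ev = TranscriptEvidence("t", "shoot_to_root", "NP7D", counts)
        assert call_mobile(ev) is expected

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError):
            TranscriptEvidence("t", "shoot_to_root", "NP7D", {})


class TestAbundanceAndIndex:
    def test_per_million_scaling(self):
        assert mobile_abundance([5], 1e6) == 5.0
        assert mobile_abundance([0, 0], 1e6) == 0.0

    def test_scaling_linearity(self):
        a = mobile_abundance([5, 7, 9], [2e6, 2e6, 2e6])
        b = mobile_abundance([10, 14, 18], [4e6, 4e6, 4e6])
        assert a == pytest.approx(b)

    def test_mobile_index_ratio(self):
        assert mobile_index(1.0, 4.0) == 0.25
        assert mobile_index(0.0, 4.0) == 0.0

    def test_zero_donor_abundance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mobile_index(1.0, 0.0)


class TestConditionClassification:
    @pytest.mark.parametrize(
        "detected,expected",
        [({"NP3D", "NP7D"}, "PSI-specific"),
         ({"NP7D"}, "PSI-specific"),
         ({"FP7D", "NP7DRP2D"}, "PSD-specific"),
         ({"FP7D"}, "PSD-specific"),
         ({"FP7D", "NP3D", "NP7D", "NP7DRP2D"}, "common"),
         ({"NP3D", "NP7DRP2D"}, "common"),
         (set(), "other")],
    )
    def test_categories(self, detected, expected):
        assert classify_condition_specificity(detected) == expected

    def test_partition_is_exhaustive_and_disjoint(self):
        # every one of the 16 detection patterns maps to exactly one category
        for r in range(5):
            for subset in itertools.combinations(CONDITIONS, r):
                category = classify_condition_specificity(set(subset))
                assert category in {
                    "PSI-specific", "PSD-specific", "common", "other"
                }
                if not subset:
                    assert category == "other"
                else:
                    assert category != "other"

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            classify_condition_specificity({"XP1D"})


class TestPhrDependence:
    def test_lost_in_mutant(self):
        dependent, retained = phr_dependence({"a", "b", "c", "d"}, {"a"})
        assert dependent == {"b", "c", "d"} and retained == 0.25

    def test_fully_retained(self):
        dependent, retained = phr_dependence({"a", "b"}, {"a", "b"})
        assert dependent == set() and retained == 1.0

    def test_empty_wildtype_rejected(self):
        with pytest.raises(ValueError):
            phr_dependence(set(), {"a"})


class TestHypergeometricOverlap:
    def test_complete_overlap_exact_probability(self):
        universe = [f"g{i}" for i in range(20)]
        a = set(universe[:5])
        p = hypergeometric_overlap(a, a, universe)
        assert p == pytest.approx(1.0 / math.comb(20, 5))

    def test_no_overlap_p_near_one(self):
        universe = [f"g{i}" for i in range(1000)]
        p = hypergeometric_overlap(universe[:5], universe[900:905], universe)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap({"x"}, {"a"}, {"a", "b"})


class TestEndToEndScreen:
    def test_screen_recovers_truth_on_small_data(self, small_truth,
                                                 small_observations):
        result = identify_mobile_transcripts(small_observations)
        assert result.mobile_set() == small_truth.mobile_transcripts()
        for direction in ("shoot_to_root", "root_to_shoot"):
            assert result.mobile_set(direction) == small_truth.mobile_transcripts(
                direction
            )

    def test_detected_conditions_match_truth(self, small_truth,
                                             small_observations):
        result = identify_mobile_transcripts(small_observations)
        truth_conditions = (
            small_truth.mobile_truth.groupby(["transcript", "direction"])[
                "condition"
            ].apply(set)
        )
        for (transcript, direction), expected in truth_conditions.items():
            assert result.detected_conditions(transcript, direction) == expected

    def test_mobile_index_tracks_transfer_rate(self, small_truth,
                                               small_observations):
        result = identify_mobile_transcripts(small_observations)
        detected = result.calls[result.calls["detected"]]
        rates = small_truth.mobile_truth.set_index(
            ["transcript", "condition", "direction"]
        )["rate"]
        for row in detected.itertuples():
            rate = rates.get((row.transcript, row.condition, row.direction))
            if rate is not None and row.foreign_reads_total >= 50:
                assert row.mobile_index == pytest.approx(rate, rel=0.35)

    def test_requires_heterograft_samples(self, small_observations):
        homo_only = small_observations[
            small_observations["scion_genotype"]
            == small_observations["rootstock_genotype"]
        ]
        with pytest.raises(ValueError, match="heterograft"):
            identify_mobile_transcripts(homo_only)
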