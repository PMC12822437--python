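"""Generators: seeded determinism, the substitution-error model, count
conservation, and the TRAP/DMS sampling contracts."""

import numpy as np
import pandas as pd
import pytest

from graftmobile import synthetic
from graftmobile.synthetic import (
    CONDITIONS,
    GraftSample,
    generate_accession_pair,
    generate_dms_experiment,
    generate_graft_experiment,
    generate_trap_experiment,
    reciprocal_design,
)


class TestAccessionPair:
    def test_seeded_determinism(self):
        a = generate_accession_pair(seed=1, n_transcripts=50, snp_density=0.01)
        b = generate_accession_pair(seed=1, n_transcripts=50, snp_density=0.01)
        pd.testing.assert_frame_equal(a.snp_table, b.snp_table)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)
        pd.testing.assert_frame_equal(a.mobile_truth, b.mobile_truth)
        assert a.genomes == b.genomes

    def test_snp_count_matches_binomial_expectation(self):
        density = 0.01
        truth = generate_accession_pair(
            seed=1, n_transcripts=200, snp_density=density, mean_length=1000
        )
        total_length = int(truth.annotation["length"].sum())
        expected = total_length * density
        sigma = np.sqrt(total_length * density * (1 - density))
        assert abs(len(truth.snp_table) - expected) < 3 * sigma

    def test_zero_density_yields_no_snps(self):
        truth = generate_accession_pair(seed=1, n_transcripts=20, snp_density=0.0)
        assert truth.snp_table.empty
        assert truth.mobile_truth.empty  # no SNP-bearing transcript is eligible

    def test_alleles_differ_at_every_snp(self, small_truth):
        assert (
            small_truth.snp_table["allele_a"] != small_truth.snp_table["allele_b"]
        ).all()

    def test_genomes_differ_exactly_at_snps(self, small_truth):
        acc_a, acc_b = small_truth.accessions
        diffs = []
        for contig, seq_a in small_truth.genomes[acc_a].items():
            seq_b = small_truth.genomes[acc_b][contig]
            for i, (x, y) in enumerate(zip(seq_a, seq_b), start=1):
                if x != y:
                    diffs.append((contig, i))
        expected = set(
            zip(small_truth.snp_table["contig"], small_truth.snp_table["pos"])
        )
        assert set(diffs) == expected

    def test_mobile_transcripts_are_nuclear_with_snps(self, small_truth):
        snp_transcripts = set(small_truth.nuclear_snp_table["transcript"])
        for t in small_truth.mobile_transcripts():
            assert t in snp_transcripts
        assert (small_truth.mobile_truth["rate"] > 0).all()

    def test_region_intervals_ordered_and_disjoint(self, small_truth):
        for row in small_truth.annotation.itertuples():
            regions = [
                (row.utr5_start, row.utr5_end),
                (row.cds_start, row.cds_end),
                (row.utr3_start, row.utr3_end),
            ]
            if row.strand == "-":
                regions = [(row.length - e + 1, row.length - s + 1)
                           for s, e in regions]
            (u5s, u5e), (cs, ce), (u3s, u3e) = regions
            assert u5s <= u5e < cs <= ce < u3s <= u3e  # 5'UTR < CDS < 3'UTR

    @pytest.mark.parametrize("density", [-0.1, 0.2, 0.5])
    def test_invalid_density_rejected(self, density):
        with pytest.raises(ValueError):
            generate_accession_pair(seed=1, n_transcripts=5, snp_density=density)

    def test_zero_transcripts_rejected(self):
        with pytest.raises(ValueError):
            generate_accession_pair(seed=1, n_transcripts=0)


class TestGraftExperiment:
    def test_seeded_determinism(self, small_truth):
        design = reciprocal_design(small_truth.accessions)
        a = generate_graft_experiment(small_truth, design, seed=5)
        b = generate_graft_experiment(small_truth, design, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_no_error_no_mobility_means_no_foreign_reads(self):
        truth = generate_accession_pair(
            seed=3, n_transcripts=30, snp_density=0.01, mobile_fraction=0.0
        )
        obs = generate_graft_experiment(
            truth, reciprocal_design(truth.accessions), error_rate=0.0, seed=4
        )
        assert (obs["n_foreign"] == 0).all()
        assert (obs["n_other"] == 0).all()

    def test_error_only_foreign_fraction_near_one_third_error(self):
        # foreign-looking reads at non-mobile sites come from substitution
        # error, uniform over the 3 non-template bases
        error = 0.005
        truth = generate_accession_pair(
            seed=7, n_transcripts=400, snp_density=0.01, mobile_fraction=0.0,
            organelle_fraction=0.0,
        )
        design = [GraftSample(truth.accessions[1], truth.accessions[0],
                              "FP7D", "root")]
        obs = generate_graft_experiment(
            truth, design, depth=100.0, error_rate=error, replicates=1, seed=8
        )
        total = int((obs["n_local"] + obs["n_foreign"] + obs["n_other"]).sum())
        p = error / 3.0
        observed = int(obs["n_foreign"].sum())
        sigma = np.sqrt(total * p * (1 - p))
        assert abs(observed - total * p) < 3 * sigma

    def test_count_conservation_and_poisson_depth(self, small_observations):
        depth = (
            small_observations["n_local"]
            + small_observations["n_foreign"]
            + small_observations["n_other"]
        )
        assert (depth >= 0).all()
        assert abs(depth.mean() - 50.0) < 1.0

    def test_mobile_transcripts_receive_foreign_reads(self, small_truth):
        # truth labels round-trip: every mobile transcript shows foreign
        # reads in at least one sample at high depth
        design = reciprocal_design(small_truth.accessions)
        obs = generate_graft_experiment(
            small_truth, design, depth=200.0, error_rate=0.0, seed=9
        )
        seen = set(obs.loc[obs["n_foreign"] > 0, "transcript"])
        assert small_truth.mobile_transcripts() <= seen

    def test_foreign_reads_only_in_truth_conditions_and_direction(self, small_truth):
        design = reciprocal_design(small_truth.accessions)
        obs = generate_graft_experiment(
            small_truth, design, depth=100.0, error_rate=0.0, seed=10
        )
        with_foreign = obs[obs["n_foreign"] > 0]
        truth_keys = set(
            zip(
                small_truth.mobile_truth["transcript"],
                small_truth.mobile_truth["condition"],
                small_truth.mobile_truth["direction"],
            )
        )
        for row in with_foreign.itertuples():
            direction = synthetic.DIRECTION_OF_TISSUE[row.tissue]
            assert row.scion_genotype != row.rootstock_genotype
            assert (row.transcript, row.condition, direction) in truth_keys

    def test_unknown_condition_rejected(self, small_truth):
        acc_a, acc_b = small_truth.accessions
        with pytest.raises(ValueError, match="condition"):
            generate_graft_experiment(
                small_truth, [GraftSample(acc_b, acc_a, "NP99D", "root")]
            )

    @pytest.mark.parametrize("kwargs", [
        {"error_rate": 0.05}, {"error_rate": -0.01}, {"replicates": 0},
    ])
    def test_invalid_parameters_rejected(self, small_truth, kwargs):
        design = reciprocal_design(small_truth.accessions)
        with pytest.raises(ValueError):
            generate_graft_experiment(small_truth, design, **kwargs)


class TestTrapExperiment:
    def test_untranslated_mobile_has_zero_ip_foreign_reads(self, small_truth,
                                                           small_observations):
        truth = small_truth
        truth_all_untranslated = synthetic.SyntheticTruth(
            **{**truth.__dict__,
               "translated_truth": {t: False for t in truth.translated_truth}}
        )
        ip = generate_trap_experiment(
            truth_all_untranslated, small_observations, 0.8, seed=1
        )
        mobile = truth.mobile_transcripts()
        assert (ip.loc[ip["transcript"].isin(mobile), "n_foreign"] == 0).all()

    def test_full_capture_preserves_translated_counts(self, small_truth,
                                                      small_observations):
        ip = generate_trap_experiment(
            small_truth, small_observations, capture_efficiency=1.0, seed=1
        )
        translated = {
            t for t, ok in small_truth.translated_truth.items() if ok
        }
        untouched = ~small_observations["transcript"].isin(
            set(small_truth.translated_truth) - translated
        )
        for col in ("n_local", "n_other"):
            assert (ip[col] == small_observations[col]).all()
        assert (
            ip.loc[untouched, "n_foreign"]
            == small_observations.loc[untouched, "n_foreign"]
        ).all()

    def test_half_thinning_halves_counts_within_3_sigma(self, small_truth,
                                                        small_observations):
        ip = generate_trap_experiment(
            small_truth, small_observations, capture_efficiency=0.5, seed=2
        )
        n = int(small_observations["n_local"].sum())
        observed = int(ip["n_local"].sum())
        sigma = np.sqrt(n * 0.5 * 0.5)
        assert abs(observed - n * 0.5) < 3 * sigma

    @pytest.mark.parametrize("eff", [0.0, -0.5, 1.5])
    def test_invalid_efficiency_rejected(self, small_truth, small_observations, eff):
        with pytest.raises(ValueError):
            generate_trap_experiment(small_truth, small_observations, eff)


class TestDmsExperiment:
    def test_paired_rate_zero_gives_zero_ac_mismatches(self):
        seq = "GACAGACACC"
        struct = "(((....)))"  # A/C at paired ends and in loop
        profile = generate_dms_experiment(
            struct, seq, depth=1000, rate_unpaired=0.05, rate_paired=0.0,
            seed=1, background_rate=0.0,
        )
        paired_ac = profile[(profile["paired"]) & (profile["base"].isin(["A", "C"]))]
        assert (paired_ac["mismatch"] == 0).all()
        gu = profile[~profile["base"].isin(["A", "C"])]
        assert (gu["mismatch"] == 0).all()

    def test_unpaired_rate_recovered_within_3_sigma(self):
        rate = 0.05
        depth = 10_000
        seq = "A" * 50
        profile = generate_dms_experiment(
            "." * 50, seq, depth=depth, rate_unpaired=rate, rate_paired=0.001,
            seed=2,
        )
        total = depth * 50
        observed = int(profile["mismatch"].sum())
        sigma = np.sqrt(total * rate * (1 - rate))
        assert abs(observed - total * rate) < 3 * sigma

    def test_seeded_determinism(self):
        args = dict(structure="..((...))", sequence="ACGACGCGU", depth=500,
                    rate_unpaired=0.04, rate_paired=0.004)
        a = generate_dms_experiment(seed=3, **args)
        b = generate_dms_experiment(seed=3, **args)
        pd.testing.assert_frame_equal(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            generate_dms_experiment("...", "ACGU", rate_unpaired=0.05,
                                    rate_paired=0.005)

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            generate_dms_experiment("....", "ACGU", rate_unpaired=0.005,
                                    rate_paired=0.05)
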