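"""cis-meQTL scan, SNP filters, dosage conversion and permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from oxewas import cis_pairs, cis_scan, dosage_from_probabilities, permutation_fdr, snp_filter
from oxewas import SimConfig, simulate_cohort


class TestSnpFilter:
    def test_maf_and_info_boundaries(self):
        meta = pd.DataFrame(
            {"maf": [0.04, 0.05, 0.5, 0.3], "info": [0.95, 0.95, 1.0, 0.8]},
            index=["low_maf", "boundary_maf", "clean", "boundary_info"],
        )
        kept = snp_filter(meta)
        assert kept == ["boundary_maf", "clean"]  # MAF >= 0.05 kept, INFO == 0.8 excluded


class TestDosageFromProbabilities:
    @pytest.mark.parametrize(
        "gp,expected",
        [((1, 0, 0), 0.0), ((0, 0, 1), 2.0), ((0.2, 0.5, 0.3), 1.1)],
    )
    def test_values(self, gp, expected):
        assert dosage_from_probabilities(np.array(gp)) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dosage_from_probabilities(np.array([-0.1, 0.6, 0.5]))

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            dosage_from_probabilities(np.array([0.5, 0.5, 0.5]))


class TestCisPairs:
    def _tables(self):
        manifest = pd.DataFrame(
            {"chromosome": ["chr1"], "position": [500_000]}, index=["cgA"]
        )
        meta = pd.DataFrame(
            {
                "chromosome": ["chr1", "chr1", "chr1", "chr2"],
                "position": [400_000, 600_000, 601_000, 500_000],
            },
            index=["in_left", "at_boundary", "outside", "other_chrom"],
        )
        return manifest, meta

    def test_window_inclusive_boundary(self):
        manifest, meta = self._tables()
        pairs = cis_pairs(manifest, meta, window_bp=100_000)
        assert set(pairs["snp"]) == {"in_left", "at_boundary"}
        assert pairs.set_index("snp").loc["at_boundary", "distance_bp"] == 100_000

    def test_empty_window_gives_empty_table(self):
        manifest, meta = self._tables()
        pairs = cis_pairs(manifest, meta.loc[["other_chrom"]], window_bp=100_000)
        assert pairs.empty


@pytest.fixture(scope="module")
def meqtl_cohort():
    cfg = SimConfig(
        n_samples=500, n_probes=50, n_snps=400,
        frac_true_cpg_effects=0.0, frac_cis_meqtl=0.2, meqtl_r2=0.3,
        disease_log_or_per_sd=0.0, n_triads=0,
        genome_length=5_000_000, seed=21,
    )
    return simulate_cohort(cfg)


class TestCisScan:
    def test_planted_meqtls_detected(self, meqtl_cohort):
        cohort, truth = meqtl_cohort
        scan = cis_scan(cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta)
        scan_idx = scan.set_index(["snp", "probe"])
        for snp, probe, _slope in truth.true_meqtl_pairs:
            assert scan_idx.loc[(snp, probe), "p"] < 1e-10

    def test_shuffled_dosage_is_null(self, meqtl_cohort, rng):
        cohort, truth = meqtl_cohort
        perm = rng.permutation(len(cohort.betas))
        dos = pd.DataFrame(cohort.dosages.to_numpy()[perm], index=cohort.dosages.index,
                           columns=cohort.dosages.columns)
        scan = cis_scan(cohort.betas, cohort.manifest, dos, cohort.snp_meta)
        assert (scan["p"] < 0.05).mean() < 0.10

    def test_sorted_by_probe_then_p(self, meqtl_cohort):
        cohort, _ = meqtl_cohort
        scan = cis_scan(cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta)
        for _, grp in scan.groupby("probe"):
            assert (np.diff(grp["p"].to_numpy()) >= 0).all()

    def test_slope_matches_simple_regression(self, meqtl_cohort):
        cohort, _ = meqtl_cohort
        scan = cis_scan(cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta)
        row = scan.iloc[0]
        x = cohort.dosages[row["snp"]].to_numpy()
        y = cohort.betas[row["probe"]].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert row["slope"] == pytest.approx(slope, rel=1e-8)


class TestPermutationFdr:
    def test_each_replicate_covers_each_probe(self, meqtl_cohort):
        cohort, _ = meqtl_cohort
        res = permutation_fdr(
            cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta,
            n_perm=3, seed=1,
        )
        probes_with_pairs = set(res.observed_min_p.index)
        for pm in res.perm_min_p:
            assert set(pm.index) == probes_with_pairs

    def test_joint_permutation_preserves_snp_covariance(self, meqtl_cohort, rng):
        cohort, _ = meqtl_cohort
        D = cohort.dosages.iloc[:, :20].to_numpy()
        perm = rng.permutation(D.shape[0])
        np.testing.assert_allclose(np.cov(D.T), np.cov(D[perm].T), atol=1e-12)

    def test_null_data_yields_no_discoveries(self):
        cfg = SimConfig(
            n_samples=200, n_probes=40, n_snps=300,
            frac_true_cpg_effects=0.0, frac_cis_meqtl=0.0,
            disease_log_or_per_sd=0.0, genome_length=3_000_000, seed=5,
        )
        cohort, truth = simulate_cohort(cfg)
        assert truth.true_meqtl_pairs == []
        res = permutation_fdr(
            cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta,
            n_perm=5, seed=2,
        )
        assert res.n_significant <= 2

    def test_detects_planted_with_sensible_threshold(self, meqtl_cohort):
        cohort, truth = meqtl_cohort
        scan = cis_scan(cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta)
        res = permutation_fdr(
            cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta,
            n_perm=5, seed=3, observed_scan=scan,
        )
        assert res.threshold_p is not None
        flagged = res.significant_records(scan)
        sig_probes = set(flagged.loc[flagged["significant"], "probe"])
        planted = truth.meqtl_probes()
        assert len(planted & sig_probes) / len(planted) >= 0.9

    def test_single_replicate_threshold_stable(self, meqtl_cohort):
        # n_perm=1 thresholds across seeds agree with the n_perm=10 threshold
        # within the replicate-to-replicate spread
        cohort, _ = meqtl_cohort
        scan = cis_scan(cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta)
        singles = [
            permutation_fdr(
                cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta,
                n_perm=1, seed=s, observed_scan=scan,
            ).threshold_p
            for s in range(5)
        ]
        t10 = permutation_fdr(
            cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta,
            n_perm=10, seed=99, observed_scan=scan,
        ).threshold_p
        assert all(t is not None for t in singles) and t10 is not None
        lo, hi = np.log10(min(singles)) - 1, np.log10(max(singles)) + 1
        assert lo <= np.log10(t10) <= hi

    def test_estimator_flag_accepted(self, meqtl_cohort):
        cohort, _ = meqtl_cohort
        res = permutation_fdr(
            cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta,
            n_perm=2, seed=4, estimator="perm_fraction",
        )
        assert res.estimator == "perm_fraction"
        with pytest.raises(ValueError):
            permutation_fdr(
                cohort.betas, cohort.manifest, cohort.dosages, cohort.snp_meta,
                n_perm=2, estimator="bogus",
            )
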