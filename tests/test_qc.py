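"""Sample/probe QC rules, quantile normalization and beta computation."""

import numpy as np
import pandas as pd
import pytest

from oxewas import IntensityData, compute_beta, probe_filter, quantile_normalize_by_type, sample_qc


def make_intensities(meth, unmeth=None, det=None, design=None):
    meth = pd.DataFrame(meth, dtype=float)
    meth.index = [f"S{i}" for i in range(meth.shape[0])]
    meth.columns = [f"cg{j}" for j in range(meth.shape[1])]
    if unmeth is None:
        unmeth = meth * 0 + 100.0
    else:
        unmeth = pd.DataFrame(np.asarray(unmeth, dtype=float), index=meth.index, columns=meth.columns)
    if det is None:
        det = meth * 0.0
    else:
        det = pd.DataFrame(np.asarray(det, dtype=float), index=meth.index, columns=meth.columns)
    if design is None:
        design = pd.Series("II", index=meth.columns)
    return IntensityData(meth, unmeth, det, design)


def meta_for(intens, **overrides):
    meta = pd.DataFrame(
        {"leukocyte_count": 6.0, "bisulphite_conversion_mean": 98.5},
        index=intens.samples,
    )
    for sample, vals in overrides.items():
        for k, v in vals.items():
            meta.loc[sample, k] = v
    return meta


class TestSampleQc:
    def test_low_pass_rate_excluded(self, rng):
        # 1000 probes, one sample with 98.4% detection pass rate
        det = np.zeros((3, 1000))
        det[1, :16] = 0.5  # 984/1000 pass
        intens = make_intensities(rng.random((3, 1000)) * 1000, det=det)
        kept, excl = sample_qc(intens, meta_for(intens))
        assert "S1" not in kept and set(kept) == {"S0", "S2"}
        assert excl.loc[excl["sample"] == "S1", "rule"].tolist() == ["pass_rate"]

    def test_high_leukocytes_excluded(self, rng):
        intens = make_intensities(rng.random((2, 10)) * 1000)
        meta = meta_for(intens, S0={"leukocyte_count": 10.5})
        kept, excl = sample_qc(intens, meta)
        assert kept == ["S1"]
        assert excl.iloc[0]["rule"] == "leukocytes"

    def test_clean_samples_all_kept(self, rng):
        intens = make_intensities(rng.random((4, 20)) * 1000)
        kept, excl = sample_qc(intens, meta_for(intens))
        assert kept == list(intens.samples)
        assert excl.empty

    def test_idempotent(self, rng):
        det = np.zeros((3, 200))
        det[0, :10] = 0.9
        intens = make_intensities(rng.random((3, 200)) * 1000, det=det)
        kept, _ = sample_qc(intens, meta_for(intens))
        sub = IntensityData(
            intens.methylated.loc[kept],
            intens.unmethylated.loc[kept],
            intens.detection_p.loc[kept],
            intens.design_type,
        )
        kept2, excl2 = sample_qc(sub, meta_for(intens).loc[kept])
        assert kept2 == kept and excl2.empty


class TestProbeFilter:
    @staticmethod
    def manifest(**rows):
        base = dict(
            chromosome="chr1", position=100, design_type="II",
            multi_mapping=False, nearest_common_snp_distance=np.nan,
            overlaps_cnv=False, autosomal=True,
        )
        return pd.DataFrame({k: {**base, **v} for k, v in rows.items()}).T

    def test_snp_window_boundary(self):
        man = self.manifest(
            at10={"nearest_common_snp_distance": 10},
            at11={"nearest_common_snp_distance": 11},
        )
        kept, excl = probe_filter(man)
        assert kept == ["at11"]
        assert excl.iloc[0]["rule"] == "snp_proximity"

    def test_non_autosomal_and_multimapping_excluded(self):
        man = self.manifest(
            chrX={"autosomal": False, "chromosome": "chrX"},
            multi={"multi_mapping": True},
            cnv={"overlaps_cnv": True},
            clean={},
        )
        kept, excl = probe_filter(man)
        assert kept == ["clean"]
        assert set(excl["rule"]) == {"non_autosomal", "multi_mapping", "cnv_overlap"}

    def test_idempotent(self):
        man = self.manifest(clean={}, multi={"multi_mapping": True})
        kept, _ = probe_filter(man)
        kept2, excl2 = probe_filter(man.loc[kept])
        assert kept2 == kept and excl2.empty


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        row = [5.0, 1.0, 3.0, 2.0]
        intens = make_intensities([row, row])
        out = quantile_normalize_by_type(intens)
        np.testing.assert_allclose(out.methylated.values, intens.methylated.values)

    def test_sorted_vectors_equal_across_samples(self, rng):
        intens = make_intensities(rng.random((5, 50)) * 1000)
        out = quantile_normalize_by_type(intens)
        sorted_rows = np.sort(out.methylated.values, axis=1)
        for i in range(1, 5):
            np.testing.assert_allclose(sorted_rows[i], sorted_rows[0])

    def test_toy_mean_of_order_statistics(self):
        # 3 samples x 4 probes; expected = mean of order statistics, mapped by rank
        vals = np.array([[4.0, 1.0, 3.0, 2.0], [40.0, 10.0, 30.0, 20.0], [8.0, 2.0, 6.0, 4.0]])
        intens = make_intensities(vals)
        out = quantile_normalize_by_type(intens)
        # order-statistic means: (1+10+2)/3, (2+20+4)/3, (3+30+6)/3, (4+40+8)/3
        target = np.array([13.0, 26.0, 39.0, 52.0]) / 3.0
        expected = np.array([target[[3, 0, 2, 1]], target[[3, 0, 2, 1]], target[[3, 0, 2, 1]]])
        np.testing.assert_allclose(out.methylated.values, expected)

    def test_rank_preserving_within_sample(self, rng):
        intens = make_intensities(rng.random((4, 30)) * 500)
        out = quantile_normalize_by_type(intens)
        for i in range(4):
            assert (
                np.argsort(out.methylated.values[i]).tolist()
                == np.argsort(intens.methylated.values[i]).tolist()
            )

    def test_types_normalized_separately(self, rng):
        design = pd.Series(["I"] * 10 + ["II"] * 10, index=[f"cg{j}" for j in range(20)])
        intens = make_intensities(rng.random((3, 20)) * 1000, design=design)
        out = quantile_normalize_by_type(intens)
        type1 = out.methylated.values[:, :10]
        np.testing.assert_allclose(np.sort(type1, axis=1)[1], np.sort(type1, axis=1)[0])


class TestComputeBeta:
    def test_zero_signal_gives_zero(self):
        intens = make_intensities([[0.0]], unmeth=[[0.0]])
        assert compute_beta(intens, offset=100).iloc[0, 0] == 0.0

    def test_arithmetic(self):
        intens = make_intensities([[300.0]], unmeth=[[100.0]])
        assert compute_beta(intens, offset=0).iloc[0, 0] == pytest.approx(0.75)
        assert compute_beta(intens, offset=100).iloc[0, 0] == pytest.approx(0.6)

    def test_negative_offset_rejected(self):
        intens = make_intensities([[1.0]])
        with pytest.raises(ValueError):
            compute_beta(intens, offset=-1)

    def test_monotone_in_methylated_signal(self):
        intens = make_intensities([[100.0], [200.0], [400.0]], unmeth=[[50.0], [50.0], [50.0]])
        betas = compute_beta(intens).iloc[:, 0].to_numpy()
        assert np.all(np.diff(betas) > 0)
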