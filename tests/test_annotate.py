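"""Island/gene-feature annotation and enrichment tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oxewas import assign_gene_features, assign_island_context, context_enrichment, overlap_permutation
from oxewas.annotate import annotate_probes


@pytest.fixture()
def islands():
    return pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_800]})


@pytest.fixture()
def transcripts():
    # one + strand and one - strand transcript with explicit sub-intervals
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "tss": [50_000, 90_000],
            "tes": [60_000, 80_000],
            "exon1_start": [50_000, 89_700],
            "exon1_end": [50_300, 90_000],
            "utr5_start": [50_000, 89_900],
            "utr5_end": [50_100, 90_000],
            "utr3_start": [59_800, 80_000],
            "utr3_end": [60_000, 80_200],
        },
        index=["TXP", "TXM"],
    )


class TestIslandContext:
    def test_inside_island(self, islands):
        assert assign_island_context(10_400, "chr1", islands) == "island"

    def test_shore_at_1500bp(self, islands):
        assert assign_island_context(10_800 + 1500, "chr1", islands) == "shore"

    @pytest.mark.parametrize(
        "offset,expected",
        [(2000, "shore"), (2001, "shelf"), (4000, "shelf"), (4001, "open_sea")],
    )
    def test_boundaries(self, islands, offset, expected):
        assert assign_island_context(10_800 + offset, "chr1", islands) == expected
        assert assign_island_context(10_000 - offset, "chr1", islands) == expected

    def test_unknown_chromosome_open_sea(self, islands, caplog):
        assert assign_island_context(500, "chr9", islands) == "open_sea"


class TestGeneFeatures:
    def test_upstream_150_plus_strand_is_tss200(self, transcripts):
        feats, collapsed = assign_gene_features(50_000 - 150, "chr1", transcripts)
        assert feats == {"TSS200"} and collapsed == "promoter"

    @pytest.mark.parametrize(
        "upstream,expected",
        [(200, "TSS200"), (201, "TSS1500"), (1500, "TSS1500")],
    )
    def test_upstream_boundaries(self, transcripts, upstream, expected):
        feats, _ = assign_gene_features(50_000 - upstream, "chr1", transcripts)
        assert expected in feats

    def test_upstream_1501_outside_promoter(self, transcripts):
        feats, collapsed = assign_gene_features(50_000 - 1501, "chr1", transcripts)
        assert collapsed == "intergenic"

    def test_minus_strand_upstream_is_to_the_right(self, transcripts):
        # 300 bp upstream of the - strand TSS at 90,000 means position 90,300
        feats, collapsed = assign_gene_features(90_300, "chr1", transcripts)
        assert feats == {"TSS1500"} and collapsed == "promoter"

    def test_no_transcript_is_intergenic(self, transcripts):
        feats, collapsed = assign_gene_features(5, "chr1", transcripts)
        assert feats == set() and collapsed == "intergenic"

    def test_body_and_utr3(self, transcripts):
        feats, collapsed = assign_gene_features(55_000, "chr1", transcripts)
        assert feats == {"body"} and collapsed == "body"
        feats, collapsed = assign_gene_features(59_900, "chr1", transcripts)
        assert feats == {"3UTR"} and collapsed == "3UTR"


def fisher_enumeration_oracle(a, b, c, d, sidedness="two_sided"):
    """Exact Fisher p by explicit enumeration over tables with fixed margins."""
    N = a + b + c + d
    r1, c1 = a + b, a + c
    kmin, kmax = max(0, r1 + c1 - N), min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, N, c1, r1)
    obs = stats.hypergeom.pmf(a, N, c1, r1)
    if sidedness == "two_sided":
        return float(pmf[pmf <= obs * (1 + 1e-9)].sum())
    if sidedness == "greater":
        return float(pmf[support >= a].sum())
    return float(pmf[support <= a].sum())


class TestFisherPrimitive:
    def test_matches_scipy_on_random_tables(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        from oxewas.annotate import fisher_exact_2x2

        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 25, size=4))
            for mode, alt in (("two_sided", "two-sided"), ("greater", "greater"), ("less", "less")):
                _, p = fisher_exact_2x2(a, b, c, d, mode)
                _, p_ref = scipy_fisher([[a, b], [c, d]], alternative=alt)
                assert p == pytest.approx(p_ref, abs=1e-10)


class TestEnrichment:
    def _labels(self, contexts):
        return pd.DataFrame({"island_context": contexts}, index=[f"p{i}" for i in range(len(contexts))])

    def test_counts_partition_background(self):
        contexts = ["island"] * 10 + ["shore"] * 20 + ["open_sea"] * 70
        labels = self._labels(contexts)
        assoc = set(labels.index[:15])
        table = context_enrichment(assoc, set(labels.index), labels)
        assert (table["a"] + table["c"]).sum() == 100

    def test_table_matches_enumeration_oracle(self):
        # (8, 2, 10, 80): assoc-and-shore etc.
        contexts = ["shore"] * 18 + ["open_sea"] * 82
        labels = self._labels(contexts)
        assoc = set(list(labels.index[:8]) + list(labels.index[18:20]))
        for sided in ("two_sided", "greater", "less"):
            table = context_enrichment(assoc, set(labels.index), labels, sidedness=sided)
            row = table.loc["shore"]
            assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 10, 80)
            assert row["p"] == pytest.approx(
                fisher_enumeration_oracle(8, 2, 10, 80, sided), rel=1e-10
            )

    def test_shore_excess_gives_or_above_one(self):
        contexts = ["shore"] * 30 + ["open_sea"] * 70
        labels = self._labels(contexts)
        assoc = set(labels.index[:20])  # all shores
        table = context_enrichment(assoc, set(labels.index), labels)
        assert table.loc["shore", "odds_ratio"] > 1

    def test_empty_association_rejected(self):
        labels = self._labels(["island"] * 5)
        with pytest.raises(ValueError):
            context_enrichment(set(), set(labels.index), labels)


class TestOverlapPermutation:
    def test_all_true_annotation_gives_p_one(self):
        ann = pd.Series(True, index=[f"p{i}" for i in range(50)])
        p, obs, _ = overlap_permutation({"p0", "p1"}, ann, n_random=200, seed=0)
        assert p == 1.0 and obs == 2

    def test_exclusive_annotation_gives_minimal_p(self):
        ann = pd.Series(False, index=[f"p{i}" for i in range(500)])
        assoc = {"p0", "p1", "p2"}
        ann[list(assoc)] = True
        p, obs, _ = overlap_permutation(assoc, ann, n_random=999, seed=0)
        assert obs == 3
        assert p == pytest.approx(1 / 1000)

    def test_enriched_overlap_matches_binomial_tail_scale(self):
        # 10% background rate, observed 23% overlap in a 100-probe set
        rng = np.random.default_rng(5)
        ann = pd.Series(False, index=[f"p{i}" for i in range(5000)])
        ann.iloc[:500] = True
        assoc = set(f"p{i}" for i in range(23)) | set(f"p{i}" for i in range(600, 677))
        p, obs, _ = overlap_permutation(assoc, ann, n_random=2000, seed=9)
        assert obs == 23
        binom_tail = stats.binom.sf(22, 100, 0.1)
        assert p < 0.01
        assert p == pytest.approx(binom_tail, abs=3 * np.sqrt(binom_tail / 2000) + 2e-3)

    def test_p_bounded_by_convention(self):
        ann = pd.Series([True, False] * 25, index=[f"p{i}" for i in range(50)])
        p, _, _ = overlap_permutation({"p0"}, ann, n_random=99, seed=1)
        assert 1 / 100 <= p <= 1.0


def test_annotation_contexts_partition_probes(null_cohort=None):
    from oxewas import SimConfig, simulate_cohort

    cohort, _ = simulate_cohort(SimConfig(n_samples=20, n_probes=150, n_snps=50, seed=3,
                                          genome_length=2_000_000))
    labels = annotate_probes(cohort.manifest, cohort.islands, cohort.transcripts)
    assert len(labels) == 150
    assert labels["island_context"].isin(["island", "shore", "shelf", "open_sea"]).all()
    counts = labels["island_context"].value_counts().sum()
    assert counts == 150
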