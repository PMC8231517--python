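"""Tests for subsampling, detection curves and the expression-variation
statistic, against hypergeometric / combinatorial oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import depthsat as ds
from depthsat.errors import ConfigError

from conftest import make_catalog, make_reads

# Fraction ladder and library size of the published-scale desk check: the
# subset-size rule must reproduce the full printed column exactly.
REFERENCE_LIBRARY = 48_495_343
REFERENCE_LADDER = {
    1.0: 48_495_343,
    0.9: 43_645_809,
    0.8: 38_796_274,
    0.7: 33_946_740,
    0.6: 29_097_206,
    0.5: 24_247_672,
    0.4: 19_398_137,
    0.3: 14_548_603,
    0.2: 9_699_069,
    0.1: 4_849_534,
    0.05: 2_424_767,
}


class TestSubsetSize:
    @pytest.mark.parametrize("fraction,expected", sorted(REFERENCE_LADDER.items()))
    def test_reference_ladder(self, fraction, expected):
        assert ds.subset_size(REFERENCE_LIBRARY, fraction) == expected

    def test_half_up_on_exact_half(self):
        # 48,495,343 * 0.5 = 24,247,671.5 -> rounds up
        assert ds.subset_size(REFERENCE_LIBRARY, 0.5) == 24_247_672

    def test_identity_at_fraction_one(self):
        assert ds.subset_size(100, 1.0) == 100

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.01])
    def test_out_of_range_fraction(self, fraction):
        with pytest.raises(ConfigError):
            ds.subset_size(100, fraction)

    @given(
        total=st.integers(min_value=1, max_value=10**9),
        fraction=st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_monotonicity(self, total, fraction):
        n = ds.subset_size(total, fraction)
        assert 0 <= n <= total
        assert n >= ds.subset_size(total, fraction / 2)


class TestSeedSchedule:
    def test_replicate_seeds_distinct(self):
        spec = ds.SubsetSpec(fractions=(0.9, 0.5), n_replicates=10, base_seed=42)
        seeds = {
            spec.replicate_seed(fi, r)
            for fi in range(len(spec.fractions))
            for r in range(spec.n_replicates)
        }
        assert len(seeds) == 20


class TestSubsampleReads:
    def test_fraction_one_reproduces_input_counts(self, toy_catalog):
        reads = make_reads(["g1"] * 5 + ["g2"] * 3 + [None] * 2)
        spec = ds.SubsetSpec(fractions=(1.0,), n_replicates=3, base_seed=1)
        reps = ds.subsample(reads, toy_catalog, spec)
        ref = ds.count_reads(reads, toy_catalog)["sample"]
        for rep in reps:
            pd.testing.assert_series_equal(rep.counts, ref, check_names=False)
            assert rep.n_total_reads == 10
            assert rep.n_mapped_reads == 8

    def test_hypergeometric_mean_oracle(self):
        """Gene with 50 of 1000 reads, fraction 0.1: mean subset count over
        2000 replicates within 3 standard errors of n*c/N = 5."""
        catalog = make_catalog([1, 1])
        reads = make_reads(["g1"] * 50 + ["g2"] * 950)
        spec = ds.SubsetSpec(fractions=(0.1,), n_replicates=2000, base_seed=7)
        reps = ds.subsample(reads, catalog, spec)
        values = np.array([rep.counts["g1"] for rep in reps], dtype=float)
        var = stats.hypergeom(1000, 50, 100).var()
        se = math.sqrt(var / len(values))
        assert abs(values.mean() - 5.0) < 3 * se

    def test_distinct_seeds_give_distinct_subsets(self):
        """Two replicates at fraction 0.5 of 10 reads coincide with
        probability 1/C(10,5) ~ 0.4%; over 20 trials at least one pair must
        differ (failure probability ~ 0.004^20)."""
        catalog = make_catalog([1] * 10)
        reads = make_reads([f"g{i + 1}" for i in range(10)])
        differed = 0
        for base in range(20):
            spec = ds.SubsetSpec(fractions=(0.5,), n_replicates=2, base_seed=base * 100)
            a, b = ds.subsample(reads, catalog, spec)
            if not a.counts.equals(b.counts):
                differed += 1
        assert differed > 0

    def test_empty_reads_error(self, toy_catalog):
        with pytest.raises(ConfigError):
            ds.subsample(make_reads([]), toy_catalog, ds.SubsetSpec(fractions=(0.5,)))

    def test_conservation(self, medium_data):
        for rep in medium_data["replicates"]:
            assert rep.counts.sum() == rep.n_mapped_reads
            assert rep.n_mapped_reads <= rep.n_total_reads


class TestSubsampleCounts:
    def test_deterministic_split(self):
        counts = pd.Series([10, 0], index=pd.Index(["g1", "g2"], name="gene_id"))
        spec = ds.SubsetSpec(fractions=(0.5,), n_replicates=5, base_seed=3)
        for rep in ds.subsample_counts(counts, spec):
            assert rep.counts["g1"] == 5
            assert rep.counts["g2"] == 0

    def test_fraction_one_unchanged(self):
        counts = pd.Series([7, 3, 90], index=pd.Index(list("abc"), name="gene_id"))
        rep = ds.subsample_counts(
            counts, ds.SubsetSpec(fractions=(1.0,), n_replicates=1)
        )[0]
        pd.testing.assert_series_equal(rep.counts, counts, check_names=False)

    def test_unmapped_bucket_scales_subset(self):
        counts = pd.Series([10], index=pd.Index(["g1"], name="gene_id"))
        rep = ds.subsample_counts(
            counts, ds.SubsetSpec(fractions=(0.5,), n_replicates=1), n_unmapped=90
        )[0]
        assert rep.n_total_reads == 50
        assert rep.n_mapped_reads == rep.counts.sum() <= 10

    def test_matches_read_level_distribution(self):
        """Count-level and read-level subsampling agree in distribution
        (chi-square homogeneity over pooled per-gene totals, 5000 draws)."""
        weights = [5, 10, 20, 30, 35]
        catalog = make_catalog(weights)
        gene_ids = np.repeat(catalog["gene_id"].to_numpy(), np.asarray(weights) * 10)
        reads = make_reads(gene_ids)  # 1000 reads
        counts = ds.count_reads(reads, catalog)["sample"]
        n_draws = 5000
        spec_r = ds.SubsetSpec(fractions=(0.3,), n_replicates=n_draws, base_seed=11)
        spec_c = ds.SubsetSpec(fractions=(0.3,), n_replicates=n_draws, base_seed=99)
        totals_r = sum(rep.counts for rep in ds.subsample(reads, catalog, spec_r))
        totals_c = sum(rep.counts for rep in ds.subsample_counts(counts, spec_c))
        table = np.vstack([totals_r.to_numpy(), totals_c.to_numpy()])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001

    def test_subset_larger_than_library_error(self):
        counts = pd.Series([1], index=pd.Index(["g1"], name="gene_id"))
        spec = ds.SubsetSpec(fractions=(0.4,), n_replicates=1)
        with pytest.raises(ConfigError):
            ds.subsample_counts(counts, spec)  # size rounds to 0


class TestDetectionCurve:
    def test_fraction_one_equals_reference(self, toy_catalog):
        reads = make_reads(["g1"] * 10 + ["g2"] * 4 + ["g3"] * 2)
        spec = ds.SubsetSpec(fractions=(1.0,), n_replicates=2, base_seed=0)
        reps = ds.subsample(reads, toy_catalog, spec)
        curve = ds.detection_curve(reps, toy_catalog)
        ref_detected = int(
            (ds.count_reads(reads, toy_catalog)["sample"] > 3).sum()
        )
        assert curve.loc[0, "mean_detected"] == ref_detected

    def test_mean_detected_nondecreasing_in_fraction(self, medium_data):
        curve = ds.detection_curve(
            medium_data["replicates"], medium_data["catalog"]
        ).sort_values("fraction")
        means = curve["mean_detected"].to_numpy()
        sds = (
            curve["cv_detected_percent"].to_numpy() / 100 * means
        )  # one replicate SD of tolerance
        assert all(means[i + 1] >= means[i] - sds[i] for i in range(len(means) - 1))

    def test_exact_hypergeometric_detection_probability(self):
        """Gene with c=4 of N=100 reads: Monte-Carlo detection frequency at
        n=50 within 3 SE of the closed-form tail P(X > 3)."""
        counts = pd.Series([4, 96], index=pd.Index(["g1", "g2"], name="gene_id"))
        n_draws = 5000
        spec = ds.SubsetSpec(fractions=(0.5,), n_replicates=n_draws, base_seed=31)
        reps = ds.subsample_counts(counts, spec)
        observed = np.mean([rep.counts["g1"] > 3 for rep in reps])
        p_exact = stats.hypergeom(100, 4, 50).sf(3)
        se = math.sqrt(p_exact * (1 - p_exact) / n_draws)
        assert abs(observed - p_exact) < 3 * se


class TestGev:
    def test_identity_case(self):
        assert ds.gev(10.0, 10.0) == 0.0

    def test_half_reference(self):
        assert ds.gev(10.0, 5.0) == 50.0

    def test_sign_convention(self):
        assert ds.gev(5.0, 10.0) == -100.0

    def test_zero_reference_error(self):
        with pytest.raises(ConfigError):
            ds.gev(0.0, 5.0)

    @given(x=st.floats(min_value=0.01, max_value=100, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_identity_for_all_nonzero(self, x):
        assert ds.gev(x, x) == 0.0


class TestGevTable:
    def test_eligibility_threshold_is_eight_of_ten(self, medium_data):
        table = medium_data["gev_table"]
        reps = [r for r in medium_data["replicates"] if r.fraction == 0.05]
        det = pd.DataFrame({r.replicate: r.counts > 3 for r in reps})
        n_detected = det.sum(axis=1)
        in_table = set(table.loc[table["fraction"] == 0.05, "gene_id"])
        under = set(n_detected.index[(n_detected > 0) & (n_detected < 8)])
        assert not (under & in_table)
        assert math.ceil(0.8 * 10) == 8

    def test_gene_in_seven_of_ten_replicates_excluded(self):
        catalog = make_catalog([1, 1])
        ref_expr = pd.Series(
            [5.0, 5.0], index=pd.Index(["g1", "g2"], name="gene_id")
        )
        reps = []
        for r in range(10):
            c1 = 10 if r < 7 else 0  # detected in exactly 7 replicates
            counts = pd.Series(
                [c1, 100], index=pd.Index(["g1", "g2"], name="gene_id")
            )
            reps.append(
                ds.SubsetReplicate(
                    fraction=0.5,
                    replicate=r,
                    seed=r,
                    counts=counts,
                    n_total_reads=110,
                    n_mapped_reads=int(counts.sum()),
                )
            )
        table = ds.gev_table(ref_expr, reps, catalog)
        assert "g1" not in set(table["gene_id"])
        assert "g2" in set(table["gene_id"])

    def test_full_fraction_single_replicate_all_zero(self, toy_catalog):
        reads = make_reads(["g1"] * 40 + ["g2"] * 30 + ["g3"] * 30)
        counts = ds.count_reads(reads, toy_catalog)
        ref_expr = ds.log2cpm(counts)["sample"]
        spec = ds.SubsetSpec(fractions=(1.0,), n_replicates=1, base_seed=0)
        reps = ds.subsample(reads, toy_catalog, spec)
        table = ds.gev_table(ref_expr, reps, toy_catalog)
        assert len(table) > 0
        assert (table["gev_percent"] == 0).all()

    def test_zero_reference_genes_excluded(self):
        catalog = make_catalog([1, 1])
        # g1 has reference log2(CPM) exactly 0
        ref_expr = pd.Series(
            [0.0, 7.0], index=pd.Index(["g1", "g2"], name="gene_id")
        )
        counts = pd.Series([50, 50], index=pd.Index(["g1", "g2"], name="gene_id"))
        rep = ds.SubsetReplicate(
            fraction=0.5, replicate=0, seed=0, counts=counts,
            n_total_reads=100, n_mapped_reads=100,
        )
        table = ds.gev_table(ref_expr, [rep], catalog, min_replicate_detection=1.0)
        assert "g1" not in set(table["gene_id"])

    def test_subset_detected_implies_reference_detected(self, medium_data):
        ref_detected = set(medium_data["ref_expr"].dropna().index)
        for rep in medium_data["replicates"]:
            sub_detected = set(rep.counts.index[rep.counts > 3])
            assert sub_detected <= ref_detected


class TestGevSummary:
    def test_all_zero_table(self):
        table = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "fraction": [0.5, 0.5],
                "replicate": [0, 0],
                "gev_percent": [0.0, 0.0],
                "coding_class": ["coding", "coding"],
                "quartile": [None, None],
            }
        )
        summary = ds.gev_summary(table)
        row = summary.overall.iloc[0]
        assert row["median_gev"] == 0 and row["mean_abs_gev"] == 0

    def test_quartile_rank_correlation_negative_at_low_fraction(self, medium_data):
        summary = ds.gev_summary(medium_data["gev_table"])
        corr = summary.quartile_correlation.set_index("fraction")
        assert corr.loc[0.05, "spearman_rho"] < 0

    def test_median_abs_gev_decreases_with_fraction(self, medium_data):
        summary = ds.gev_summary(medium_data["gev_table"])
        overall = summary.overall.set_index("fraction")
        assert overall.loc[0.9, "median_abs_gev"] <= overall.loc[0.05, "median_abs_gev"]

    def test_q4_recovery_at_high_fraction(self, medium_data):
        """Mean |variation| of top-quartile genes at fraction 0.9 below 5%."""
        table = medium_data["gev_table"]
        q4 = table[(table["fraction"] == 0.9) & (table["quartile"] == "Q4")]
        assert q4["gev_percent"].abs().mean() < 5.0

    def test_empty_table_error(self):
        with pytest.raises(ConfigError):
            ds.gev_summary(pd.DataFrame(columns=["fraction", "gev_percent"]))
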