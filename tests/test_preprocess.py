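import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mhcprofiler.cohort import CohortConfig, generate_cohort
from mhcprofiler.preprocess import (
    combat_adjust,
    filter_low_expression,
    filter_small_subtypes,
    gc_quantile_normalize,
    log_cpm,
    pca_outlier_removal,
    remove_small_batches,
)


def frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        counts = frame([[0] * 4, [100] * 4])
        assert list(filter_low_expression(counts).index) == ["g1"]

    def test_boundary_fraction_inclusive(self):
        # gene g0 has CPM >= 1 in exactly 2 of 10 samples; min_fraction 0.2 keeps it
        counts = np.full((2, 10), 0)
        counts[1] = 1_000_000
        counts[0, :2] = 10            # CPM = 10/1e6 * 1e6 ~ 10 in 2 samples
        kept = filter_low_expression(frame(counts), min_cpm=1.0, min_fraction=0.2)
        assert "g0" in kept.index

    def test_min_fraction_one_rejects_single_zero(self):
        counts = np.full((2, 5), 1000)
        counts[0, 0] = 0
        kept = filter_low_expression(frame(counts), min_cpm=1.0, min_fraction=1.0)
        assert "g0" not in kept.index and "g1" in kept.index

    def test_everything_removed_is_an_error(self):
        counts = frame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            filter_low_expression(counts, min_cpm=1e7, min_fraction=0.5)


class TestLogCpm:
    def test_zero_count_maps_to_minus_two(self):
        counts = frame([[0], [4_000_000]])
        out = log_cpm(counts)
        assert out.iloc[0, 0] == pytest.approx(-2.0)

    def test_worked_example(self):
        # count 15 in a library of 4e6 -> CPM 3.75 -> log2(3.75 + .25) = 2
        counts = frame([[15], [3_999_985]])
        assert log_cpm(counts).iloc[0, 0] == pytest.approx(2.0)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(frame([[0], [0]]))


class TestGcQuantileNormalize:
    def test_identity_when_strata_share_distribution(self):
        # two GC strata with identical value distributions, identical samples:
        # the full-quantile maps are the identity up to interpolation tolerance
        values = np.array([1.0, 3.0, 7.0, 20.0] * 2)
        counts = frame(np.tile(values[:, None], (1, 3)))
        gc = pd.Series([0.3] * 4 + [0.7] * 4, index=counts.index)
        out = gc_quantile_normalize(counts, gc, n_gc_bins=2)
        assert np.allclose(out.to_numpy(), counts.to_numpy(), atol=1e-9)

    def test_sorted_columns_identical_after_stage_two(self, rng):
        # continuous values: with ties the midrank convention assigns tied
        # entries a shared interpolated value, so exact distribution sharing
        # holds on tie-free data
        counts = frame(rng.gamma(5.0, 10.0, size=(40, 6)))
        gc = pd.Series(rng.uniform(0.3, 0.7, 40), index=counts.index)
        out = gc_quantile_normalize(counts, gc, n_gc_bins=4)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]], atol=1e-9)

    def test_gc_trend_attenuated_on_biased_cohort(self):
        cohort = generate_cohort(CohortConfig(
            seed=21, gc_bias_sd=2.0, n_genes_background=150,
            panel_spec={"MHC": 10}, samples_per_subtype=10, n_normal_per_type=5,
            n_cpgs=30))
        counts, gc = cohort.counts, cohort.gc
        before = log_cpm(counts)
        after = log_cpm(gc_quantile_normalize(counts, gc))
        # per-sample correlation of expression with GC must shrink
        rho_before = np.mean([abs(spearmanr(before[s], gc).statistic)
                              for s in counts.columns[:20]])
        rho_after = np.mean([abs(spearmanr(after[s], gc).statistic)
                             for s in counts.columns[:20]])
        assert rho_after < 0.5 * rho_before

    def test_underfilled_bin_is_an_error(self):
        counts = frame(np.ones((3, 2)))
        gc = pd.Series([0.4, 0.5, 0.6], index=counts.index)
        with pytest.raises(ValueError, match="fewer bins|fewer than 2"):
            gc_quantile_normalize(counts, gc, n_gc_bins=3)

    def test_sample_permutation_equivariance(self, rng):
        counts = frame(rng.poisson(30, size=(30, 5)).astype(float))
        gc = pd.Series(rng.uniform(0.3, 0.7, 30), index=counts.index)
        out = gc_quantile_normalize(counts, gc, n_gc_bins=3)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        out_perm = gc_quantile_normalize(counts[perm], gc, n_gc_bins=3)
        assert np.allclose(out[perm].to_numpy(), out_perm.to_numpy(), atol=1e-12)


class TestPcaOutlierRemoval:
    def test_displaced_sample_removed(self, rng):
        x = rng.normal(0, 1, size=(50, 30))
        x[:, 0] += 10 * np.sign(rng.normal(size=50))
        expr = frame(x)
        kept = pca_outlier_removal(expr, sd_threshold=3.0)
        assert "s0" not in kept

    def test_infinite_threshold_retains_all(self, rng):
        expr = frame(rng.normal(size=(20, 10)))
        assert len(pca_outlier_removal(expr, sd_threshold=np.inf)) == 10

    def test_spherical_cloud_mostly_retained(self):
        # 3x RMS in a 2-PC projection of an isotropic cloud removes ~e^-9 of
        # samples; over seeds the average retention should exceed 97/100
        retained = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            expr = frame(r.normal(size=(40, 100)))
            retained.append(len(pca_outlier_removal(expr, sd_threshold=3.0)))
        assert np.mean(retained) >= 97

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_outlier_removal(frame(rng.normal(size=(5, 2))))


class TestRemoveSmallBatches:
    def make_meta(self, batches):
        rows = [(f"s{i}", b) for i, b in enumerate(batches)]
        return pd.DataFrame({"batch": [b for _, b in rows]},
                            index=pd.Index([s for s, _ in rows], name="sample_id"))

    def test_batch_of_four_dropped(self):
        meta = self.make_meta(["a"] * 10 + ["b"] * 4)
        kept = remove_small_batches(meta)
        assert len(kept) == 10 and all(meta.loc[kept, "batch"] == "a")

    def test_batch_of_five_retained(self):
        meta = self.make_meta(["a"] * 10 + ["b"] * 5)
        assert len(remove_small_batches(meta)) == 15

    def test_single_batch_all_retained(self):
        meta = self.make_meta(["a"] * 6)
        assert len(remove_small_batches(meta)) == 6

    def test_duplicate_ids_first_kept(self):
        meta = self.make_meta(["a"] * 6)
        dup = pd.concat([meta, meta.iloc[[0]]])
        kept = remove_small_batches(dup)
        assert list(kept) == [f"s{i}" for i in range(6)]


class TestCombat:
    def shifted_data(self, n_genes=60, n_per_batch=50, shift=2.0, sd=1.0, seed=0):
        r = np.random.default_rng(seed)
        base = r.normal(5, 2, size=(n_genes, 1))
        x = base + r.normal(0, sd, size=(n_genes, 2 * n_per_batch))
        delta = r.normal(shift, 0.3, size=(n_genes, 1))
        x[:, n_per_batch:] += delta
        batch = ["b1"] * n_per_batch + ["b2"] * n_per_batch
        return frame(x), batch

    def test_single_batch_is_identity_with_warning(self, rng):
        expr = frame(rng.normal(size=(10, 8)))
        with pytest.warns(UserWarning, match="single batch"):
            out = combat_adjust(expr, ["a"] * 8)
        assert out.equals(expr)

    def test_constant_shift_removed(self):
        # per-gene batch-mean differences after adjustment retain sampling
        # noise (even an oracle subtracting the true shift would), but the
        # systematic component must be gone: the average difference over
        # genes shrinks below 0.05 from a planted shift of 2
        expr, batch = self.shifted_data()
        out = combat_adjust(expr, batch)
        b1 = out.iloc[:, :50].mean(axis=1)
        b2 = out.iloc[:, 50:].mean(axis=1)
        assert abs((b1 - b2).mean()) < 0.05
        assert (b1 - b2).abs().mean() < 0.2

    def test_overall_gene_means_preserved(self):
        expr, batch = self.shifted_data(seed=4)
        out = combat_adjust(expr, batch)
        assert np.allclose(out.mean(axis=1), expr.mean(axis=1), atol=1e-6)

    def test_batch_variance_explained_reduced_90_percent(self):
        expr, batch = self.shifted_data(shift=2.0, sd=1.0, seed=2)
        out = combat_adjust(expr, batch)

        def eta_squared(df):
            x = df.to_numpy()
            grand = x.mean(axis=1, keepdims=True)
            b1, b2 = x[:, :50], x[:, 50:]
            ss_between = 50 * ((b1.mean(axis=1, keepdims=True) - grand) ** 2
                               + (b2.mean(axis=1, keepdims=True) - grand) ** 2).ravel()
            ss_total = ((x - grand) ** 2).sum(axis=1)
            return (ss_between / ss_total).mean()

        assert eta_squared(out) <= 0.1 * eta_squared(expr)

    def test_zero_variance_gene_floored_with_warning(self):
        expr, batch = self.shifted_data(n_genes=10)
        expr.iloc[0, :50] = 3.0
        with pytest.warns(UserWarning, match="floored"):
            out = combat_adjust(expr, batch)
        assert np.isfinite(out.to_numpy()).all()

    def test_agrees_with_scanpy_implementation(self):
        """Independent cross-check against the scanpy port of the same
        empirical-Bayes scheme (after per-gene centering: the package
        re-centres genes to their original means, scanpy does not)."""
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        expr, batch = self.shifted_data(n_genes=40, n_per_batch=30, seed=9)
        ours = combat_adjust(expr, batch)
        ad = anndata.AnnData(
            expr.T.to_numpy(),
            obs=pd.DataFrame({"batch": pd.Categorical(batch)}, index=expr.columns),
        )
        sc.pp.combat(ad, key="batch")
        theirs = pd.DataFrame(ad.X.T, index=expr.index, columns=expr.columns)
        o = ours.sub(ours.mean(axis=1), axis=0).to_numpy()
        t = theirs.sub(theirs.mean(axis=1), axis=0).to_numpy()
        assert np.abs(o - t).max() < 0.02
        assert np.corrcoef(o.ravel(), t.ravel())[0, 1] > 0.9999


class TestFilterSmallSubtypes:
    def make_meta(self, spec):
        # spec: list of (cancer_type, subtype, is_tumor, count)
        rows = []
        for ct, st, tumor, n in spec:
            for i in range(n):
                rows.append((f"{ct}_{st}_{tumor}_{i}", ct, st, tumor))
        return pd.DataFrame(
            [(ct, st, t) for _, ct, st, t in rows],
            columns=["cancer_type", "subtype", "is_tumor"],
            index=pd.Index([r[0] for r in rows], name="sample_id"),
        )

    def test_nine_tumor_subtype_removed_ten_retained(self):
        meta = self.make_meta([("A", "x", 1, 9), ("A", "y", 1, 10)])
        kept = meta.loc[filter_small_subtypes(meta)]
        assert set(kept["subtype"]) == {"y"}

    def test_normals_always_retained(self):
        meta = self.make_meta([("A", "x", 1, 3), ("A", "normal", 0, 4)])
        kept = meta.loc[filter_small_subtypes(meta)]
        assert (kept["is_tumor"] == 0).sum() == 4
        assert (kept["is_tumor"] == 1).sum() == 0

    def test_subtype_names_scoped_within_cancer_type(self):
        # subtype "x" is large in type A, small in type B: only B's is removed
        meta = self.make_meta([("A", "x", 1, 12), ("B", "x", 1, 5)])
        kept = meta.loc[filter_small_subtypes(meta)]
        assert set(kept["cancer_type"]) == {"A"}
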