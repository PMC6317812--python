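import numpy as np
import pandas as pd
import pytest

from pcca import preprocess as pp
from pcca.containers import ConfounderMatrix, ExpressionMatrix, GenotypeMatrix


def _expr(values, state="tpm", samples=None, genes=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=samples, columns=genes), state)


class TestAggregateTranscripts:
    def test_sum_of_member_transcripts(self):
        tx = _expr([[1.5, 2.5]], genes=["t1", "t2"])
        out = pp.aggregate_transcripts_to_genes(tx, pd.Series({"t1": "gA", "t2": "gA"}))
        assert out.values.loc["s0", "gA"] == 4.0

    def test_single_transcript_gene_identity(self):
        tx = _expr([[3.25], [0.5]], genes=["t1"])
        out = pp.aggregate_transcripts_to_genes(tx, pd.Series({"t1": "gA"}))
        np.testing.assert_array_equal(out.values["gA"], [3.25, 0.5])

    def test_matches_groupby_sum_oracle(self, rng):
        tpm = rng.uniform(0, 10, size=(4, 7))
        tx2gene = pd.Series(
            {"t0": "gA", "t1": "gA", "t2": "gB", "t3": "gB", "t4": "gB", "t5": "gC", "t6": "gC"}
        )
        tx = _expr(tpm, genes=list(tx2gene.index))
        out = pp.aggregate_transcripts_to_genes(tx, tx2gene)
        # brute-force double loop oracle
        for s in range(4):
            for gene in ["gA", "gB", "gC"]:
                expected = sum(
                    tpm[s, i] for i, t in enumerate(tx2gene.index) if tx2gene[t] == gene
                )
                assert out.values.iloc[s][gene] == pytest.approx(expected, abs=1e-12)

    def test_unmapped_transcript_errors(self):
        tx = _expr([[1.0, 2.0]], genes=["t1", "tX"])
        with pytest.raises(ValueError, match="tX"):
            pp.aggregate_transcripts_to_genes(tx, pd.Series({"t1": "gA"}))


class TestMeanTpmFilter:
    def test_boundary_mean_exactly_at_threshold_kept(self):
        m = _expr([[0.1], [0.1]])
        assert list(pp.filter_transcripts_by_mean_tpm(m, 0.1).gene_ids) == ["g0"]

    def test_all_zero_feature_removed(self):
        m = _expr([[0.0, 1.0], [0.0, 1.0]])
        assert list(pp.filter_transcripts_by_mean_tpm(m, 0.01).gene_ids) == ["g1"]

    def test_kept_set_matches_mean_oracle(self, rng):
        tpm = rng.uniform(0, 0.3, size=(6, 20))
        m = _expr(tpm)
        kept = set(pp.filter_transcripts_by_mean_tpm(m, 0.1).gene_ids)
        expected = {f"g{i}" for i in range(20) if tpm[:, i].mean() >= 0.1}
        assert kept == expected


class TestRegionFilter:
    @pytest.fixture()
    def annotation(self):
        return pd.DataFrame(
            {
                "gene_id": ["auto", "sex", "mhc", "chr6ok"],
                "chromosome": ["1", "X", "6", "6"],
                "tss": [1000, 1000, 30_000_000, 1_000_000],
            }
        ).set_index("gene_id", drop=False)

    def test_filters(self, annotation):
        m = _expr(np.ones((2, 4)), genes=["auto", "sex", "mhc", "chr6ok"])
        out = pp.filter_genes_by_region(m, annotation)
        assert list(out.gene_ids) == ["auto", "chr6ok"]

    def test_unannotated_gene_errors(self, annotation):
        m = _expr(np.ones((2, 1)), genes=["mystery"])
        with pytest.raises(ValueError, match="mystery"):
            pp.filter_genes_by_region(m, annotation)


class TestFilterVariants:
    def test_monomorphic_removed(self):
        g = GenotypeMatrix(pd.DataFrame({"snp1": [0.0] * 10, "snp2": [0, 1] * 5}, index=[f"s{i}" for i in range(10)]))
        out = pp.filter_variants(g, maf_min=0.05)
        assert list(out.snp_ids) == ["snp2"]

    def test_boundary_maf_inclusive(self):
        # 10 samples, dosage sum 1 => p = 0.05 exactly, kept at maf_min=0.05
        dosages = [1.0] + [0.0] * 9
        g = GenotypeMatrix(pd.DataFrame({"snp1": dosages}, index=[f"s{i}" for i in range(10)]))
        assert list(pp.filter_variants(g, maf_min=0.05).snp_ids) == ["snp1"]

    def test_indel_removed_regardless_of_frequency(self):
        g = GenotypeMatrix(
            pd.DataFrame({"indel": [0, 1, 2, 1], "snp": [0, 1, 2, 1]}, index=list("abcd"), dtype=float)
        )
        ann = pd.DataFrame(
            {"snp_id": ["indel", "snp"], "chromosome": "1", "position": [1, 2],
             "is_biallelic_snp": [False, True]}
        ).set_index("snp_id", drop=False)
        assert list(pp.filter_variants(g, ann, maf_min=0.05).snp_ids) == ["snp"]

    def test_idempotent(self, rng):
        values = pd.DataFrame(
            rng.integers(0, 3, size=(30, 40)).astype(float),
            index=[f"s{i}" for i in range(30)],
            columns=[f"snp{i}" for i in range(40)],
        )
        once = pp.filter_variants(GenotypeMatrix(values), maf_min=0.1)
        twice = pp.filter_variants(once, maf_min=0.1)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_maf_uses_nonmissing_calls(self):
        col = [2.0, np.nan, np.nan, 0.0, 0.0, 0.0, 0.0, 0.0]
        g = GenotypeMatrix(pd.DataFrame({"snp1": col}, index=[f"s{i}" for i in range(8)]))
        # p = 2 / (2 * 6) = 1/6 over non-missing calls
        assert pp.snp_maf(g)["snp1"] == pytest.approx(1 / 6)


class TestQuantileNormalize:
    def test_permuted_samples_share_value_set(self, rng):
        base = rng.uniform(0, 50, size=12)
        values = np.vstack([base, rng.permutation(base), rng.permutation(base)])
        out = pp.quantile_normalize(_expr(values))
        sorted_rows = np.sort(out.values.to_numpy(), axis=1)
        np.testing.assert_allclose(sorted_rows[0], sorted_rows[1], atol=1e-12)
        np.testing.assert_allclose(sorted_rows[0], sorted_rows[2], atol=1e-12)

    def test_single_sample_unchanged(self):
        values = [[5.0, 1.0, 3.0, 3.0]]
        out = pp.quantile_normalize(_expr(values))
        np.testing.assert_allclose(out.values.to_numpy(), values, atol=1e-12)

    def test_hand_computed_fixture_with_tie(self):
        # 3 samples x 4 genes; sample 2 has a tie at its two smallest positions.
        values = np.array(
            [
                [2.0, 4.0, 6.0, 8.0],
                [1.0, 1.0, 5.0, 9.0],
                [3.0, 6.0, 9.0, 12.0],
            ]
        )
        # reference (mean order statistics): [2, 11/3, 20/3, 29/3]
        ref = np.array([2.0, 11 / 3, 20 / 3, 29 / 3])
        expected = np.array(
            [
                ref,
                # ties at rank 1-2 get the mean of ref[0:2] = 17/6
                [17 / 6, 17 / 6, ref[2], ref[3]],
                ref,
            ]
        )
        out = pp.quantile_normalize(_expr(values))
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-12)

    def test_rejects_non_tpm_state(self):
        with pytest.raises(ValueError):
            pp.quantile_normalize(_expr([[0.0]], state="standardized"))


class TestStandardizeGenes:
    def test_population_variance_convention(self):
        out = pp.standardize_genes(_expr([[1.0], [2.0], [3.0]], state="quantile_normalized"))
        np.testing.assert_allclose(out.values["g0"], [-np.sqrt(1.5), 0, np.sqrt(1.5)] / np.sqrt(1), atol=1e-12)
        # population sd of [1,2,3] is sqrt(2/3); (1-2)/sqrt(2/3) = -sqrt(1.5)
        assert out.values["g0"].var(ddof=0) == pytest.approx(1.0)

    def test_idempotent(self, rng):
        m = _expr(rng.standard_normal((10, 4)), state="quantile_normalized")
        once = pp.standardize_genes(m)
        twice = pp.standardize_genes(ExpressionMatrix(once.values, "quantile_normalized"))
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_constant_gene_errors(self):
        with pytest.raises(ValueError, match="g0"):
            pp.standardize_genes(_expr([[1.0], [1.0]], state="quantile_normalized"))


class TestConfounderMatrix:
    @staticmethod
    def _metadata(n, n_labs, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "population": "GBR",
                "batch": [f"lab{rng.integers(n_labs) + 1}" for _ in range(n)],
                "gender": rng.choice(["male", "female"], size=n),
            }
        ).set_index("sample_id", drop=False)

    def test_six_labs_give_seven_columns(self):
        conf = pp.build_confounder_matrix(self._metadata(343, 6))
        assert conf.values.shape == (343, 7)
        # one-hot block rows sum to 1
        np.testing.assert_allclose(conf.values[conf.batch_columns].sum(axis=1), 1.0)

    def test_single_batch(self):
        meta = self._metadata(5, 1)
        conf = pp.build_confounder_matrix(meta)
        assert len(conf.batch_columns) == 1
        np.testing.assert_array_equal(conf.values[conf.batch_columns[0]], 1.0)

    def test_hand_written_indicator_matrix(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "population": "GBR",
                "batch": ["L1", "L2", "L1", "L2"],
                "gender": ["male", "female", "female", "male"],
            }
        ).set_index("sample_id", drop=False)
        conf = pp.build_confounder_matrix(meta)
        np.testing.assert_array_equal(conf.values["batch_L1"], [1, 0, 1, 0])
        np.testing.assert_array_equal(conf.values["batch_L2"], [0, 1, 0, 1])
        np.testing.assert_array_equal(conf.values["gender"], [1, 0, 0, 1])

    def test_singleton_batch_warns(self):
        meta = self._metadata(5, 1)
        meta.loc["s4", "batch"] = "lonely"
        with pytest.warns(UserWarning, match="lonely"):
            pp.build_confounder_matrix(meta)


class TestRegressOutConfounders:
    def _conf(self, values, samples):
        df = pd.DataFrame(values, index=samples)
        return ConfounderMatrix(df, batch_columns=list(df.columns))

    def test_gene_equal_to_indicator_residual_zero(self):
        samples = [f"s{i}" for i in range(6)]
        ind = np.array([1.0, 1, 1, 0, 0, 0])
        expr = _expr(ind[:, None], state="standardized", samples=samples)
        out = pp.regress_out_confounders(expr, self._conf({"b": ind}, samples))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_confounder_leaves_gene_centered(self, rng):
        samples = [f"s{i}" for i in range(8)]
        gene = rng.standard_normal(8)
        conf_col = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        gene = gene - gene @ conf_col / 8 * conf_col  # orthogonalize
        expr = _expr(gene[:, None], state="standardized", samples=samples)
        out = pp.regress_out_confounders(expr, self._conf({"c": conf_col}, samples))
        np.testing.assert_allclose(out.values.to_numpy()[:, 0], gene - gene.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        samples = [f"s{i}" for i in range(10)]
        Y = rng.standard_normal((10, 3))
        C = rng.standard_normal((10, 2))
        expr = _expr(Y, state="standardized", samples=samples)
        out = pp.regress_out_confounders(expr, self._conf({"c1": C[:, 0], "c2": C[:, 1]}, samples))
        D = np.column_stack([np.ones(10), C])
        expected = Y - D @ np.linalg.solve(D.T @ D, D.T @ Y)
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-10)

    def test_residuals_orthogonal_to_confounders(self, rng):
        samples = [f"s{i}" for i in range(20)]
        Y = rng.standard_normal((20, 5))
        C = rng.standard_normal((20, 3))
        conf = self._conf({f"c{i}": C[:, i] for i in range(3)}, samples)
        out = pp.regress_out_confounders(_expr(Y, state="standardized", samples=samples), conf)
        dots = np.abs(C.T @ out.values.to_numpy())
        assert dots.max() < 1e-8 * 20
        assert np.abs(out.values.mean(axis=0)).max() < 1e-8


class TestOrthogonalConfounderProjection:
    def _scores(self, rng, n, k, samples):
        q, _ = np.linalg.qr(rng.standard_normal((n, k)))
        return pd.DataFrame(q, index=samples, columns=[f"PC{i+1}" for i in range(k)])

    def test_noise_confounders_near_chance_and_orthogonal_removal(self, rng):
        from pcca.pcca_core import full_cca

        n = 200
        samples = [f"s{i}" for i in range(n)]
        scores = self._scores(rng, n, 4, samples)
        conf = ConfounderMatrix(pd.DataFrame(rng.standard_normal((n, 2)), index=samples))
        rho, (zx, _) = full_cca(scores.to_numpy(), conf.values.to_numpy(), l=1)
        assert rho[0] < 0.4  # independent noise: correlation at chance scale, not ~1
        out = pp.orthogonal_confounder_projection(scores, conf, d=1)
        # returned scores are uncorrelated with the removed canonical direction
        assert np.abs(out.to_numpy().T @ zx[:, 0]).max() < 1e-8
        # one direction of ~unit energy is removed (slightly less than 1 because
        # full_cca centers columns and random orthonormal scores are not exactly centered)
        assert np.linalg.norm(out.to_numpy() - scores.to_numpy()) == pytest.approx(1.0, abs=0.01)

    def test_batch_indicator_column_annihilated(self, rng):
        n = 40
        samples = [f"s{i}" for i in range(n)]
        batch = np.array([1.0] * 20 + [0.0] * 20)
        col = (batch - batch.mean()) / np.linalg.norm(batch - batch.mean())
        other = self._scores(rng, n, 3, samples).to_numpy()
        other = other - col[:, None] * (col @ other)  # orthogonal to the batch direction
        other, _ = np.linalg.qr(other)
        scores = pd.DataFrame(
            np.column_stack([col, other]), index=samples, columns=["PC1", "PC2", "PC3", "PC4"]
        )
        conf = ConfounderMatrix(pd.DataFrame({"batch": batch}, index=samples))
        out = pp.orthogonal_confounder_projection(scores, conf, d=1)
        np.testing.assert_allclose(out["PC1"].to_numpy(), 0.0, atol=1e-8)

    def test_d_too_large_errors(self, rng):
        n = 30
        samples = [f"s{i}" for i in range(n)]
        scores = self._scores(rng, n, 3, samples)
        conf = ConfounderMatrix(pd.DataFrame({"b": np.repeat([0.0, 1.0], 15)}, index=samples))
        with pytest.raises(ValueError):
            pp.orthogonal_confounder_projection(scores, conf, d=3)

    def test_batch_separability_drops(self, small_dataset):
        ds = small_dataset
        expr = pp.standardize_genes(pp.quantile_normalize(ds.expression))
        from pcca.pcca_core import pca

        scores = pca(expr.values, 6).scores
        conf = pp.build_confounder_matrix(ds.metadata)
        corrected = pp.orthogonal_confounder_projection(scores, conf, d=2)

        def ratio(frame):
            overall = frame.mean(axis=0)
            between = within = 0.0
            for _, g in frame.groupby(ds.truth.batches.to_numpy()):
                between += len(g) * ((g.mean(axis=0) - overall) ** 2).sum()
                within += ((g - g.mean(axis=0)) ** 2).sum().sum()
            return between / within

        assert ratio(corrected) < ratio(scores)
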