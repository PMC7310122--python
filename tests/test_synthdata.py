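import numpy as np
import pandas as pd
import pytest

from coexpred import synthdata


class TestStructure:
    def test_study_scale_sample_count(self):
        """241 genotypes across 11 populations with 218 duplicated gives 459 samples."""
        design, kinship = synthdata.generate_structure(
            n_pops=11, genotypes_per_pop=241, duplicated_fraction=218 / 241, seed=0
        )
        assert len(design) == 459
        assert design["genotype"].nunique() == 241
        assert design["population"].nunique() == 11
        counts = design["genotype"].value_counts()
        assert (counts == 2).sum() == 218 and (counts == 1).sum() == 23
        assert kinship.shape == (241, 241)

    def test_minimal_two_singletons(self):
        design, kinship = synthdata.generate_structure(
            n_pops=2, genotypes_per_pop=[1, 1], duplicated_fraction=0.0, seed=0
        )
        assert len(design) == 2
        assert kinship.shape == (2, 2)

    def test_determinism(self):
        a = synthdata.generate_structure(3, 30, seed=42)
        b = synthdata.generate_structure(3, 30, seed=42)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_kinship_symmetric_psd_and_structured(self):
        design, K = synthdata.generate_structure(4, 80, seed=3)
        A = K.to_numpy()
        assert np.allclose(A, A.T)
        assert np.linalg.eigvalsh(A).min() > -1e-8
        pops = design.drop_duplicates("genotype").set_index("genotype")["population"]
        labels = pops.reindex(K.index).to_numpy()
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(A), dtype=bool)
        assert A[same & off].mean() > A[~same].mean()

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            synthdata.generate_structure(2, [5, 0], seed=0)
        with pytest.raises(ValueError):
            synthdata.generate_structure(1, 10, seed=0)


class TestSNPs:
    @staticmethod
    def _design(n_pops, per_pop, seed=0):
        design, _ = synthdata.generate_structure(
            n_pops, per_pop, duplicated_fraction=0.0, seed=seed,
        )
        return design

    def test_zero_divergence_fst_near_zero(self):
        design = self._design(2, 200)
        dosages, _ = synthdata.generate_snps(design, n_snps=2000, divergence=0.0, seed=1)
        fst = _nei_fst(dosages, design)
        assert abs(fst) < 0.02

    def test_planted_divergence_recovered(self):
        """Nei F_ST on the simulated panel recovers the Balding-Nichols
        parameter at the study's population count.

        G_ST carries an inherent (1 - 1/k) deflation from estimating the
        total heterozygosity on the pooled mean frequency of k demes; at the
        study's k = 11 the expectation is d (1 - 1/k) / (1 - d/k) ~ 0.185 for
        d = 0.2, inside the Monte-Carlo tolerance around the parameter.
        """
        design = self._design(11, 440)
        dosages, _ = synthdata.generate_snps(design, n_snps=2000, divergence=0.2, seed=1)
        fst = _nei_fst(dosages, design)
        assert abs(fst - 0.2) < 0.05

    def test_monomorphic_ancestral_all_homozygous(self):
        design = self._design(2, 20)
        dosages, _ = synthdata.generate_snps(
            design, n_snps=10, divergence=0.1, seed=0, ancestral=np.ones(10)
        )
        assert (dosages.to_numpy() == 2).all()

    def test_divergence_out_of_range_rejected(self):
        design = self._design(2, 10)
        with pytest.raises(ValueError):
            synthdata.generate_snps(design, n_snps=10, divergence=1.0)

    def test_gene_assignment_covers_all_snps(self):
        design = self._design(2, 10)
        dosages, assign = synthdata.generate_snps(
            design, n_snps=40, snps_per_gene=4, gene_ids=[f"g{i}" for i in range(10)]
        )
        assert len(assign) == 40
        assert assign.value_counts().eq(4).all()


class TestExpression:
    def test_no_signal_genes_are_exchangeable_noise(self):
        """Zero genetic variance and no loading leaves only residual scatter."""
        design, K = synthdata.generate_structure(3, 30, seed=0)
        n_genes = 40
        truth = synthdata.TruthRecord(
            sigma_b2=np.zeros(n_genes), sigma_w2=np.zeros(n_genes),
            sigma_e2=np.full(n_genes, 1.0), module=np.zeros(n_genes, dtype=int),
            loading=np.zeros(n_genes),
        )
        counts, latent, genetic = synthdata.generate_expression(design, K, truth, seed=0)
        assert np.allclose(genetic.to_numpy(), 0.0)
        # latent rows are iid noise: off-diagonal correlations stay small
        C = np.corrcoef(latent.to_numpy())
        off = C[~np.eye(n_genes, dtype=bool)]
        assert np.abs(off).mean() < 0.2

    def test_single_module_high_loading_correlated(self):
        """Genes loaded 1.0 on one factor correlate strongly on the latent scale."""
        design, K = synthdata.generate_structure(3, 60, seed=1)
        n_genes = 50
        truth = synthdata.TruthRecord(
            sigma_b2=np.zeros(n_genes), sigma_w2=np.zeros(n_genes),
            sigma_e2=np.full(n_genes, 0.05), module=np.ones(n_genes, dtype=int),
            loading=np.ones(n_genes),
        )
        _, latent, _ = synthdata.generate_expression(design, K, truth, seed=0)
        from scipy.stats import spearmanr
        rho = spearmanr(latent.to_numpy(), axis=1).statistic
        off = rho[~np.eye(n_genes, dtype=bool)]
        assert off.min() > 0.8

    def test_library_multiplier_scales_column_sum(self):
        design, K = synthdata.generate_structure(3, 30, seed=2)
        n_genes = 300
        truth = synthdata.TruthRecord(
            sigma_b2=np.zeros(n_genes), sigma_w2=np.zeros(n_genes),
            sigma_e2=np.full(n_genes, 0.1), module=np.zeros(n_genes, dtype=int),
            loading=np.zeros(n_genes),
        )
        lib = np.ones(len(design))
        lib[0] = 2.0
        truth.library_multipliers = lib
        counts, _, _ = synthdata.generate_expression(design, K, truth, seed=3)
        sums = counts.sum(axis=0).to_numpy(dtype=float)
        ratio = sums[0] / np.median(sums[1:])
        assert 1.6 < ratio < 2.4

    def test_dimension_mismatch_rejected(self):
        design, K = synthdata.generate_structure(3, 30, seed=0)
        truth = synthdata.TruthRecord(
            sigma_b2=np.zeros(3), sigma_w2=np.zeros(3), sigma_e2=np.ones(3),
            module=np.zeros(3, dtype=int), loading=np.zeros(3),
        )
        with pytest.raises(ValueError):
            synthdata.generate_expression(design.assign(genotype="nope"), K, truth)


class TestTraits:
    @staticmethod
    def _genetic(n=200, p=5, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.standard_normal((n, p)),
            index=[f"G{i}" for i in range(n)],
            columns=[f"gene{i}" for i in range(p)],
        )

    @staticmethod
    def _truth(effects):
        t = synthdata.TruthRecord(
            sigma_b2=np.zeros(5), sigma_w2=np.zeros(5), sigma_e2=np.ones(5),
            module=np.zeros(5, dtype=int), loading=np.zeros(5),
        )
        t.trait_effects = effects
        return t

    def test_pure_additive_no_noise_equals_gene(self):
        G = self._genetic()
        truth = self._truth(
            {"t": {"additive": {"gene0": 1.0}, "pairs": [], "signal_fraction": 1.0}}
        )
        traits = synthdata.generate_traits(G, truth, seed=0)
        np.testing.assert_allclose(traits["t"].to_numpy(), G["gene0"].to_numpy())

    def test_signal_fraction_half_recovered(self):
        """The generating linear predictor explains q = 0.5 of the trait variance."""
        r2s = []
        for seed in range(10):
            G = self._genetic(n=200, seed=seed)
            truth = self._truth(
                {"t": {"additive": {"gene0": 1.0, "gene1": -0.5}, "pairs": [],
                       "signal_fraction": 0.5}}
            )
            y = synthdata.generate_traits(G, truth, seed=seed)["t"].to_numpy()
            signal = G["gene0"] - 0.5 * G["gene1"]
            r2s.append(np.corrcoef(signal, y)[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.5) < 0.05

    def test_interaction_only_additive_oracle_fails(self):
        """An additive-only regression explains little of a product trait."""
        G = self._genetic(n=300, seed=1)
        truth = self._truth(
            {"t": {"additive": {}, "pairs": [(("gene0", "gene1"), 1.0)],
                   "signal_fraction": 1.0}}
        )
        y = synthdata.generate_traits(G, truth, seed=0)["t"].to_numpy()
        X = np.column_stack([np.ones(len(G)), G.to_numpy()])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid.var() / y.var()
        assert r2 < 0.20

    def test_unknown_effect_gene_rejected(self):
        G = self._genetic()
        truth = self._truth(
            {"t": {"additive": {"missing": 1.0}, "pairs": [], "signal_fraction": 1.0}}
        )
        with pytest.raises(KeyError):
            synthdata.generate_traits(G, truth, seed=0)


class TestBundle:
    def test_bundle_consistency_and_determinism(self, small_bundle):
        small_bundle.validate()
        again = synthdata.generate_bundle(
            n_pops=6, n_genotypes=60, n_genes=120, n_modules=2,
            grey_fraction=0.4, n_snps=400, n_traits=2, seed=11,
        )
        pd.testing.assert_frame_equal(small_bundle.counts, again.counts)
        pd.testing.assert_frame_equal(small_bundle.traits, again.traits)

    def test_truth_variances_validated(self):
        with pytest.raises(ValueError):
            synthdata.TruthRecord(
                sigma_b2=np.array([-1.0]), sigma_w2=np.zeros(1),
                sigma_e2=np.zeros(1), module=np.zeros(1, dtype=int),
                loading=np.zeros(1),
            )
        with pytest.raises(ValueError):
            synthdata.TruthRecord(
                sigma_b2=np.ones(1), sigma_w2=np.zeros(1), sigma_e2=np.zeros(1),
                module=np.zeros(1, dtype=int), loading=np.zeros(1), divergence=1.5,
            )

    def test_writes_plain_text_outputs(self, small_bundle, tmp_path):
        small_bundle.write(tmp_path)
        for name in ("counts.tsv", "design.csv", "kinship.tsv", "dosages.tsv",
                     "traits.csv", "truth.json"):
            assert (tmp_path / name).exists()

    def test_minimal_vcf_roundtrip(self, small_bundle, tmp_path):
        from coexpred.popgen import read_vcf_dosages

        path = tmp_path / "panel.vcf"
        sub = small_bundle.dosages.iloc[:5, :10]
        synthdata.write_minimal_vcf(sub, path)
        text = path.read_text().splitlines()
        assert text[0].startswith("##fileformat")
        assert len([l for l in text if not l.startswith("#")]) == 10
        back = read_vcf_dosages(path)
        np.testing.assert_array_equal(back.to_numpy(), sub.to_numpy())


def _nei_fst(dosages: pd.DataFrame, design: pd.DataFrame) -> float:
    """Independent multilocus Nei F_ST oracle on observed allele frequencies."""
    pops = design.drop_duplicates("genotype").set_index("genotype")["population"]
    labels = pops.reindex(dosages.index).to_numpy()
    D = dosages.to_numpy(dtype=float)
    p_all = D.mean(axis=0) / 2
    ht = 2 * p_all * (1 - p_all)
    hs = np.zeros_like(ht)
    for pop in np.unique(labels):
        mask = labels == pop
        p = D[mask].mean(axis=0) / 2
        hs += mask.mean() * 2 * p * (1 - p)
    ok = ht > 0
    return float(np.sum(ht[ok] - hs[ok]) / np.sum(ht[ok]))
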