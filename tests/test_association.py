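import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridexpress import (
    NormalizedMatrix,
    SimulationConfig,
    TraitAssociationModel,
    cpm_normalize,
    filter_cpm,
    gene_trait_score,
    genomewide_threshold,
    manhattan_table,
    module_eigengene,
    module_trait_correlation,
    qpcr_relative_expression,
    simulate_family,
    simulate_traits,
)


def _norm(values: np.ndarray, genes=None, samples=None) -> NormalizedMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale="log2cpm"
    )


class TestGeneTraitScore:
    def test_zero_correlation_scores_zero(self):
        # orthogonal contrast: r is exactly 0
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # strip any linear part
        rec = gene_trait_score(x, y)
        assert rec["score"] == pytest.approx(0.0, abs=1e-12)

    def test_t_distribution_oracle_n9(self):
        # r = 0.8 with 9 genotypes: R^2 = 0.64, p from t with 7 df
        rng = np.random.default_rng(0)
        x = rng.normal(size=9)
        # build y with exact sample correlation 0.8
        z = rng.normal(size=9)
        xs = (x - x.mean()) / x.std()
        zs = z - z.mean()
        zs -= xs * (zs @ xs) / (xs @ xs)
        zs /= zs.std()
        y = 0.8 * xs + np.sqrt(1 - 0.64) * zs
        rec = gene_trait_score(x, y)
        t = 0.8 * np.sqrt(7) / np.sqrt(1 - 0.64)
        p_expected = 2 * stats.t.sf(t, df=7)
        assert rec["r_squared"] == pytest.approx(0.64, abs=1e-10)
        assert rec["p_value"] == pytest.approx(p_expected, rel=1e-9)
        assert rec["score"] == pytest.approx(0.64 * -np.log10(p_expected), rel=1e-9)

    def test_affine_trait_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = gene_trait_score(x, y)
        b = gene_trait_score(x, 3.5 * y - 40.0)
        assert a["score"] == pytest.approx(b["score"], rel=1e-12)

    def test_degenerate_inputs_flagged_not_raised(self):
        rec = gene_trait_score([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert rec == {"r_squared": 0.0, "p_value": 1.0, "score": 0.0, "degenerate": True}
        with pytest.raises(ValueError, match="at least 3"):
            gene_trait_score([1.0, 2.0], [0.0, 1.0])


class TestThreshold:
    def test_closed_form(self):
        assert genomewide_threshold(1000, 0.05) == pytest.approx(
            -np.log10(5e-5), abs=1e-12
        )
        assert genomewide_threshold(1, 0.05) == pytest.approx(1.3010299956639813, abs=1e-12)

    def test_strictly_increasing_in_n(self):
        ns = [1, 2, 10, 100, 10_000]
        vals = [genomewide_threshold(n) for n in ns]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            genomewide_threshold(0)
        with pytest.raises(ValueError):
            genomewide_threshold(10, alpha=0.0)


class TestManhattan:
    def _records(self, scores):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(scores))],
             "trait_name": "t", "score": scores}
        )

    def _annotation(self, n):
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            {"chromosome": [f"Chr{1 + i % 3:02d}" for i in range(n)],
             "start": rng.integers(0, 10**7, n)},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        ).assign(end=lambda d: d["start"] + 1000)

    def test_row_conservation_and_sorting(self):
        rec = self._records([0.1, 5.0, 0.2, 3.0])
        tab = manhattan_table(rec, self._annotation(4))
        assert len(tab) == 4
        key = list(zip(tab["chromosome"], tab["position_mb"]))
        assert key == sorted(key)

    def test_zero_scores_never_pass(self):
        tab = manhattan_table(self._records([0.0] * 5), self._annotation(5))
        assert not tab["passes_threshold"].any()

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(ValueError, match="missing from annotation"):
            manhattan_table(self._records([1.0, 2.0]), self._annotation(1))


class TestEigengene:
    def test_identical_profiles_rank_one(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        norm = _norm(np.tile(profile, (4, 1)))
        eig = module_eigengene(norm, norm.gene_ids)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig.values.to_numpy(), z, atol=1e-12)
        assert eig.variance_explained == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair_orients_to_first_gene(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        norm = _norm(np.vstack([profile, -profile]))
        eig = module_eigengene(norm, ["g0", "g1"])
        assert eig.variance_explained == pytest.approx(1.0, abs=1e-12)
        assert np.corrcoef(eig.values, profile)[0, 1] > 0.99

    def test_mean_member_correlation_nonnegative(self):
        rng = np.random.default_rng(2)
        norm = _norm(rng.normal(size=(6, 10)))
        eig = module_eigengene(norm, norm.gene_ids)
        corrs = [
            np.corrcoef(eig.values, norm.values.loc[g])[0, 1] for g in norm.gene_ids
        ]
        assert np.mean(corrs) >= 0
        assert abs(eig.values.mean()) < 1e-10

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 8))
        norm = _norm(vals)
        eig = module_eigengene(norm, norm.gene_ids)
        gperm = rng.permutation(5)
        sperm = rng.permutation(8)
        shuffled = NormalizedMatrix(
            norm.values.iloc[gperm, sperm], scale="log2cpm"
        )
        eig2 = module_eigengene(shuffled, shuffled.gene_ids)
        np.testing.assert_allclose(
            eig2.values.loc[eig.values.index].to_numpy(),
            eig.values.to_numpy(),
            atol=1e-8,
        )

    def test_constant_module_rejected(self):
        norm = _norm(np.ones((3, 5)))
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(norm, norm.gene_ids)


@pytest.fixture(scope="module")
def family_with_trait():
    cfg = SimulationConfig(n_genes=300, causal_module_size=25, seed=21)
    m, samples, ann, truth = simulate_family(cfg)
    mf = filter_cpm(m)
    return mf, samples, ann, truth


class TestModuleTrait:
    def test_noiseless_trait_perfectly_correlated(self, family_with_trait):
        mf, samples, ann, truth = family_with_trait
        traits = simulate_traits(truth, mf, samples, effect=1.3, noise_sd=0.0, seed=1)
        members = truth.index[truth["module_label"] == "causal"]
        eig = module_eigengene(cpm_normalize(mf, log_scale=True), members)
        tser = traits.set_index("genotype_id")["value"]
        r, p = module_trait_correlation(eig, tser, samples)
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_sign_flips_with_negated_trait(self, family_with_trait):
        mf, samples, ann, truth = family_with_trait
        traits = simulate_traits(truth, mf, samples, effect=1.0, noise_sd=0.2, seed=2)
        members = truth.index[truth["module_label"] == "causal"]
        eig = module_eigengene(cpm_normalize(mf, log_scale=True), members)
        tser = traits.set_index("genotype_id")["value"]
        r1, _ = module_trait_correlation(eig, tser, samples)
        r2, _ = module_trait_correlation(eig, -tser, samples)
        assert r1 == pytest.approx(-r2, abs=1e-12)

    def test_permuted_trait_rarely_strong(self, family_with_trait):
        # independence null: |r| < 0.7 for n = 9 in the vast majority of
        # seeded permutations
        mf, samples, ann, truth = family_with_trait
        traits = simulate_traits(truth, mf, samples, effect=1.0, noise_sd=0.2, seed=3)
        members = truth.index[truth["module_label"] == "causal"]
        eig = module_eigengene(cpm_normalize(mf, log_scale=True), members)
        tser = traits.set_index("genotype_id")["value"]
        rng = np.random.default_rng(99)
        weak = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = pd.Series(rng.permutation(tser.to_numpy()), index=tser.index)
            r, _ = module_trait_correlation(eig, perm, samples)
            weak += abs(r) < 0.7
        assert weak / n_perm >= 0.95


class TestModelFit:
    def test_causal_gene_attains_max_score(self, family_with_trait):
        mf, samples, ann, truth = family_with_trait
        # trait equal to one gene's genotype-mean expression plus small noise
        causal_gene = mf.gene_ids[10]
        norm = cpm_normalize(mf, log_scale=True)
        geno = samples.set_index("sample_id")["genotype_id"]
        expr = norm.values.loc[causal_gene].groupby(geno).mean()
        rng = np.random.default_rng(4)
        traits = pd.DataFrame(
            {"genotype_id": expr.index, "trait_name": "t",
             "value": expr.to_numpy() + rng.normal(0, 0.01 * expr.std(), len(expr))}
        )
        res = TraitAssociationModel(mf, samples, traits, ann).fit()
        rec = res.records
        assert rec.loc[rec["score"].idxmax(), "gene_id"] == causal_gene
        tab = res.manhattan_table("t")
        assert len(tab) == len(rec)

    def test_unmatched_genotypes_reported(self, family_with_trait):
        mf, samples, *_ = family_with_trait
        traits = pd.DataFrame(
            {"genotype_id": ["X1", "X2", "X3"], "trait_name": "t", "value": [1, 2, 3]}
        )
        with pytest.raises(ValueError, match="X1"):
            TraitAssociationModel(mf, samples, traits)


class TestQpcr:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20.0, 18.0, 20.0, 18.0), 1.0),   # ddCt = 0
            ((22.0, 18.0, 20.0, 18.0), 0.25),  # ddCt = 2
            ((20.0, 18.0, 22.0, 18.0), 4.0),   # ddCt = -2
        ],
    )
    def test_comparative_ct(self, cts, expected):
        assert qpcr_relative_expression(*cts) == pytest.approx(expected, abs=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            qpcr_relative_expression(np.nan, 18, 20, 18)
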