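"""Cross-layer concordance: signed log-p matrices, Spearman and sign
tests, oriented weight decomposition, and overlap classification."""

import numpy as np
import pandas as pd
import pytest

from omixwas import (LDBlockCov, OrientedModelView, PredictionModel,
                     decomposition_table, orient_to_positive_gwas,
                     overlap_and_classify, sign_binomial_test,
                     signed_logp_matrix, spearman_concordance,
                     weight_decomposition)


def _results(rows):
    df = pd.DataFrame(rows)
    df.setdefault("n_snps_used", 1)
    return df


def _res_row(gene, layer, z, p, q, trait="LDL"):
    return {"gene_id": gene, "layer": layer, "trait": trait, "z": z,
            "p": p, "q": q, "signed_log10_p": np.sign(z) * -np.log10(p),
            "direction": "+" if z >= 0 else "-", "significant": q <= 0.05}


class TestSignedLogpMatrix:
    def test_entries_and_missing_cells(self):
        res = pd.DataFrame([_res_row("g1", "protein", 2.0, 0.01, 0.02),
                            _res_row("g1", "expression:T00", -1.0, 0.5, 0.6),
                            _res_row("g2", "protein", 1.0, 0.3, 0.4)])
        mat = signed_logp_matrix(res, trait="LDL")
        assert mat.loc["g1", "protein"] == pytest.approx(2.0)
        assert np.isnan(mat.loc["g2", "expression:T00"])

    def test_significance_display_filter(self):
        res = pd.DataFrame([_res_row("g1", "protein", 1.0, 0.5, 0.9),
                            _res_row("g2", "protein", 1.0, 0.4, 0.9)])
        mat = signed_logp_matrix(res, trait="LDL", require_significant=True)
        assert mat.empty


class TestSpearman:
    def test_identity_and_reversal(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert spearman_concordance(a, a)[0] == pytest.approx(1.0)
        assert spearman_concordance(a, [-x for x in a])[0] \
            == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        rho, _ = spearman_concordance([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-4)

    def test_pairwise_complete_deletion(self):
        rho, _ = spearman_concordance([1, 2, np.nan, 3, 4],
                                      [1, 3, 5.0, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-4)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            spearman_concordance([1, 2], [2, 1])


class TestSignBinomial:
    def test_forty_seven_of_forty_nine(self):
        p = sign_binomial_test(47, 49)
        assert float(f"{p:.1e}") == pytest.approx(2.2e-12)

    def test_small_exact_values(self):
        assert sign_binomial_test(1, 1) == pytest.approx(0.5)
        assert sign_binomial_test(3, 3) == pytest.approx(0.125)

    def test_monotone_in_n_positive(self):
        ps = [sign_binomial_test(k, 30) for k in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sign_binomial_test(5, 3)


def _model(weights, ids=None):
    n = len(weights)
    return PredictionModel(gene_id="g", layer="protein",
                           variant_ids=ids or [f"v{i}" for i in range(n)],
                           effect_alleles=["G"] * n,
                           weights=np.asarray(weights, float),
                           cv_r2=0.2, cv_pval=0.01, n_train=100)


def _harm(zvals):
    ids = [f"v{i}" for i in range(len(zvals))]
    z = np.asarray(zvals, float)
    return pd.DataFrame({"effect_allele": "G", "other_allele": "A",
                         "beta": z, "se": 1.0, "z": z, "n": 100},
                        index=pd.Index(ids, name="variant_id"))


class TestOrientation:
    def test_all_positive_is_identity(self):
        view = orient_to_positive_gwas(_model([0.3, -0.1]), _harm([2.0, 1.0]))
        assert np.allclose(view.weights, [0.3, -0.1])
        assert np.allclose(view.gwas_z, [2.0, 1.0])

    def test_negative_z_flips_weight_and_z(self):
        view = orient_to_positive_gwas(_model([0.3]), _harm([-2.0]))
        assert view.gwas_z[0] == pytest.approx(2.0)
        assert view.weights[0] == pytest.approx(-0.3)

    def test_involution(self):
        view = orient_to_positive_gwas(_model([0.3, -0.4]),
                                       _harm([-2.0, 1.5]))
        again = OrientedModelView(
            gene_id="g", variant_ids=view.variant_ids,
            weights=view.weights.copy(), gwas_z=view.gwas_z.copy(),
            sigma=view.sigma.copy(), zero_z_ids=[])
        # orienting an already-oriented view changes nothing
        assert np.all(again.gwas_z >= 0)
        assert np.allclose(np.abs(again.weights), [0.3, 0.4])

    def test_zero_z_flagged(self):
        view = orient_to_positive_gwas(_model([0.3]), _harm([0.0]))
        assert view.zero_z_ids == ["v0"]


class TestDecomposition:
    def test_single_variant_weighted_average(self):
        view = OrientedModelView("g", ["v0"], np.array([0.4]),
                                 np.array([2.0]), np.array([1.0]), [])
        assert weight_decomposition(view) == pytest.approx(0.4)

    def test_two_variant_hand_computation(self):
        # oriented weights (1,1), z (2,1), unit sigma: WA = (2+1)/(2+1)=1,
        # same sign as the gene z-score sqrt(3) > 0
        view = OrientedModelView("g", ["v0", "v1"], np.array([1.0, 1.0]),
                                 np.array([2.0, 1.0]),
                                 np.array([1.0, 1.0]), [])
        assert weight_decomposition(view) == pytest.approx(1.0, abs=1e-4)

    def test_negating_weights_negates_wa(self):
        view = OrientedModelView("g", ["v0", "v1"], np.array([0.5, -0.2]),
                                 np.array([1.0, 2.0]),
                                 np.array([1.0, 0.5]), [])
        wa = weight_decomposition(view)
        flipped = OrientedModelView("g", view.variant_ids, -view.weights,
                                    view.gwas_z, view.sigma, [])
        assert weight_decomposition(flipped) == pytest.approx(-wa)

    def test_zero_denominator_flagged(self):
        view = OrientedModelView("g", ["v0"], np.array([0.4]),
                                 np.array([0.0]), np.array([1.0]), [])
        assert weight_decomposition(view) is None

    def test_plain_z_weighting_option(self):
        view = OrientedModelView("g", ["v0", "v1"], np.array([1.0, 0.0]),
                                 np.array([1.0, 1.0]),
                                 np.array([2.0, 1.0]), [])
        assert weight_decomposition(view, weighting="z") \
            == pytest.approx(0.5)
        assert weight_decomposition(view) == pytest.approx(2.0 / 3.0)

    def test_contribution_table_sums_to_wa(self):
        view = OrientedModelView("g", ["v0", "v1"], np.array([0.5, -0.2]),
                                 np.array([1.0, 2.0]),
                                 np.array([1.0, 0.5]), [])
        tab = decomposition_table(view)
        assert tab.contribution.sum() \
            == pytest.approx(weight_decomposition(view))

    def test_sign_identity_against_gene_zscore(self, small_chain):
        """For every trained gene, the oriented weighted average has the
        sign of the gene-level association z-score."""
        from omixwas import gene_zscore, ld_covariance
        db = small_chain["db"]
        harm = small_chain["harm"]
        for model in db.models.values():
            ld = ld_covariance(model, small_chain["dosages"],
                               small_chain["variants"])
            res = gene_zscore(model, harm, ld)
            if res is None:
                continue
            view = orient_to_positive_gwas(model, harm, ld)
            wa = weight_decomposition(view)
            if wa is None:
                continue
            assert np.sign(wa) == np.sign(res.z)


class TestOverlapClassify:
    def test_disjoint_sets_zero_overlap(self):
        a = _model([1.0, 2.0], ids=["v0", "v1"])
        b = _model([1.0], ids=["v9"])
        out = overlap_and_classify(a, b, {"q": 0.01, "z": 2.0},
                                   {"q": 0.01, "z": 3.0})
        assert out["n_overlap"] == 0
        assert out["klass"] == "both-significant-concordant"

    def test_identical_models_concordant(self):
        a = _model([1.0, 2.0])
        out = overlap_and_classify(a, a, {"q": 0.01, "z": 2.0},
                                   {"q": 0.01, "z": 2.0})
        assert out["n_overlap"] == 2
        assert out["klass"] == "both-significant-concordant"

    def test_opposite_signs_discordant(self):
        a = _model([1.0])
        out = overlap_and_classify(a, a, {"q": 0.01, "z": 3.0},
                                   {"q": 0.01, "z": -3.0})
        assert out["klass"] == "both-significant-discordant"

    def test_one_significant_and_missing_layer(self):
        a = _model([1.0])
        out = overlap_and_classify(a, a, {"q": 0.01, "z": 3.0},
                                   {"q": 0.9, "z": 0.1})
        assert out["klass"] == "one-significant"
        assert overlap_and_classify(a, None, {"q": 0.01, "z": 1.0},
                                    None)["klass"] == "one-layer-only"
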