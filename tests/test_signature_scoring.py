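import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import immunoprofiler as ip
from immunoprofiler.nanostring import SignatureDefinition

from conftest import cohort_expression
from oracles import gsva_brute


def expr_from(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ip.ExpressionMatrix(data=pd.DataFrame(values, index=genes, columns=samples))


def normed(values, panel_probes, samples):
    data = pd.DataFrame(values, index=samples, columns=panel_probes, dtype=float)
    return ip.CountsMatrix(data=data, stage="fully_normalized")


class TestLog2Transform:
    def test_hand_values(self):
        cm = normed([[256.0, 0.0]], ["A", "B"], ["S1"])
        expr = ip.log2_transform(cm)
        assert expr.data.loc["A", "S1"] == 8.0
        assert expr.data.loc["B", "S1"] == 0.0
        assert expr.scale == "log2_counts"

    def test_monotone(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1000, size=50)
        b = a + rng.uniform(0, 100, size=50)
        cm = normed(np.column_stack([a, b]).T, [f"P{i}" for i in range(50)], ["lo", "hi"])
        expr = ip.log2_transform(cm)
        assert (expr.data["hi"] >= expr.data["lo"]).all()

    def test_requires_fully_normalized(self):
        cm = ip.CountsMatrix(data=pd.DataFrame([[1.0]], index=["S"], columns=["G"]), stage="raw")
        with pytest.raises(ValueError):
            ip.log2_transform(cm)


class TestLinearScore:
    def test_zero_weights_and_single_gene(self):
        expr = expr_from([[8.0, 3.0], [5.0, 1.0]])
        zero = SignatureDefinition("zero", pd.Series({"G0": 0.0, "G1": 0.0}))
        assert (ip.linear_score(expr, zero) == 0).all()
        one = SignatureDefinition("one", pd.Series({"G0": 1.0}))
        assert ip.linear_score(expr, one).tolist() == [8.0, 3.0]

    def test_additivity_in_one_gene(self):
        rng = np.random.default_rng(1)
        expr = expr_from(rng.normal(8, 1, size=(5, 4)))
        w = pd.Series(rng.normal(size=5), index=expr.genes)
        sig = SignatureDefinition("s", w)
        base = ip.linear_score(expr, sig)
        bumped = expr.data.copy()
        bumped.loc["G2"] += 0.37
        after = ip.linear_score(ip.ExpressionMatrix(data=bumped), sig)
        np.testing.assert_allclose(after - base, w["G2"] * 0.37, rtol=1e-12)

    def test_missing_gene_is_listed(self):
        expr = expr_from([[1.0, 2.0]])
        sig = SignatureDefinition("s", pd.Series({"G0": 1.0, "ABSENT": 2.0}))
        with pytest.raises(KeyError, match="ABSENT"):
            ip.linear_score(expr, sig)


def test_tis_increases_with_latent_infiltration():
    """The inflammation score tracks the latent infiltration that generated
    the counts (Spearman rho > 0.9 at n = 200, generator defaults)."""
    cfg = ip.simulate.null_config(seed=9, n=200)
    expr, truth, _ = cohort_expression(cfg)
    tis = ip.linear_score(expr, ip.tis_signature())
    z = truth.set_index("sample_id").loc[tis.index, "z"]
    rho = spearmanr(tis.to_numpy(), z.to_numpy()).statistic
    assert rho > 0.9


class TestGSVA:
    def test_identical_samples_get_identical_scores(self):
        rng = np.random.default_rng(2)
        col = rng.normal(8, 2, size=10)
        X = np.column_stack([col, col, rng.normal(8, 2, size=10), col])
        expr = expr_from(X)
        scores = ip.gsva_score(expr, {"set1": ["G0", "G3", "G7"]})
        assert scores.loc["set1", "S0"] == scores.loc["set1", "S1"] == scores.loc["set1", "S3"]

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        expr = expr_from(rng.normal(8, 2, size=(12, 6)))
        sets = {"a": ["G1", "G5", "G9"], "b": ["G0", "G2"]}
        base = ip.gsva_score(expr, sets)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = ip.ExpressionMatrix(data=expr.data.iloc[:, perm])
        out = ip.gsva_score(permuted, sets)
        pd.testing.assert_frame_equal(out, base.iloc[:, perm])

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        expr = expr_from(rng.normal(8, 2, size=(10, 5)))
        sets = {"a": ["G1", "G5", "G9"]}
        base = ip.gsva_score(expr, sets)
        shuffled = ip.ExpressionMatrix(data=expr.data.sample(frac=1, random_state=7))
        pd.testing.assert_frame_equal(ip.gsva_score(shuffled, sets), base)

    @pytest.mark.parametrize("shape,seed", [((6, 5), 0), ((12, 8), 1), ((20, 10), 2)])
    def test_matches_brute_force_oracle(self, shape, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(8, 2, size=shape)
        genes = [f"G{i}" for i in range(shape[0])]
        sets = {"a": genes[::3], "b": genes[1:4]}
        expr = expr_from(X)
        ours = ip.gsva_score(expr, sets)
        ref = gsva_brute(X.tolist(), genes, sets)
        for name in sets:
            np.testing.assert_allclose(ours.loc[name].to_numpy(), ref[name], atol=1e-8)

    def test_errors(self):
        expr = expr_from(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError, match="3 samples"):
            ip.gsva_score(expr, {"a": ["G0"]})
        expr3 = expr_from(np.arange(12.0).reshape(4, 3))
        with pytest.raises(ValueError, match="no genes"):
            ip.gsva_score(expr3, {"a": ["NOPE"]})


class TestHarmonizeRnaseq:
    def test_single_gene_full_mass(self):
        tpm = pd.DataFrame({"S1": [33.0, 0.0]}, index=["CODING", "NONCODING"])
        out = ip.harmonize_rnaseq(tpm, ["CODING"])
        assert out.data.loc["CODING", "S1"] == pytest.approx(np.log2(1e7 + 1))
        assert out.data.loc["CODING", "S1"] == pytest.approx(23.25, abs=0.01)
        assert out.scale == "log2_tpm10"

    def test_rescaled_value(self):
        # two genes; first lands at rescaled TPM 102.4 -> log2(1024 + 1)
        tpm = pd.DataFrame({"S1": [102.4, 1e6 - 102.4]}, index=["A", "B"])
        out = ip.harmonize_rnaseq(tpm, ["A", "B"])
        assert out.data.loc["A", "S1"] == pytest.approx(10.0, abs=0.002)

    def test_rescaling_idempotent(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(0, 50, size=(20, 3))
        tpm = pd.DataFrame(raw * 1e6 / raw.sum(axis=0), index=[f"G{i}" for i in range(20)],
                           columns=list("abc"))
        once = ip.harmonize_rnaseq(tpm, list(tpm.index))
        twice = ip.harmonize_rnaseq(2 ** once.data - 1, list(tpm.index))
        # already normalized to 1e6 per sample up to the range factor: the
        # underlying rescale is a fixed point
        rescaled = tpm.to_numpy() / tpm.to_numpy().sum(axis=0) * 1e6
        np.testing.assert_allclose(rescaled, tpm.to_numpy(), rtol=1e-12)

    def test_all_zero_sample_is_error(self):
        tpm = pd.DataFrame({"S1": [0.0], "S2": [3.0]}, index=["G"])
        with pytest.raises(ValueError, match="S1"):
            ip.harmonize_rnaseq(tpm, ["G"])


def test_zscore_rows_and_coefficient_scoring():
    rng = np.random.default_rng(6)
    expr = expr_from(rng.normal(8, 1, size=(6, 5)))
    z = ip.zscore_rows(expr)
    np.testing.assert_allclose(z.data.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(z.data.std(axis=1, ddof=1), 1, rtol=1e-12)
    sig = SignatureDefinition("pathway", pd.Series({"G0": 0.5, "G3": -1.0}),
                              transform="zscored_log_expression")
    scores = ip.linear_score(z, sig)
    expected = 0.5 * z.data.loc["G0"] - 1.0 * z.data.loc["G3"]
    np.testing.assert_allclose(scores.to_numpy(), expected.to_numpy(), rtol=1e-12)
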