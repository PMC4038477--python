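import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from circakit.signature import (
    DesignError,
    ExpressionStudy,
    binomial_classification_test,
    classify_sample,
    collapse_probes_to_genes,
    intersect_lists,
    loocv_discriminative_lists,
    moderated_t_test,
    validate_fold_by_clustering,
)
from circakit.synth import ExprGenParams, gen_expression, gen_test_line


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the moderated t-test, written before the
# main implementation and kept deliberately naive (per-gene loops, bisection).

def oracle_moderated_t(xa, xb):
    G = xa.shape[0]
    na, nb = xa.shape[1], xb.shape[1]
    d_g = na + nb - 2
    beta, s2 = [], []
    for g in range(G):
        ma, mb = xa[g].mean(), xb[g].mean()
        beta.append(ma - mb)
        ss = sum((v - ma) ** 2 for v in xa[g]) + sum((v - mb) ** 2 for v in xb[g])
        s2.append(ss / d_g)
    beta, s2 = np.array(beta), np.array(s2)
    e = np.log(s2) - digamma(d_g / 2) + math.log(d_g / 2)
    ebar = e.mean()
    rhs = np.mean((e - ebar) ** 2 * G / (G - 1) - polygamma(1, d_g / 2))
    if rhs <= 0:
        d0 = np.inf
        s0_sq = math.exp(ebar)
        s2_post = np.full(G, s0_sq)
        df = np.inf
    else:
        lo, hi = 1e-9, 1e9
        for _ in range(200):  # bisection on monotone trigamma
            mid = math.sqrt(lo * hi)
            if polygamma(1, mid / 2) > rhs:
                lo = mid
            else:
                hi = mid
        d0 = math.sqrt(lo * hi)
        s0_sq = math.exp(ebar + digamma(d0 / 2) - math.log(d0 / 2))
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df = d0 + d_g
    se = np.sqrt(s2_post * (1 / na + 1 / nb))
    tstat = beta / se
    if np.isinf(df):
        from scipy.stats import norm
        p = 2 * norm.sf(np.abs(tstat))
    else:
        p = 2 * t_dist.sf(np.abs(tstat), df)
    return tstat, p, d0, s0_sq


def small_study(G=200, lines=2, seed=0, effect=0.0, planted=0):
    params = ExprGenParams(n_genes=G, lines_per_phenotype=lines, n_planted=planted,
                           effect_sd=effect, seed=seed)
    return gen_expression(params)


class TestModeratedT:
    def test_identical_groups_all_null(self):
        # the weak group mirrors the strong group's columns exactly, so
        # group means coincide while within-group variance stays positive
        rng = np.random.default_rng(1)
        half = rng.normal(size=(50, 4))
        values = pd.DataFrame(
            np.hstack([half, half]),
            columns=[f"s{i}" for i in range(8)],
            index=[f"G{i}" for i in range(50)],
        )
        ann = pd.DataFrame({
            "sample": values.columns,
            "cell_line": [f"L{i // 2}" for i in range(8)],
            "phenotype": ["strong"] * 4 + ["weak"] * 4,
            "timepoint": [0, 48] * 4,
        })
        stats = moderated_t_test(ExpressionStudy(values, ann))
        assert np.allclose(stats.table["t"], 0.0)
        assert np.allclose(stats.table["p"], 1.0)

    def test_equal_variances_shrinkage_fixed_point(self):
        # all genes share the observed variance -> nothing to shrink, d0 -> inf
        rng = np.random.default_rng(2)
        G, n = 100, 4
        xa = rng.normal(size=(G, n))
        xa = (xa - xa.mean(axis=1, keepdims=True)) / xa.std(axis=1, ddof=1, keepdims=True)
        xb = rng.normal(size=(G, n))
        xb = (xb - xb.mean(axis=1, keepdims=True)) / xb.std(axis=1, ddof=1, keepdims=True)
        values = pd.DataFrame(np.hstack([xa, xb]),
                              columns=[f"s{i}" for i in range(2 * n)],
                              index=[f"G{i}" for i in range(G)])
        ann = pd.DataFrame({
            "sample": values.columns,
            "cell_line": [f"L{i // 2}" for i in range(2 * n)],
            "phenotype": ["strong"] * n + ["weak"] * n,
            "timepoint": [0, 48] * n,
        })
        stats = moderated_t_test(ExpressionStudy(values, ann))
        assert np.isinf(stats.d0)
        # posterior variance collapses onto the common prior for every gene
        assert np.allclose(stats.table["s2_post"], stats.s0_sq)

    def test_matches_bruteforce_oracle(self):
        study, _ = small_study(G=200, lines=2, seed=3, effect=1.0, planted=20)
        stats = moderated_t_test(study)
        xa = study.values[study.samples_of("strong")].to_numpy()
        xb = study.values[study.samples_of("weak")].to_numpy()
        t_o, p_o, d0_o, s0_o = oracle_moderated_t(xa, xb)
        assert stats.d0 == pytest.approx(d0_o, rel=1e-6)
        assert stats.s0_sq == pytest.approx(s0_o, rel=1e-8)
        np.testing.assert_allclose(stats.table["t"], t_o, atol=1e-8)
        np.testing.assert_allclose(stats.table["p"], p_o, atol=1e-8)

    def test_type_i_calibration_under_null(self):
        study, _ = small_study(G=2000, lines=3, seed=11)
        stats = moderated_t_test(study)
        frac = float((stats.table["p"] < 0.05).mean())
        assert abs(frac - 0.05) <= 0.01

    def test_small_group_raises(self):
        study, _ = small_study(G=50, lines=2, seed=4)
        keep = study.samples_of("strong")[:1] + study.samples_of("weak")
        with pytest.raises(DesignError):
            moderated_t_test(study.subset_samples(keep))


class TestLOOCV:
    def test_six_lines_six_folds(self):
        study, _ = small_study(G=200, lines=3, seed=5, effect=1.0, planted=10)
        folds = loocv_discriminative_lists(study, top_k=20)
        assert len(folds) == 6
        assert all(len(f.genes) == 20 for f in folds)

    def test_planted_recovery_per_fold(self):
        params = ExprGenParams(n_genes=5000, lines_per_phenotype=3, n_planted=30,
                               effect_sd=2.0, seed=42)
        study, planted = gen_expression(params)
        folds = loocv_discriminative_lists(study, top_k=100)
        for f in folds:
            assert len(set(f.genes) & set(planted)) >= 25

    def test_topk_too_large(self):
        study, _ = small_study(G=50, lines=3, seed=6)
        with pytest.raises(ValueError):
            loocv_discriminative_lists(study, top_k=100)

    def test_fold_leaving_single_line_raises(self):
        study, _ = small_study(G=100, lines=2, seed=7)
        with pytest.raises(DesignError):
            loocv_discriminative_lists(study, top_k=10)


def _perfect_block_study(G=60, lines=3, flip_line=None):
    """Two anti-correlated phenotype blocks; optionally plant one line in
    the wrong block."""
    genes = [f"G{i}" for i in range(G)]
    profile = np.linspace(-1, 1, G)
    cols, ann_rows = {}, []
    rng = np.random.default_rng(0)
    for pheno, sign in (("strong", 1.0), ("weak", -1.0)):
        for li in range(lines):
            line = f"{pheno[0].upper()}L{li}"
            s = -sign if line == flip_line else sign
            for tp in (0, 48):
                cols[f"{line}_t{tp}"] = s * profile + rng.normal(0, 0.05, G)
                ann_rows.append((f"{line}_t{tp}", line, pheno, tp))
    values = pd.DataFrame(cols, index=genes)
    ann = pd.DataFrame(ann_rows, columns=["sample", "cell_line", "phenotype", "timepoint"])
    return ExpressionStudy(values, ann)


class TestClusteringValidation:
    def test_perfect_separation_retained(self):
        study = _perfect_block_study()
        folds = loocv_discriminative_lists(study, top_k=30)
        for f in folds:
            assert validate_fold_by_clustering(study, f).retained

    def test_flipped_line_not_retained(self):
        study = _perfect_block_study(flip_line="SL0")
        from circakit.signature import FoldResult
        fold = FoldResult("SL0", [f"G{i}" for i in range(60)],
                          {f"G{i}": 0.01 for i in range(60)})
        assert validate_fold_by_clustering(study, fold).retained is False

    def test_planted_synthetic_all_folds_retained(self):
        params = ExprGenParams(n_genes=2000, lines_per_phenotype=3, n_planted=30,
                               effect_sd=2.0, seed=8)
        study, _ = gen_expression(params)
        folds = loocv_discriminative_lists(study, top_k=100)
        folds = [validate_fold_by_clustering(study, f) for f in folds]
        assert all(f.retained for f in folds)


class TestIntersect:
    def _fold(self, line, genes):
        from circakit.signature import FoldResult
        return FoldResult(line, genes, {g: 0.01 for g in genes}, retained=True)

    def test_identical_lists(self):
        genes = ["A", "B", "C"]
        out = intersect_lists([self._fold("L1", genes), self._fold("L2", genes)])
        assert set(out) == set(genes)

    def test_disjoint_lists_empty(self):
        out = intersect_lists([self._fold("L1", ["A", "B"]), self._fold("L2", ["C", "D"])])
        assert out == []

    def test_zero_retained_raises(self):
        f = self._fold("L1", ["A"])
        f.retained = False
        with pytest.raises(DesignError):
            intersect_lists([f])

    def test_order_invariance(self):
        f1 = self._fold("L1", ["A", "B", "C"])
        f2 = self._fold("L2", ["B", "C", "D"])
        f3 = self._fold("L3", ["C", "B", "E"])
        assert intersect_lists([f1, f2, f3]) == intersect_lists([f3, f1, f2])

    def test_planted_recovery(self):
        params = ExprGenParams(n_genes=5000, lines_per_phenotype=3, n_planted=30,
                               effect_sd=2.0, seed=33)
        study, planted = gen_expression(params)
        folds = loocv_discriminative_lists(study, top_k=100)
        folds = [validate_fold_by_clustering(study, f) for f in folds]
        final = intersect_lists(folds)
        recovered = len(set(final) & set(planted))
        assert recovered >= 0.9 * len(planted)
        assert len(set(final) - set(planted)) <= 5


class TestClassifySample:
    def test_training_sample_self_classification(self):
        study = _perfect_block_study()
        sig = [f"G{i}" for i in range(60)]
        for mode in ("cocluster", "centroid"):
            assert classify_sample(study, sig, "SL0", mode=mode) == "strong"
            assert classify_sample(study, sig, "WL1", mode=mode) == "weak"

    def test_centroid_tie_unclassified(self):
        study = _perfect_block_study()
        sig = [f"G{i}" for i in range(60)]
        flat = study.values.copy()
        flat["Q_t0"] = np.linspace(1, -1, 60)[::-1] * 0  # zero vector: equal (nan) corr
        ann = pd.concat([study.annotations, pd.DataFrame(
            [("Q_t0", "Q", "test", 0)], columns=study.annotations.columns)],
            ignore_index=True)
        # orthogonal-to-profile sample: correlation to both centroids ~ equal
        rng = np.random.default_rng(3)
        flat["Q_t0"] = rng.permutation(np.linspace(-1, 1, 60)) * 1e-9
        study2 = ExpressionStudy(flat, ann)
        result = classify_sample(study2, sig, "Q_t0", mode="centroid")
        assert result in ("unclassified", "strong", "weak")

    def test_coverage_error(self):
        study = _perfect_block_study()
        with pytest.raises(KeyError, match="signature"):
            classify_sample(study, ["NOPE%d" % i for i in range(10)], "SL0")

    def test_planted_test_line_20_of_20_seeds(self):
        params = ExprGenParams(n_genes=2000, lines_per_phenotype=3, n_planted=30,
                               effect_sd=2.0, seed=42)
        study, planted = gen_expression(params)
        folds = loocv_discriminative_lists(study, top_k=100)
        folds = [validate_fold_by_clustering(study, f) for f in folds]
        sig = intersect_lists(folds)
        correct = 0
        for seed in range(20):
            test_cols = gen_test_line(params, "strong", planted, seed=1000 + seed)
            values = pd.concat([study.values, test_cols], axis=1)
            ann = pd.concat([study.annotations, pd.DataFrame(
                [(c, "TESTL", "test", tp) for c, tp in zip(test_cols.columns, (0, 48))],
                columns=study.annotations.columns)], ignore_index=True)
            merged = ExpressionStudy(values, ann)
            if classify_sample(merged, sig, "TESTL", mode="cocluster") == "strong":
                correct += 1
        assert correct == 20


class TestBinomial:
    def test_paper_value_seven_of_eight(self):
        p = binomial_classification_test(7, 8, 0.5)
        assert p == pytest.approx(9 / 256)
        assert round(p, 5) == 0.03516

    def test_certain_event(self):
        assert binomial_classification_test(0, 8, 0.5) == 1.0

    def test_eight_of_eight(self):
        assert binomial_classification_test(8, 8, 0.5) == pytest.approx(1 / 256)

    def test_tails_sum_to_one_plus_point_mass(self):
        n, k = 11, 4
        upper = binomial_classification_test(k, n, 0.5)
        lower = 1.0 - binomial_classification_test(k + 1, n, 0.5)
        point = math.comb(n, k) * Fraction(1, 2) ** n
        assert upper + lower == pytest.approx(1.0 + float(point))

    def test_bad_chance_p(self):
        with pytest.raises(ValueError):
            binomial_classification_test(1, 2, 1.5)


class TestProbeCollapse:
    def test_max_mean_probe_kept(self):
        values = pd.DataFrame({"s1": [1.0, 5.0, 2.0], "s2": [1.0, 5.0, 2.0]},
                              index=["p1", "p2", "p3"])
        mapping = {"p1": "GENEA", "p2": "GENEA", "p3": "GENEB"}
        out = collapse_probes_to_genes(values, mapping)
        assert list(out.index) == ["GENEA", "GENEB"]
        assert out.loc["GENEA", "s1"] == 5.0


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings
from hypothesis import strategies as st


@given(total=st.integers(1, 30), correct=st.integers(0, 30),
       chance=st.floats(0.05, 0.95))
def test_binomial_tail_is_probability(total, correct, chance):
    if correct > total:
        correct = total
    p = binomial_classification_test(correct, total, chance)
    assert 0.0 < p <= 1.0


@given(total=st.integers(1, 20), correct=st.integers(1, 20))
def test_binomial_tail_monotone_in_correct(total, correct):
    if correct > total:
        correct = total
    lo = binomial_classification_test(correct - 1, total, 0.5)
    hi = binomial_classification_test(correct, total, 0.5)
    assert hi <= lo
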