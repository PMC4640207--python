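"""Immune signature construction, TIL gating, subtypes, DE with step-up FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from famcna import expression as ex
from famcna.exceptions import ConfigurationError, DegenerateInputError
from oracles import oracle_bh, oracle_spearman


def _matrix(rng, n_genes=300, n_samples=40, sd=0.25):
    x = rng.normal(7, 1, n_genes)[:, None] + rng.normal(
        0, sd, (n_genes, n_samples))
    return pd.DataFrame(x, index=[f"G{i:04d}" for i in range(n_genes)],
                        columns=[f"S{i:03d}" for i in range(n_samples)])


def _planted_signature(rng, n_sig=30, n_genes=300, n_samples=60,
                       shift_sd_units=1.5, sd=0.25):
    """Matrix with binary TIL groups and a mixed-direction planted signature."""
    matrix = _matrix(rng, n_genes, n_samples, sd)
    high = np.arange(n_samples) % 2 == 1
    directions = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
    matrix.iloc[:n_sig, high] += (shift_sd_units * sd * directions)[:, None]
    til = pd.Series(np.where(high, 80.0, 10.0), index=matrix.columns)
    return matrix, til, high, list(matrix.index[:n_sig])


class TestBhFdr:
    def test_worked_case_all_point_04(self):
        out = ex.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    @settings(max_examples=100)
    def test_matches_direct_min_over_tail_formula(self, p):
        p = np.array(p)
        assert np.allclose(ex.bh_fdr(p), oracle_bh(p), atol=1e-12)

    def test_monotone_in_rank_order(self, rng):
        p = rng.uniform(size=200)
        adjusted = ex.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-15).all()


class TestAnova:
    def test_matches_scipy_f_oneway(self, rng):
        x = rng.normal(0, 1, (50, 30))
        in_a = np.arange(30) < 12
        f, p = ex._anova_two_group(x, in_a)
        for i in range(0, 50, 7):
            ref = stats.f_oneway(x[i, in_a], x[i, ~in_a])
            assert f[i] == pytest.approx(ref.statistic)
            assert p[i] == pytest.approx(ref.pvalue)

    def test_identical_means_give_f_zero(self):
        x = np.tile(np.array([1.0, 2.0, 1.0, 2.0]), (3, 1))
        f, p = ex._anova_two_group(x, np.array([True, True, False, False]))
        assert np.allclose(f, 0.0) and np.allclose(p, 1.0)

    def test_zero_variance_unequal_means_flagged(self):
        x = np.array([[1.0, 1.0, 2.0, 2.0]])
        f, p = ex._anova_two_group(x, np.array([True, True, False, False]))
        assert np.isinf(f[0]) and p[0] == 0.0


class TestSignature:
    def test_null_simulation_yields_empty_signature(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            matrix = _matrix(rng, n_genes=500, n_samples=60)
            til = pd.Series(rng.uniform(0, 100, 60), index=matrix.columns)
            subtypes = pd.Series(["luminal"] * 40 + ["basal"] * 20,
                                 index=matrix.columns)
            sig = ex.build_immune_signature(matrix, til, subtypes)
            sizes.append(len(sig))
        assert np.mean(sizes) <= 1.0

    def test_planted_shift_recovered_in_both_strata(self):
        # 1.5-SD shift between TIL groups at study-scale strata (82 luminal /
        # 38 basal, 2000 genes): most signature genes are recovered and the
        # recovered set is essentially pure
        fractions, purities = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            matrix, til, high, sig_genes = _planted_signature(
                rng, n_sig=100, n_genes=2000, n_samples=120)
            subtypes = pd.Series(
                np.where(np.arange(120) < 82, "luminal", "basal"),
                index=matrix.columns)
            sig = ex.build_immune_signature(matrix, til, subtypes)
            fractions.append(len(set(sig.genes) & set(sig_genes))
                             / len(sig_genes))
            purities.append(len(set(sig.genes) & set(sig_genes))
                            / max(len(sig.genes), 1))
        assert np.mean(fractions) >= 0.8
        assert np.mean(purities) >= 0.9

    def test_direction_signs_match_planting(self, rng):
        matrix, til, high, sig_genes = _planted_signature(rng)
        subtypes = pd.Series(np.where(np.arange(60) % 4 < 2, "luminal",
                                      "basal"), index=matrix.columns)
        sig = ex.build_immune_signature(matrix, til, subtypes)
        for i, gene in enumerate(sig_genes):
            if gene in sig.genes:
                assert sig.direction[gene] == (1 if i % 2 == 0 else -1)

    def test_median_ties_go_to_low_group(self):
        values = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0])
        high = ex.median_split(values)
        assert list(high) == [False, False, False, True, True]

    def test_order_invariance(self, rng):
        matrix, til, _, _ = _planted_signature(rng)
        subtypes = pd.Series(np.where(np.arange(60) % 4 < 2, "luminal",
                                      "basal"), index=matrix.columns)
        sig1 = ex.build_immune_signature(matrix, til, subtypes)
        perm = rng.permutation(matrix.shape[1])
        sig2 = ex.build_immune_signature(matrix.iloc[:, perm], til, subtypes)
        assert sig1.genes == sig2.genes

    def test_small_stratum_rejected(self, rng):
        matrix = _matrix(rng, n_samples=6)
        til = pd.Series(np.arange(6.0), index=matrix.columns)
        subtypes = pd.Series(["luminal"] * 3 + ["basal"] * 3,
                             index=matrix.columns)
        with pytest.raises(ConfigurationError, match="median split"):
            ex.build_immune_signature(matrix, til, subtypes)


class TestGate:
    def test_separable_groups_recovered_exactly(self, rng):
        matrix, til, high, sig_genes = _planted_signature(
            rng, shift_sd_units=8.0)
        sig = ex.ImmuneSignature(
            genes=sig_genes,
            direction=pd.Series([1 if i % 2 == 0 else -1
                                 for i in range(len(sig_genes))],
                                index=sig_genes))
        got = ex.gate_til(matrix, sig)
        assert (got.to_numpy() == high).all()

    def test_identical_samples_raise_rather_than_split(self):
        matrix = pd.DataFrame(np.tile(np.arange(10.0)[:, None], (1, 6)),
                              index=[f"G{i}" for i in range(10)],
                              columns=[f"S{i}" for i in range(6)])
        sig = ex.ImmuneSignature(genes=[f"G{i}" for i in range(10)],
                                 direction=pd.Series(1, index=[f"G{i}" for i
                                                               in range(10)]))
        with pytest.raises(DegenerateInputError):
            ex.gate_til(matrix, sig)

    def test_empty_signature_rejected(self, rng):
        matrix = _matrix(rng)
        sig = ex.ImmuneSignature(genes=[], direction=pd.Series(dtype=int))
        with pytest.raises(ConfigurationError):
            ex.signature_score(matrix, sig)


class TestSpearman:
    def test_strictly_monotone_pairs(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert ex.spearman_til(x, x * 2)[0] == pytest.approx(1.0)
        assert ex.spearman_til(x, -x)[0] == pytest.approx(-1.0)

    def test_tie_case_matches_hand_rank_oracle(self):
        score = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0])
        til = pd.Series([0.1, 0.5, 0.2, 0.9, 0.8])
        rho, _ = ex.spearman_til(score, til)
        assert rho == pytest.approx(
            oracle_spearman(score.to_numpy(), til.to_numpy()))

    def test_constant_input_reported_undefined(self):
        score = pd.Series([1.0, 1.0, 1.0])
        til = pd.Series([0.1, 0.2, 0.3])
        rho, p = ex.spearman_til(score, til)
        assert np.isnan(rho) and np.isnan(p)


class TestSubtype:
    def _subtype_data(self, rng, sep=2.0, n_int=40, n_samples=30):
        matrix = _matrix(rng, n_genes=200, n_samples=n_samples)
        luminal = np.arange(n_samples) < n_samples // 2
        signs = np.where(np.arange(n_int) < n_int // 2, 1.0, -1.0)
        base = matrix.iloc[:n_int].mean(axis=1).to_numpy()
        matrix.iloc[:n_int, luminal] += (sep / 2 * signs)[:, None]
        matrix.iloc[:n_int, ~luminal] -= (sep / 2 * signs)[:, None]
        intrinsic = list(matrix.index[:n_int])
        archetypes = pd.DataFrame({
            "luminal": base + sep / 2 * signs,
            "basal": base - sep / 2 * signs}, index=intrinsic)
        truth = np.where(luminal, "luminal", "basal")
        return matrix, intrinsic, archetypes, truth

    def test_planted_archetypes_recovered(self, rng):
        matrix, intrinsic, archetypes, truth = self._subtype_data(rng)
        got = ex.assign_subtype(matrix, intrinsic, archetypes)
        assert (got.to_numpy() == truth).all()

    def test_sample_order_invariance(self, rng):
        matrix, intrinsic, archetypes, truth = self._subtype_data(rng)
        got = ex.assign_subtype(matrix, intrinsic, archetypes)
        perm = rng.permutation(matrix.shape[1])
        got2 = ex.assign_subtype(matrix.iloc[:, perm], intrinsic, archetypes)
        assert (got2.loc[got.index] == got).all()

    def test_accuracy_over_replicates(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            matrix, intrinsic, archetypes, truth = self._subtype_data(
                rng, sep=1.0)
            got = ex.assign_subtype(matrix, intrinsic, archetypes)
            accs.append((got.to_numpy() == truth).mean())
        assert np.mean(accs) >= 0.95

    def test_empty_overlap_rejected(self, rng):
        matrix = _matrix(rng)
        with pytest.raises(ConfigurationError):
            ex.assign_subtype(matrix, ["missing"],
                              pd.DataFrame({"luminal": [], "basal": []}))


class TestDifferentialExpression:
    def test_no_effect_gives_flat_f_and_high_fdr(self, rng):
        matrix = _matrix(rng, n_genes=200, n_samples=48)
        labels = pd.Series(["a"] * 14 + ["b"] * 34, index=matrix.columns)
        de = ex.differential_expression(matrix, labels, "a", "b")
        assert (de["fdr_p"] > 0.2).mean() > 0.95

    def test_fold_change_convention_signed_ratio(self, rng):
        matrix = _matrix(rng, n_genes=10, n_samples=20, sd=0.01)
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=matrix.columns)
        matrix.iloc[0, :10] += 1.0   # higher in a: FC ~ +2
        matrix.iloc[1, 10:] += 1.0   # higher in b: FC ~ -2
        de = ex.differential_expression(matrix, labels, "a", "b")
        assert de["fold_change"].iloc[0] == pytest.approx(2.0, rel=0.05)
        assert de["fold_change"].iloc[1] == pytest.approx(-2.0, rel=0.05)
        assert (de["fold_change"].abs() >= 1.0).all()

    def test_planted_effect_detected(self, rng):
        matrix = _matrix(rng, n_genes=500, n_samples=48)
        labels = pd.Series(["a"] * 14 + ["b"] * 34, index=matrix.columns)
        matrix.iloc[:5, :14] += 1.26
        de = ex.differential_expression(matrix, labels, "a", "b")
        assert (de["fdr_p"].iloc[:5] < 0.05).all()

    def test_null_fdr_control(self):
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            matrix = _matrix(rng, n_genes=400, n_samples=30)
            labels = pd.Series(["a"] * 15 + ["b"] * 15, index=matrix.columns)
            de = ex.differential_expression(matrix, labels, "a", "b")
            fractions.append((de["fdr_p"] < 0.05).mean())
        assert np.mean(fractions) <= 0.05

    def test_extra_classes_dropped(self, rng):
        matrix = _matrix(rng, n_genes=20, n_samples=30)
        labels = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                           index=matrix.columns)
        de = ex.differential_expression(matrix, labels, "a", "b")
        assert len(de) == 20
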