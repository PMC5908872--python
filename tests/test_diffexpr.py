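"""NB differential-expression stage: size factors, dispersion, Wald, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lymphomap import diffexpr
from lymphomap.simulate import simulate_null
from lymphomap.types import ConfigError

from conftest import make_count_matrix, make_design


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_count_matrix([[5, 5], [9, 9], [2, 2]])
        sf = diffexpr.estimate_size_factors(cm)
        assert np.allclose(sf, [1.0, 1.0])

    def test_hand_computed_example(self):
        """Counts [[2,4],[4,8],[6,12]]: all per-gene ratios are 1/sqrt(2) and
        sqrt(2), so the medians are (0.707, 1.414), already at geometric mean 1."""
        cm = make_count_matrix([[2, 4], [4, 8], [6, 12]])
        sf = diffexpr.estimate_size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_scale_equivariance_in_ratio(self, rng):
        vals = rng.integers(1, 100, size=(50, 3))
        cm = make_count_matrix(vals)
        sf1 = diffexpr.estimate_size_factors(cm)
        vals2 = vals.copy()
        vals2[:, 1] *= 2
        sf2 = diffexpr.estimate_size_factors(make_count_matrix(vals2))
        # rescaling to geometric mean 1 cancels in ratios
        assert np.isclose(
            (sf2.iloc[1] / sf2.iloc[0]), 2.0 * (sf1.iloc[1] / sf1.iloc[0])
        )

    def test_geometric_mean_is_one(self, rng):
        vals = rng.integers(1, 500, size=(100, 6))
        sf = diffexpr.estimate_size_factors(make_count_matrix(vals))
        assert abs(np.mean(np.log(sf))) < 1e-9

    def test_error_when_no_all_positive_gene(self):
        cm = make_count_matrix([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="total-count"):
            diffexpr.estimate_size_factors(cm)


class TestModeratedLog:
    @pytest.mark.parametrize(
        "count,s,pc,expected",
        [(0, 1.0, 1.0, 0.0), (7, 1.0, 1.0, 3.0), (100, 2.0, 0.5, np.log2(50.5))],
    )
    def test_pointwise_values(self, count, s, pc, expected):
        cm = make_count_matrix([[count]])
        sf = pd.Series([s], index=["s0"])
        out = diffexpr.moderated_log(cm, sf, pseudocount=pc)
        assert out.iloc[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_count(self):
        cm = make_count_matrix([[i] for i in range(20)])
        sf = pd.Series([1.0], index=["s0"])
        out = diffexpr.moderated_log(cm, sf).to_numpy().ravel()
        assert (np.diff(out) > 0).all()

    def test_nonpositive_pseudocount_rejected(self):
        cm = make_count_matrix([[1]])
        with pytest.raises(ConfigError):
            diffexpr.moderated_log(cm, pd.Series([1.0], index=["s0"]), pseudocount=0)


class TestDispersion:
    def _mc_design(self, n):
        samples = {f"a{i}": "A" for i in range(n // 2)}
        samples.update({f"b{i}": "control" for i in range(n - n // 2)})
        return make_design(samples)

    def test_poisson_gene_estimates_near_zero(self):
        """500 Poisson genes at mu=100, n=20: mean raw alpha-hat within 0.02 of 0."""
        rng = np.random.default_rng(7)
        vals = rng.poisson(100.0, size=(500, 20))
        design = self._mc_design(20)
        cm = make_count_matrix(vals, sample_ids=list(design.sample_to_group.index))
        alpha_raw, _ = diffexpr.method_of_moments_alpha(
            cm.counts.astype(float), design
        )
        assert abs(alpha_raw.mean()) < 0.02

    def test_nb_dispersion_recovery(self):
        """500 NB genes at alpha=0.2, mu=100, n=40: mean estimate within 25%."""
        rng = np.random.default_rng(8)
        alpha, mu = 0.2, 100.0
        vals = rng.poisson(rng.gamma(1 / alpha, alpha * mu, size=(500, 40)))
        design = self._mc_design(40)
        cm = make_count_matrix(vals, sample_ids=list(design.sample_to_group.index))
        alpha_raw, _ = diffexpr.method_of_moments_alpha(
            cm.counts.astype(float), design
        )
        assert abs(alpha_raw.mean() - alpha) / alpha < 0.25

    def test_constant_gene_clamped_to_zero(self):
        design = make_design({"a": "A", "b": "A", "c": "control", "d": "control"})
        cm = make_count_matrix([[5, 5, 5, 5]], sample_ids=list("abcd"))
        alpha_raw, _ = diffexpr.method_of_moments_alpha(cm.counts.astype(float), design)
        assert alpha_raw[0] == 0.0

    def test_shrinkage_moves_toward_trend(self, rng):
        vals = rng.poisson(rng.gamma(10.0, 0.01 * 50, size=(200, 10)))
        design = self._mc_design(10)
        cm = make_count_matrix(vals, sample_ids=list(design.sample_to_group.index))
        sf = pd.Series(1.0, index=cm.sample_ids)
        a_raw = diffexpr.estimate_dispersion(cm, sf, design, shrink=0.0)
        a_full = diffexpr.estimate_dispersion(cm, sf, design, shrink=1.0)
        a_half = diffexpr.estimate_dispersion(cm, sf, design, shrink=0.5)
        assert np.allclose(a_half, 0.5 * a_raw + 0.5 * a_full, atol=1e-12)

    def test_all_singleton_groups_rejected(self):
        design = make_design({"a": "A", "b": "B", "c": "control"}, validate=False)
        cm = make_count_matrix([[1, 2, 3]], sample_ids=list("abc"))
        with pytest.raises(ValueError, match="2 replicates"):
            diffexpr.method_of_moments_alpha(cm.counts.astype(float), design)


class TestWald:
    def test_identical_groups_give_zero_fc_p_one(self):
        design = make_design({"a": "G", "b": "G", "c": "control", "d": "control"})
        sf = pd.Series(1.0, index=list("abcd"))
        lfc, se, w, p = diffexpr.wald_test_group(
            pd.Series([12, 12, 12, 12], index=list("abcd")), sf, design, "G", 0.1
        )
        assert lfc == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_p_from_wald_is_two_sided_normal(self):
        """A Wald statistic of +/-1.959964 corresponds to p = 0.05."""
        design = make_design({"a": "G", "b": "G", "c": "control", "d": "control"})
        sf = pd.Series(1.0, index=list("abcd"))
        raw = diffexpr.wald_test_all(
            pd.DataFrame([[30, 40, 20, 25]], index=["g"], columns=list("abcd")),
            sf, design, np.array([0.05]),
        )
        row = raw.iloc[0]
        assert row.p == pytest.approx(2 * stats.norm.sf(abs(row.wald)), rel=1e-12)
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_closed_form_fold_change_at_zero_dispersion(self):
        """Control (10,10) vs group (40,40) at alpha=0: log2fc = 2 exactly."""
        design = make_design({"a": "G", "b": "G", "c": "control", "d": "control"})
        sf = pd.Series(1.0, index=list("abcd"))
        lfc, se, w, p = diffexpr.wald_test_group(
            pd.Series([40, 40, 10, 10], index=list("abcd")), sf, design, "G", 0.0
        )
        assert lfc == pytest.approx(2.0, abs=1e-8)

    def test_size_factors_enter_the_fit(self):
        """Doubling a sample's size factor halves its effective contribution."""
        design = make_design({"a": "G", "b": "G", "c": "control", "d": "control"})
        sf = pd.Series([2.0, 2.0, 1.0, 1.0], index=list("abcd"))
        lfc, *_ = diffexpr.wald_test_group(
            pd.Series([20, 20, 10, 10], index=list("abcd")), sf, design, "G", 0.0
        )
        assert lfc == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_group_stays_finite(self):
        design = make_design({"a": "G", "b": "G", "c": "control", "d": "control"})
        sf = pd.Series(1.0, index=list("abcd"))
        lfc, se, w, p = diffexpr.wald_test_group(
            pd.Series([0, 0, 50, 50], index=list("abcd")), sf, design, "G", 0.1
        )
        assert np.isfinite(lfc) and lfc < 0
        assert np.isfinite(p)

    def test_contrasting_control_rejected(self):
        design = make_design({"a": "G", "b": "G", "c": "control", "d": "control"})
        sf = pd.Series(1.0, index=list("abcd"))
        with pytest.raises(ConfigError):
            diffexpr.wald_test_group(
                pd.Series([1, 1, 1, 1], index=list("abcd")), sf, design, "control", 0.1
            )

    def test_vectorized_matches_per_gene_calls(self, rng):
        design = make_design(
            {"a": "G", "b": "G", "c": "G", "d": "control", "e": "control"}
        )
        samples = list("abcde")
        vals = rng.integers(0, 200, size=(30, 5))
        counts = pd.DataFrame(vals, index=[f"g{i}" for i in range(30)], columns=samples)
        sf = pd.Series(rng.uniform(0.7, 1.4, 5), index=samples)
        alphas = rng.uniform(0.01, 0.3, 30)
        full = diffexpr.wald_test_all(counts, sf, design, alphas)
        for i in [0, 7, 19, 29]:
            lfc, se, w, p = diffexpr.wald_test_group(
                counts.iloc[i], sf, design, "G", alphas[i]
            )
            row = full.iloc[i]
            assert row.log2fc == pytest.approx(lfc, abs=1e-9)
            assert row.p == pytest.approx(p, abs=1e-9)


def brute_force_bh(p):
    """Literal step-up definition: q_i = min over p_(j) >= p_i of p_(j)*n/rank(j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = [p[order[j]] * n / (j + 1) for j in range(n)]
    q = np.empty(n)
    for i in range(n):
        q[i] = min(1.0, min(adj[j] for j in range(n) if p[order[j]] >= p[i]))
    return q


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_known_vectors(self, p, expected):
        assert np.allclose(diffexpr.bh_adjust(p), expected, atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            p = np.round(rng.random(n), 3)
            assert np.allclose(diffexpr.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 200)))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(diffexpr.bh_adjust(p), q_sm, atol=1e-12)

    def test_order_preserving_and_q_ge_p(self, rng):
        p = rng.random(100)
        q = diffexpr.bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([-0.1])


class TestCalls:
    def _result(self, rows):
        table = pd.DataFrame(
            rows, columns=["gene", "group", "log2fc", "se", "wald", "p", "q"]
        )
        table["call"] = np.where(
            (table.q <= 1e-5) & (table.log2fc > 0), "up",
            np.where((table.q <= 1e-5) & (table.log2fc < 0), "down", "ns"),
        )
        return diffexpr.DEResult(table=table, fdr=1e-5)

    def test_direction_rules(self):
        res = self._result(
            [
                ["g1", "G", 1.2, 0.1, 12, 1e-7, 1e-6],
                ["g2", "G", 0.0, 0.1, 0, 1e-7, 1e-6],
                ["g3", "G", -3.0, 0.1, -30, 1e-6, 2e-5],
            ]
        )
        d = res.directions()
        assert d.loc["g1", "G"] == 1
        assert d.loc["g2", "G"] == 0  # zero effect never called
        assert d.loc["g3", "G"] == 0  # q above cutoff

    def test_threshold_sweep(self):
        raw = pd.DataFrame(
            [["g3", "G", -3.0, 0.1, -30.0, 2e-5]],
            columns=["gene", "group", "log2fc", "se", "wald", "p"],
        )
        strict = diffexpr.adjust_and_call(raw, fdr=1e-5)
        loose = diffexpr.adjust_and_call(raw, fdr=1e-4)
        assert strict.table.iloc[0]["call"] == "ns"
        assert loose.table.iloc[0]["call"] == "down"


class TestFullStage:
    def test_singleton_group_contrast_completes(self):
        """A single-replicate group (like GL-1) runs and yields finite stats."""
        cm, design, _ = simulate_null(n_genes=300, seed=2)
        de, sf, alpha = diffexpr.run_de(cm, design)
        gl1 = de.table[de.table.group == "GL1"]
        assert len(gl1) == cm.n_genes
        assert gl1["p"].notna().all()
        assert np.isfinite(gl1["log2fc"]).all()

    def test_na_p_excluded_from_bh(self):
        raw = pd.DataFrame(
            [
                ["g1", "G", 1.0, 0.1, 10.0, 0.02],
                ["g2", "G", 1.0, 0.1, 10.0, np.nan],
                ["g3", "G", 1.0, 0.1, 10.0, 0.04],
            ],
            columns=["gene", "group", "log2fc", "se", "wald", "p"],
        )
        res = diffexpr.adjust_and_call(raw, fdr=0.05)
        t = res.table.set_index("gene")
        assert np.isnan(t.loc["g2", "q"])
        assert t.loc["g2", "call"] == "ns"
        # BH over the two valid p-values only: q = (0.04, 0.04)
        assert t.loc["g1", "q"] == pytest.approx(0.04)
        assert t.loc["g3", "q"] == pytest.approx(0.04)
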