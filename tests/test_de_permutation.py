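from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import combine_pvalues

import permde as P
from permde.io_formats import ValidationError
from conftest import make_normalized


class TestGeneStatistics:
    def test_identical_groups_zero(self):
        m, groups = make_normalized([[3.0, 4.0, 5.0, 3.0, 4.0, 5.0]])
        df = P.gene_statistics(m, groups)
        assert df.t_stat[0] == 0.0 and df.log2fc[0] == 0.0

    def test_constant_shift_gives_unit_log2fc(self):
        m, groups = make_normalized([[2.0, 3.0, 4.0, 1.0, 2.0, 3.0]])
        assert P.gene_statistics(m, groups).log2fc[0] == pytest.approx(1.0)

    def test_pooled_t_matches_textbook_formula(self):
        # case (2,4,6), control (1,2,3): pooled var = (2*4 + 2*1)/4 = 2.5,
        # t = 2 / sqrt(2.5 * (1/3 + 1/3))
        m, groups = make_normalized([[2.0, 4.0, 6.0, 1.0, 2.0, 3.0]])
        df = P.gene_statistics(m, groups)
        assert df.log2fc[0] == pytest.approx(2.0)
        assert df.t_stat[0] == pytest.approx(2 / np.sqrt(2.5 * (2 / 3)), rel=1e-12)

    def test_welch_flavor_differs_for_unbalanced_groups(self):
        # at equal group sizes the two statistics coincide, so use 3 vs 7
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=(50, 10))
        x[:, :3] *= 4
        m, _ = make_normalized(x)
        groups = {
            s: ("case" if j < 3 else "control")
            for j, s in enumerate(m.sample_ids)
        }
        tp = P.gene_statistics(m, groups, t_flavor="pooled").t_stat
        tw = P.gene_statistics(m, groups, t_flavor="welch").t_stat
        assert not np.allclose(tp, tw)

    def test_small_group_rejected(self):
        m, _ = make_normalized(np.ones((3, 4)))
        groups = {"s0": "case", "s1": "control", "s2": "control", "s3": "control"}
        with pytest.raises(ValidationError, match="at least 2"):
            P.gene_statistics(m, groups)

    @given(st.integers(0, 2**31 - 1))
    def test_sign_symmetry_under_label_swap(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=(20, 8))
        m, groups = make_normalized(x)
        swapped = {
            s: ("case" if g == "control" else "control") for s, g in groups.items()
        }
        a = P.gene_statistics(m, groups)
        b = P.gene_statistics(m, swapped)
        np.testing.assert_allclose(b.t_stat, -a.t_stat, atol=1e-12)
        np.testing.assert_allclose(b.log2fc, -a.log2fc, atol=1e-12)


class TestPermutationNull:
    def test_pooled_size_contract_and_seed_determinism(self):
        rng = np.random.default_rng(1)
        m, groups = make_normalized(rng.normal(0, 1, size=(50, 10)))
        cfg = P.DeConfig(n_permutations=40, seed=9)
        null = P.permutation_null(m, groups, cfg)
        assert null.pooled_t.size == 50 * 40
        null2 = P.permutation_null(m, groups, cfg)
        assert np.array_equal(null.null_t, null2.null_t)
        assert np.array_equal(null.null_fc, null2.null_fc)

    def test_warns_when_permutations_exceed_distinct_assignments(self):
        rng = np.random.default_rng(2)
        m, groups = make_normalized(rng.normal(0, 1, size=(5, 6)))
        with pytest.warns(UserWarning, match="distinct assignments"):
            P.permutation_null(m, groups, P.DeConfig(n_permutations=30, seed=0))

    def test_exhaustive_3v3_matches_independent_enumeration(self):
        """All C(6,3)=20 assignments, cross-checked against a plain-python
        enumeration of the pooled-t and mean-difference formulas."""
        rng = np.random.default_rng(3)
        x = rng.normal(5, 2, size=(12, 6))
        m, groups = make_normalized(x)
        cfg = P.DeConfig(n_permutations=300, seed=0, variance_floor_quantile=0.0)
        null = P.permutation_null(m, groups, cfg, exhaustive=True)
        assert null.null_t.shape == (12, 20)

        ts, fcs = [], []
        for case in combinations(range(6), 3):
            ctrl = [j for j in range(6) if j not in case]
            for g in range(12):
                a, b = x[g, list(case)], x[g, ctrl]
                fc = a.mean() - b.mean()
                sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
                ts.append(fc / np.sqrt(sp2 * (2 / 3)))
                fcs.append(fc)
        np.testing.assert_allclose(
            np.sort(null.pooled_t), np.sort(ts), atol=1e-10
        )
        np.testing.assert_allclose(
            np.sort(null.pooled_fc), np.sort(fcs), atol=1e-10
        )


class TestEmpiricalPvalue:
    def test_plus_one_rule_when_stat_exceeds_all(self):
        null = np.linspace(-1, 1, 599)
        assert P.empirical_pvalue(5.0, null) == pytest.approx(1 / 600)

    def test_zero_stat_gives_one(self):
        assert P.empirical_pvalue(0.0, np.array([0.0, 0.5, -0.5])) == 1.0

    def test_direct_count(self):
        # 5 of 99 null values at or beyond |stat|
        null = np.concatenate([np.full(94, 0.1), np.full(5, 2.0)])
        assert P.empirical_pvalue(1.0, null) == pytest.approx(0.06)

    def test_non_finite_stat_rejected(self):
        with pytest.raises(ValidationError):
            P.empirical_pvalue(np.nan, np.array([1.0]))


class TestStouffer:
    def test_midpoint_fixed(self):
        assert P.stouffer_combine(0.5, 0.5) == pytest.approx(0.5)

    def test_two_moderate_pvalues_reinforce(self):
        # z = 1.6449 each -> combined z = 2.3263 -> p ~= 0.0100
        assert P.stouffer_combine(0.05, 0.05) == pytest.approx(0.0100, abs=5e-4)

    def test_opposite_evidence_cancels(self):
        assert P.stouffer_combine(0.05, 0.95) == pytest.approx(0.5, abs=1e-12)

    def test_boundary_p_of_one_is_clipped_not_rejected(self):
        assert 0 < P.stouffer_combine(1.0, 0.5) <= 1

    @given(
        st.floats(1e-6, 1 - 1e-6), st.floats(1e-6, 1 - 1e-6)
    )
    def test_matches_scipy_stouffer(self, p1, p2):
        expected = combine_pvalues([p1, p2], method="stouffer").pvalue
        assert P.stouffer_combine(p1, p2) == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            P.stouffer_combine(0.0, 0.5)


class TestDegCalling:
    @pytest.mark.parametrize(
        "p_comb,p_t,fc,expected",
        [
            (0.01, 0.03, 1.0, "up"),
            (0.01, 0.03, 0.50, "none"),
            (0.06, 0.03, 1.0, "none"),
            (0.01, 0.03, -1.0, "down"),
        ],
    )
    def test_three_criteria(self, p_comb, p_t, fc, expected):
        import pandas as pd

        records = pd.DataFrame(
            {
                "gene_id": ["g"],
                "log2fc": [fc],
                "t_stat": [fc * 3],
                "p_t_adj": [p_t],
                "p_fc_adj": [0.02],
                "p_combined": [p_comb],
            }
        )
        up, down = P.call_degs(records, P.DeConfig())
        assert records.direction[0] == expected
        assert records.is_deg[0] == (expected != "none")
        assert (len(up), len(down)) == (
            int(expected == "up"),
            int(expected == "down"),
        )

    def test_adaptive_cutoff_requires_resolution(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "gene_id": ["g"], "log2fc": [1.0], "t_stat": [3.0],
                "p_t_adj": [0.01], "p_fc_adj": [0.01], "p_combined": [0.01],
            }
        )
        with pytest.raises(ValidationError, match="adaptive"):
            P.call_degs(records, P.DeConfig(fc_cutoff="adaptive"))


class TestAdaptiveCutoff:
    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(4)
        sigma = 0.3
        null = rng.normal(0, sigma, size=100_000)
        cutoff = P.adaptive_fc_cutoff(null, (10, 90))
        assert cutoff == pytest.approx(1.2816 * sigma, rel=0.02)

    def test_degenerate_null(self):
        assert P.adaptive_fc_cutoff(np.zeros(100), (10, 90)) == 0.0

    def test_wider_percentile_pair_gives_larger_cutoff(self):
        rng = np.random.default_rng(5)
        null = rng.normal(0, 1, size=50_000)
        assert P.adaptive_fc_cutoff(null, (2.5, 97.5)) > P.adaptive_fc_cutoff(
            null, (10, 90)
        )


class TestRunDe:
    def test_records_complete_and_consistent(self, small_cohort):
        _, counts, fpkm, _ = small_cohort
        norm, _, _ = P.preprocess_pipeline(counts, fpkm)
        cfg = P.DeConfig(n_permutations=100, seed=1)
        records, null, cutoff = P.run_de(norm, counts.groups, cfg)
        assert cutoff == 0.58
        assert null.pooled_t.size == len(records) * 100
        assert ((records.p_t_adj > 0) & (records.p_t_adj <= 1)).all()
        assert ((records.p_combined > 0) & (records.p_combined <= 1)).all()
        deg = records[records.is_deg]
        assert (deg.direction != "none").all()
        assert (np.sign(deg.log2fc) == np.where(deg.direction == "up", 1, -1)).all()
        assert (records.loc[~records.is_deg, "direction"] == "none").all()

    def test_adaptive_cutoff_used(self, small_cohort):
        _, counts, fpkm, _ = small_cohort
        norm, _, _ = P.preprocess_pipeline(counts, fpkm)
        cfg = P.DeConfig(n_permutations=50, seed=1, fc_cutoff="adaptive",
                         percentile_pair=(10, 90))
        records, null, cutoff = P.run_de(norm, counts.groups, cfg)
        assert cutoff == pytest.approx(
            P.adaptive_fc_cutoff(null.pooled_fc, (10, 90))
        )

    def test_label_swap_swaps_up_and_down_lists(self, small_cohort):
        _, counts, fpkm, _ = small_cohort
        norm, _, _ = P.preprocess_pipeline(counts, fpkm)
        cfg = P.DeConfig(n_permutations=60, seed=2)
        swapped = {
            s: ("case" if g == "control" else "control")
            for s, g in counts.groups.items()
        }
        r1, _, _ = P.run_de(norm, counts.groups, cfg)
        r2, _, _ = P.run_de(norm, swapped, cfg)
        np.testing.assert_allclose(r2.log2fc, -r1.log2fc, atol=1e-12)
        np.testing.assert_allclose(r2.t_stat, -r1.t_stat, atol=1e-12)
        assert set(r2.loc[r2.direction == "up", "gene_id"]) == set(
            r1.loc[r1.direction == "down", "gene_id"]
        )
        assert set(r2.loc[r2.direction == "down", "gene_id"]) == set(
            r1.loc[r1.direction == "up", "gene_id"]
        )


def test_config_validation():
    with pytest.raises(ValidationError):
        P.DeConfig(n_permutations=0)
    with pytest.raises(ValidationError):
        P.DeConfig(alpha_t=1.5)
    with pytest.raises(ValidationError):
        P.DeConfig(fc_cutoff=-1.0)
    with pytest.raises(ValidationError):
        P.DeConfig(percentile_pair=(10, 80))
    with pytest.raises(ValidationError):
        P.DeConfig(t_flavor="bogus")
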