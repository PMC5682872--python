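import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressdeg.datasets import CADMIUM_RESPONSE_LOG2FC, WT_STRESS_DEG_COUNTS
from stressdeg.deg import (
    CANONICAL_CONTRASTS,
    ContrastResult,
    ContrastSpec,
    audic_claverie_p,
    audic_claverie_pmf,
    bh_fdr,
    compute_rpkm,
    run_contrast,
    select_strong_degs,
    strong_change_rule,
    summarize_contrast,
)
from stressdeg.io import AnalysisConfig, CountTable

from _oracles import ac_two_sided, ac_two_sided_grid


class TestRPKM:
    @pytest.mark.parametrize(
        "count,length,size,expected",
        [(10, 500, 1_000_000, 20.0), (0, 500, 1_000_000, 0.0),
         (1000, 2000, 10_000_000, 50.0)],
    )
    def test_definition(self, count, length, size, expected):
        assert compute_rpkm(count, length, size) == pytest.approx(expected)

    @pytest.mark.parametrize("length,size", [(0, 1_000_000), (500, 0), (-10, 1)])
    def test_domain_errors(self, length, size):
        with pytest.raises(ValueError):
            compute_rpkm(1, length, size)


class TestAudicClaverie:
    def test_identical_zero_counts_give_p_one(self):
        assert audic_claverie_p(0, 0, 1_000_000, 1_000_000) == 1.0

    def test_matches_term_summation_oracle_spot(self):
        p = audic_claverie_p(5, 20, 1_000_000, 1_000_000)
        assert abs(p - ac_two_sided(5, 20, 1.0)) < 1e-10

    @pytest.mark.parametrize("f", [0.5, 1.0, 2.0])
    def test_matches_oracle_on_small_grid(self, f):
        n1 = 1_000_000
        n2 = int(n1 * f)
        oracle = ac_two_sided_grid(60, 60, f)
        x, y = np.meshgrid(np.arange(61), np.arange(61), indexing="ij")
        ours = audic_claverie_p(x.ravel(), y.ravel(), n1, n2).reshape(61, 61)
        assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_pmf_label_symmetry_identity(self):
        # the exact pointwise identity N2 * p(y|x; N1,N2) = N1 * p(x|y; N2,N1)
        n1, n2 = 2_000_000, 1_000_000
        for x, y in [(3, 7), (0, 5), (40, 12)]:
            left = n2 * audic_claverie_pmf(y, x, n1, n2)
            right = n1 * audic_claverie_pmf(x, y, n2, n1)
            assert left == pytest.approx(right, rel=1e-12)

    def test_two_sided_p_is_conditioning_asymmetric(self):
        # conditioning on the first count is not label-symmetric, even
        # with equal library sizes: both tails are sums over the second
        # library's count distribution given the first
        p_37 = audic_claverie_p(3, 7, 1_000_000, 1_000_000)
        p_73 = audic_claverie_p(7, 3, 1_000_000, 1_000_000)
        assert p_37 == pytest.approx(0.34375, abs=1e-12)
        assert p_73 == pytest.approx(0.2265625, abs=1e-12)

    @pytest.mark.parametrize("x,y", [(-1, 0), (0.5, 1), (1, 2.7)])
    def test_non_integer_or_negative_counts_rejected(self, x, y):
        with pytest.raises(ValueError):
            audic_claverie_p(x, y, 1_000_000, 1_000_000)

    def test_null_calibration_poisson(self):
        # equal per-gene means in both libraries: small-p fraction
        # should track the nominal level
        rng = np.random.default_rng(123)
        means = np.exp(rng.normal(np.log(100), 0.5, 5000))
        x = rng.poisson(means)
        y = rng.poisson(means)
        p = audic_claverie_p(x, y, 1_000_000, 1_000_000)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.015)
        assert np.mean(p < 0.01) == pytest.approx(0.01, abs=0.008)


class TestBHFDR:
    def test_all_equal_p_unchanged(self):
        assert np.allclose(bh_fdr([0.2] * 5), 0.2)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_monotone_along_sorted_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(st.permutations(list(range(8))))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, perm):
        p = np.array([0.001, 0.2, 0.04, 0.8, 0.02, 0.5, 0.11, 0.31])
        perm = np.array(perm)
        assert np.allclose(bh_fdr(p[perm]), bh_fdr(p)[perm])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0


class TestRunContrast:
    def test_identical_columns_give_zero_degs(self, tiny_annotation, config):
        counts = pd.DataFrame(
            {"A": [100, 50, 3, 900, 10, 0], "B": [100, 50, 3, 900, 10, 0]},
            index=tiny_annotation.index,
        )
        table = CountTable(counts, pd.Series(1_000_000, index=["A", "B"]))
        spec = ContrastSpec("self", "A", "B", "stress")
        result = run_contrast(table, tiny_annotation, spec, config)
        assert result.frame["is_deg"].sum() == 0
        assert (result.frame["p_value"] > 0.3).all()

    def test_deg_threshold_default(self, config):
        assert config.fdr_threshold == 0.005

    def test_unknown_library_rejected(self, tiny_table, tiny_annotation, config):
        spec = ContrastSpec("bad", "nope", "WT_ctrl", "stress")
        with pytest.raises(KeyError):
            run_contrast(tiny_table, tiny_annotation, spec, config)

    def test_direction_follows_fold_change_sign(self, tiny_table, tiny_annotation, config):
        result = run_contrast(
            tiny_table, tiny_annotation, CANONICAL_CONTRASTS["WT_Cd_vs_WT_ctrl"], config
        )
        frame = result.frame
        assert frame.loc["g0", "direction"] == "up"      # 100 -> 800 reads
        assert frame.loc["g3", "direction"] == "down"    # 400 -> 50 reads
        assert frame.loc["g2", "direction"] == "none"    # 0 -> 0 reads
        degs = frame[frame["is_deg"]]
        assert ((degs["direction"] == "up") == (degs["log2fc"] > 0)).all()

    def test_planted_changes_recovered(self, planted_sim, planted_contrasts):
        wt, _ = planted_contrasts
        truth = planted_sim.truth
        joined = wt.frame.join(truth)
        # strongly planted, well-expressed genes must be recalled
        mean_ctrl = (
            truth["baseline_rpkm"]
            * truth["transcript_length_bp"] / 1e3
            * planted_sim.counts.library_sizes["WT_ctrl"] / 1e6
        )
        strong = joined[
            (np.abs(truth["true_log2fc_wt"]) >= 3) & (mean_ctrl >= 50)
        ]
        assert strong["is_deg"].mean() >= 0.95
        # and the direction of every recalled planted gene is correct
        hits = strong[strong["is_deg"]]
        assert (np.sign(hits["log2fc"]) == np.sign(hits["true_log2fc_wt"])).all()

    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(0.0, 5.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pseudocount_never_flips_sign(self, rpkm_a, rpkm_b, eps):
        base = np.log2((rpkm_a + 0.1) / (rpkm_b + 0.1))
        shifted = np.log2((rpkm_a + 0.1 + eps) / (rpkm_b + 0.1 + eps))
        assert np.sign(base) == np.sign(shifted) or base == shifted == 0


def _fake_result(log2fc, is_deg, counts=None):
    n = len(log2fc)
    frame = pd.DataFrame(
        {
            "count_num": counts if counts is not None else [10] * n,
            "count_den": counts if counts is not None else [10] * n,
            "rpkm_num": 1.0,
            "rpkm_den": 1.0,
            "log2fc": log2fc,
            "p_value": 0.5,
            "q_value": np.where(is_deg, 1e-4, 0.5),
            "direction": np.where(
                np.array(log2fc) > 0, "up", np.where(np.array(log2fc) < 0, "down", "none")
            ),
            "is_deg": is_deg,
        },
        index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
    )
    spec = ContrastSpec("fake_stress", "Cd", "ctrl", "stress")
    return ContrastResult(spec, frame, 0.005)


class TestSummarizeContrast:
    def test_antilog_mean_of_up_degs(self):
        result = _fake_result(np.log2([2, 2, 4, 8]), [True] * 4)
        summary = summarize_contrast(result)
        assert summary.n_up == 4 and summary.n_down == 0
        assert summary.mean_log2fc_up == pytest.approx(2.0)  # mean(2,2,4,8)=4
        assert summary.ratio_R is None

    def test_down_degs_use_inverse_fold_changes(self):
        result = _fake_result(-np.log2([2, 2, 4, 8]), [True] * 4)
        summary = summarize_contrast(result)
        assert summary.mean_log2fc_down == pytest.approx(-2.0)

    def test_reported_wt_contrast_ratio(self):
        n_up, n_down = WT_STRESS_DEG_COUNTS
        assert n_up / n_down == pytest.approx(2.308, abs=5e-4)

    def test_no_degs_yields_undefined_ratios(self):
        result = _fake_result([0.5, -0.2], [False, False])
        summary = summarize_contrast(result)
        assert summary.n_up == summary.n_down == 0
        assert summary.ratio_R is None and summary.ratio_R_means is None

    def test_unobserved_genes_excluded(self):
        result = _fake_result([3.0, 3.0], [True, True], counts=[0, 10])
        assert summarize_contrast(result).n_up == 1


class TestStrongDEGs:
    @pytest.mark.parametrize(
        "fc_wt,fc_pk,expected",
        [
            (2.5, 0.5, True),
            (2.5, 2.1, False),  # difference 0.4 <= 1
            (0.5, 0.2, False),  # neither exceeds the magnitude cutoff
            (-2.5, -0.5, True),
        ],
    )
    def test_rule(self, fc_wt, fc_pk, expected):
        assert strong_change_rule(fc_wt, fc_pk) is expected

    def test_reported_metal_gene_pairs_all_selected(self):
        for gene, (fc_wt, fc_pk) in CADMIUM_RESPONSE_LOG2FC.items():
            assert strong_change_rule(fc_wt, fc_pk), gene

    def test_selection_and_ordering(self, config):
        wt = _fake_result([4.0, 2.5, 2.5, 0.1], [True, True, True, False])
        pk = _fake_result([1.0, 2.1, 0.3, 0.0], [True, True, False, False])
        out = select_strong_degs(wt, pk, config)
        assert list(out.index) == ["g0", "g2"]  # g1 fails the difference cut
        assert (out["log2fc_WT"].diff().dropna() <= 0).all()

    def test_mismatched_universe_rejected(self, config):
        wt = _fake_result([1.0], [True])
        pk = _fake_result([1.0, 2.0], [True, True])
        with pytest.raises(ValueError):
            select_strong_degs(wt, pk, config)
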