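"""Agreement metrics: hand-computed oracles, Monte-Carlo nulls,
independent library cross-checks, and invariances."""

import numpy as np
import pytest

from nirsdot.reliability import (
    ReliabilityReport,
    classify_by_date,
    core_overlap_rate,
    detection_rate,
    dice,
    dice_pairs,
    evaluate_reliability,
    fleiss_kappa,
    gwet_ac1,
    icc_1_1,
    image_correlation,
)

# 5 voxels rated by 3 dates over {L<R, none, L>R}; chance-corrected
# agreement computed by hand from P-bar and P-bar_e
TOY_TABLE = np.array(
    [[1, 1, 1], [1, 1, 0], [0, 0, -1], [-1, -1, -1], [0, 1, -1]]
)
TOY_KAPPA = 0.2905405405405405  # (0.5333... - 0.342222...) / (1 - 0.342222...)
TOY_AC1 = 0.3046357615894040

# 4 ROIs x 3 dates; one-way ANOVA by hand: BMS = 22.888..., WMS = 0.666...
TOY_ICC_TABLE = np.array([[9.0, 8, 7], [7, 6, 6], [4, 5, 3], [2, 2, 1]])
TOY_ICC = 0.9174311926605504


class TestClassifyByDate:
    def test_stacks_and_checks_alignment(self):
        a, b = np.array([1, 0, -1]), np.array([0, 0, 1])
        table = classify_by_date([a, b])
        assert table.shape == (3, 2)
        with pytest.raises(ValueError):
            classify_by_date([a, np.zeros(5)])

    def test_unanimous_rows_for_identical_maps(self):
        a = np.array([1, -1, 0, 0])
        table = classify_by_date([a, a, a])
        assert (table == table[:, :1]).all()


class TestFleissKappa:
    def test_perfect_agreement_across_mixed_categories(self):
        table = np.array([[1, 1], [0, 0], [-1, -1], [1, 1]])
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_computed_toy_table(self):
        assert fleiss_kappa(TOY_TABLE) == pytest.approx(TOY_KAPPA, rel=1e-12)

    def test_matches_statsmodels_reference(self):
        import statsmodels.stats.inter_rater as ir

        rng = np.random.default_rng(0)
        table = rng.choice([-1, 0, 1], size=(60, 4))
        agg, _ = ir.aggregate_raters(table)
        assert fleiss_kappa(table) == pytest.approx(ir.fleiss_kappa(agg), rel=1e-10)

    def test_monte_carlo_null_near_zero(self):
        rng = np.random.default_rng(1)
        table = rng.choice([-1, 0, 1], size=(10000, 3))
        assert abs(fleiss_kappa(table)) < 0.02

    def test_single_category_undefined(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.ones((6, 3), dtype=int))


class TestGwetAC1:
    def test_perfect_agreement(self):
        table = np.array([[1, 1], [0, 0], [-1, -1]])
        assert gwet_ac1(table) == pytest.approx(1.0)

    def test_hand_computed_toy_table(self):
        assert gwet_ac1(TOY_TABLE) == pytest.approx(TOY_AC1, rel=1e-12)

    def test_robust_to_category_imbalance(self):
        """Near-unanimous one-category table: AC1 stays high while kappa
        collapses (the prevalence paradox)."""
        table = np.zeros((200, 3), dtype=int)
        table[:5, 0] = 1  # a few disagreements
        assert gwet_ac1(table) > fleiss_kappa(table)
        assert gwet_ac1(table) > 0.9

    def test_monte_carlo_null_near_zero(self):
        rng = np.random.default_rng(2)
        table = rng.choice([-1, 0, 1], size=(10000, 3))
        assert abs(gwet_ac1(table)) < 0.02


class TestDice:
    def test_identical_masks(self):
        m = np.array([1, 1, 0, 0], dtype=bool)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        assert dice(np.array([1, 0], bool), np.array([0, 1], bool)) == 0.0

    def test_formula_arithmetic(self):
        a = np.zeros(300, bool)
        b = np.zeros(300, bool)
        a[:100] = True
        b[75:125] = True  # |A|=100, |B|=50, overlap 25
        assert dice(a, b) == pytest.approx(1.0 / 3.0)

    def test_pairs_mean_and_empty_skip(self):
        t1 = np.array([1, 1, 0, -1])
        t2 = np.array([1, 0, 0, 0])
        t3 = np.zeros(4, dtype=int)  # empty for both labels
        table = classify_by_date([t1, t2, t3])
        # label +1: (t1,t2) = 2/3; (t1,t3) = 0; (t2,t3) = 0
        # label -1: (t1,t2) = 0; (t1,t3) = 0; (t2,t3) skipped (0/0)
        expected = (2 / 3) / 5
        assert dice_pairs(table) == pytest.approx(expected)


class TestDetectionRate:
    @pytest.mark.parametrize("fill,expected", [(0, 0.0), (1, 1.0)])
    def test_extremes(self, fill, expected):
        table = np.full((40, 3), fill)
        assert detection_rate(table) == expected

    def test_half(self):
        table = np.zeros((40, 2), dtype=int)
        table[:20] = 1
        assert detection_rate(table) == 0.5


class TestICC:
    def test_exact_copies_give_one(self):
        col = np.array([3.0, 1.0, 5.0, 2.0])
        table = np.column_stack([col, col, col])
        assert icc_1_1(table) == pytest.approx(1.0)

    def test_hand_anova_oracle(self):
        assert icc_1_1(TOY_ICC_TABLE) == pytest.approx(TOY_ICC, rel=1e-12)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 4)) + rng.standard_normal((8, 1)) * 2
        n, k = X.shape
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": X.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="ratings")
        ref_val = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert icc_1_1(X) == pytest.approx(ref_val, rel=1e-8)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5000, 3))
        assert abs(icc_1_1(X)) < 0.03

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            icc_1_1(np.ones((1, 3)))


class TestInvariances:
    def test_metrics_invariant_to_category_relabeling(self):
        rng = np.random.default_rng(5)
        table = rng.choice([-1, 0, 1], size=(500, 3))
        relabel = {-1: 1, 0: -1, 1: 0}
        swapped = np.vectorize(relabel.get)(table)
        assert fleiss_kappa(swapped) == pytest.approx(fleiss_kappa(table), rel=1e-12)
        assert gwet_ac1(swapped) == pytest.approx(gwet_ac1(table), rel=1e-12)

    def test_metrics_invariant_to_voxel_permutation(self):
        rng = np.random.default_rng(6)
        table = rng.choice([-1, 0, 1], size=(500, 3))
        perm = rng.permutation(500)
        assert fleiss_kappa(table[perm]) == pytest.approx(fleiss_kappa(table), rel=1e-12)
        assert gwet_ac1(table[perm]) == pytest.approx(gwet_ac1(table), rel=1e-12)

    def test_agreement_increases_with_snr(self):
        """Shared spatial truth, per-date independent noise: agreement
        metrics rise on average as noise shrinks (20 replicates)."""
        rng = np.random.default_rng(7)
        truth = np.zeros(400)
        truth[:40] = 3.0
        truth[40:80] = -3.0

        def run(noise_sd):
            ks, acs = [], []
            for _ in range(20):
                maps = []
                for _d in range(3):
                    t = truth + noise_sd * rng.standard_normal(400)
                    maps.append(np.sign(t) * (np.abs(t) > 2.0))
                table = classify_by_date([m.astype(int) for m in maps])
                ks.append(fleiss_kappa(table))
                acs.append(gwet_ac1(table))
            return np.mean(ks), np.mean(acs)

        k_hi, ac_hi = run(noise_sd=0.5)
        k_lo, ac_lo = run(noise_sd=2.0)
        assert k_hi > k_lo
        assert ac_hi > ac_lo


class TestReportAssembly:
    def test_core_overlap_of_mirrored_maps(self):
        core_hbo = np.array([1, 1, -1, -1, 0, 0])
        core_hbr = -core_hbo
        assert core_overlap_rate(core_hbo, core_hbr) == 1.0

    def test_full_report_roundtrip(self, tmp_path):
        maps = [np.array([1, 0, -1, 0]), np.array([1, 0, -1, 1]), np.array([1, 0, 0, 0])]
        rep = evaluate_reliability(
            maps, roi_t_table=TOY_ICC_TABLE,
            t_hbo=np.array([1.0, 2, 3, 4]), t_hbr=np.array([-1.0, -2, -3, -4]),
        )
        assert isinstance(rep, ReliabilityReport)
        assert rep.hb_image_correlation == pytest.approx(-1.0)
        rep.to_json(tmp_path / "rep.json")
        import json

        loaded = json.loads((tmp_path / "rep.json").read_text())
        assert loaded["icc11"] == pytest.approx(TOY_ICC)


class TestPropertyBased:
    def test_dice_bounds_and_symmetry(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=50, derandomize=True)
        @given(st.lists(st.booleans(), min_size=1, max_size=60),
               st.lists(st.booleans(), min_size=1, max_size=60))
        def check(a, b):
            n = min(len(a), len(b))
            x, y = np.array(a[:n]), np.array(b[:n])
            d = dice(x, y)
            if np.isnan(d):
                assert not x.any() and not y.any()
            else:
                assert 0.0 <= d <= 1.0
                assert d == dice(y, x)
                if d == 1.0:
                    np.testing.assert_array_equal(x, y)

        check()

    def test_kappa_and_ac1_bounded_above_by_one(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=50, derandomize=True)
        @given(st.lists(st.tuples(st.sampled_from([-1, 0, 1]),
                                  st.sampled_from([-1, 0, 1]),
                                  st.sampled_from([-1, 0, 1])),
                        min_size=3, max_size=40))
        def check(rows):
            table = np.array(rows)
            try:
                k = fleiss_kappa(table)
                a = gwet_ac1(table)
            except ValueError:
                return  # degenerate single-category table
            assert k <= 1.0 + 1e-12
            assert a <= 1.0 + 1e-12

        check()
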