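import numpy as np
import pytest

from tilscope import (BinaryMask, HPFSpec, RatingsMatrix,
                      agreement_report, bland_altman, cohens_kappa,
                      count_in_fields, fleiss_kappa, grade, icc_absolute,
                      stromal_mask)


def anova_icc_oracle(x):
    """Independent spreadsheet-style two-way ANOVA -> ICC(A,1)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ssr = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ssc = n * ((x.mean(axis=0) - grand) ** 2).sum()
    sse = ((x - grand) ** 2).sum() - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestStromalMask:
    def test_empty_parenchyma_gives_tissue(self, rng):
        t = BinaryMask((rng.uniform(size=(10, 10)) < 0.5).astype(np.uint8))
        p = BinaryMask(np.zeros((10, 10), np.uint8))
        assert np.array_equal(stromal_mask(t, p).grid, t.grid)

    def test_full_parenchyma_gives_empty(self, rng):
        t = BinaryMask((rng.uniform(size=(10, 10)) < 0.5).astype(np.uint8))
        assert stromal_mask(t, t).area() == 0

    def test_random_masks_match_set_difference(self, rng):
        t = BinaryMask((rng.uniform(size=(12, 12)) < 0.6).astype(np.uint8))
        p = BinaryMask((t.grid & (rng.uniform(size=(12, 12)) < 0.5)).astype(np.uint8))
        out = stromal_mask(t, p)
        oracle = np.array([[1 if t.grid[r, c] and not p.grid[r, c] else 0
                            for c in range(12)] for r in range(12)])
        assert np.array_equal(out.grid, oracle)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stromal_mask(BinaryMask(np.zeros((2, 2), np.uint8)),
                         BinaryMask(np.zeros((3, 3), np.uint8)))


class TestCountInFields:
    HPF = HPFSpec(field_area_mm2=0.0025, mpp=1.0)  # 50 um side at mpp 1

    def test_no_boxes_all_zero(self):
        stroma = BinaryMask(np.ones((200, 200), np.uint8))
        assert count_in_fields([], stroma, self.HPF, 5, seed=0) == [0] * 5

    def test_tight_cluster_counted_whole_when_window_covers_it(self):
        """Ten boxes packed in a 6 um cluster: any window whose center is
        within reach counts all ten, and no window counts more."""
        grid = np.zeros((200, 200), np.uint8)
        grid[70:130, 70:130] = 1
        stroma = BinaryMask(grid)
        boxes = [(97 + 0.5 * i, 97 + 0.5 * i, 99 + 0.5 * i, 99 + 0.5 * i)
                 for i in range(10)]
        counts = count_in_fields(boxes, stroma, self.HPF, 25, seed=0)
        assert all(0 <= c <= 10 for c in counts)
        assert 10 in counts  # at least one seeded window covers the cluster

    def test_poisson_mean_recovery(self, rng):
        """Mean field count over many seeded placements tracks the realized
        frame density times the field area."""
        frame = 300
        stroma = BinaryMask(np.ones((frame, frame), np.uint8))
        n = int(rng.poisson(2000.0 * 0.09))  # 0.3 mm x 0.3 mm frame
        xy = rng.uniform(0, frame, (n, 2))
        boxes = [(x - 1, y - 1, x + 1, y + 1) for x, y in xy]
        counts = []
        for seed in range(100):
            counts.extend(count_in_fields(boxes, stroma, self.HPF, 5,
                                          seed=seed))
        # windows centered near the frame edge are truncated; for a uniform
        # center each axis loses (side/2)^2 / frame of coverage in expectation
        side = self.HPF.side_px
        e_len = side - (side / 2) ** 2 / frame
        expect = (n / frame ** 2) * e_len ** 2
        se = np.sqrt(expect / len(counts))
        assert abs(np.mean(counts) - expect) <= 3 * se

    def test_stroma_too_small_names_areas(self):
        stroma = BinaryMask(np.ones((5, 5), np.uint8))
        with pytest.raises(ValueError, match="required .* available"):
            count_in_fields([], stroma, HPFSpec(mpp=1.0), 5, seed=0)

    def test_hotspot_mode_returns_densest_fields(self):
        stroma = BinaryMask(np.ones((100, 100), np.uint8))
        hpf = HPFSpec(field_area_mm2=0.0004, mpp=1.0)  # 20 um side
        boxes = [(10 + dx, 10 + dy, 12 + dx, 12 + dy)
                 for dx in range(0, 10, 2) for dy in range(0, 10, 2)]
        counts = count_in_fields(boxes, stroma, hpf, 2, seed=0, hotspot=True)
        assert counts[0] >= counts[1] >= 0
        assert counts[0] > 0


class TestGrading:
    @pytest.mark.parametrize("count,expected", [
        (0, "low"), (99, "low"), (100, "moderate"), (200, "moderate"),
        (300, "moderate"), (301, "high"), (1000, "high"),
    ])
    def test_boundaries(self, count, expected):
        assert grade(count) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            grade(-1)


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        x = np.column_stack([np.arange(10.0)] * 3)
        r = icc_absolute(x)
        assert r.estimate == pytest.approx(1.0)
        assert r.ci_high == pytest.approx(1.0)
        assert r.strength == "excellent"

    def test_independent_noise_near_zero(self, rng):
        x = rng.normal(0, 1, (300, 2))
        r = icc_absolute(x)
        assert abs(r.estimate) < 0.15

    def test_fixed_6x2_matrix_matches_anova_oracle(self):
        x = np.array([[9, 2], [1, 10], [8, 9], [2, 16], [7, 13], [9, 20]],
                     dtype=float)
        r = icc_absolute(x)
        assert r.estimate == pytest.approx(anova_icc_oracle(x), abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        subj = rng.normal(50, 10, 25)
        x = np.column_stack([subj + rng.normal(0, 5, 25) for _ in range(3)])
        df = pd.DataFrame({"s": np.repeat(np.arange(25), 3),
                           "r": np.tile(np.arange(3), 25),
                           "y": x.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        ref_a1 = ref[ref["Type"] == "ICC(A,1)"] if "ICC(A,1)" in set(ref["Type"]) \
            else ref[ref["Type"] == "ICC2"]
        mine = icc_absolute(x)
        assert mine.estimate == pytest.approx(float(ref_a1["ICC"].iloc[0]),
                                              abs=1e-9)

    def test_invariant_under_shift_and_scale(self, rng):
        subj = rng.normal(0, 2, 40)
        x = np.column_stack([subj + rng.normal(0, 1, 40) for _ in range(2)])
        base = icc_absolute(x).estimate
        assert icc_absolute(x + 100).estimate == pytest.approx(base)
        assert icc_absolute(x * 7.5).estimate == pytest.approx(base)

    def test_parameter_recovery_n200(self):
        """Mean estimate over replicate n=200 panels recovers the variance
        ratio within 0.05."""
        rng = np.random.default_rng(42)
        sigma_s, sigma_e = 20.0, 10.0
        truth = sigma_s ** 2 / (sigma_s ** 2 + sigma_e ** 2)
        estimates = []
        for _ in range(5):
            subj = rng.normal(100, sigma_s, 200)
            x = np.column_stack([subj + rng.normal(0, sigma_e, 200)
                                 for _ in range(2)])
            estimates.append(icc_absolute(x).estimate)
        assert abs(np.mean(estimates) - truth) <= 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_absolute(np.full((5, 2), 3.0))


class TestKappa:
    def test_identical_vectors(self):
        a = np.array(["low", "high", "moderate", "low"])
        r = cohens_kappa(a, a, n_boot=100)
        assert r.estimate == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)

    def test_complete_disagreement_binary(self):
        a = np.array([0, 1] * 10)
        b = np.array([1, 0] * 10)
        assert cohens_kappa(a, b, n_boot=50).estimate == pytest.approx(-1.0)

    def test_contingency_hand_value(self):
        a = np.array(["a"] * 25 + ["b"] * 25)
        b = np.array(["a"] * 20 + ["b"] * 5 + ["a"] * 10 + ["b"] * 15)
        assert cohens_kappa(a, b, n_boot=50).estimate == pytest.approx(0.4)

    def test_degenerate_constant_raters(self):
        a = np.array(["x"] * 10)
        r = cohens_kappa(a, a, n_boot=50)
        assert r.estimate == 1.0 and r.degenerate

    def test_invariant_under_relabeling(self, rng):
        a = rng.integers(0, 3, 80)
        b = rng.integers(0, 3, 80)
        relabel = {0: "p", 1: "q", 2: "r"}
        ra = np.array([relabel[v] for v in a])
        rb = np.array([relabel[v] for v in b])
        assert cohens_kappa(a, b, n_boot=50).estimate == \
            pytest.approx(cohens_kappa(ra, rb, n_boot=50).estimate)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        a = rng.integers(0, 3, 120)
        b = np.where(rng.uniform(size=120) < 0.6, a, rng.integers(0, 3, 120))
        tab = np.zeros((3, 3))
        for i, j in zip(a, b):
            tab[i, j] += 1
        assert cohens_kappa(a, b, n_boot=50).estimate == \
            pytest.approx(float(sm.cohens_kappa(tab).kappa))


class TestFleiss:
    def test_unanimous_raters(self):
        labels = np.array([["a", "a", "a"], ["b", "b", "b"]])
        r = fleiss_kappa(labels, n_boot=50)
        assert r.estimate == 1.0

    def test_uniform_random_near_zero(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, (500, 3))
        assert abs(fleiss_kappa(labels, n_boot=50).estimate) < 0.1

    def test_fixed_4x3_matches_direct_formula(self):
        labels = np.array([[0, 0, 1], [1, 1, 1], [0, 2, 2], [2, 2, 2]])
        n, k = labels.shape
        counts = np.array([[np.sum(row == c) for c in range(3)]
                           for row in labels])
        p_j = counts.sum(axis=0) / (n * k)
        p_i = ((counts ** 2).sum(axis=1) - k) / (k * (k - 1))
        expect = (p_i.mean() - (p_j ** 2).sum()) / (1 - (p_j ** 2).sum())
        assert fleiss_kappa(labels, n_boot=50).estimate == \
            pytest.approx(expect, abs=1e-12)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        labels = rng.integers(0, 3, (60, 4))
        agg, _ = sm.aggregate_raters(labels)
        assert fleiss_kappa(labels, n_boot=50).estimate == \
            pytest.approx(float(sm.fleiss_kappa(agg)))


class TestBlandAltman:
    def test_equal_vectors(self):
        r = bland_altman([1, 2, 3], [1, 2, 3])
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        r = bland_altman(a, a + 5)
        assert r.bias == pytest.approx(-5.0)
        assert r.loa_low == pytest.approx(-5.0)
        assert r.loa_high == pytest.approx(-5.0)

    def test_hand_computed_limits(self):
        r = bland_altman([1, -1, 3, -3], [0, 0, 0, 0])
        sd = np.std([1, -1, 3, -3], ddof=1)
        assert r.bias == 0.0
        assert r.loa_high == pytest.approx(1.96 * sd)
        assert r.loa_high == pytest.approx(5.06, abs=0.01)

    def test_swap_flips_bias_keeps_width(self, rng):
        a = rng.normal(10, 3, 20)
        b = rng.normal(11, 3, 20)
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r1.bias == pytest.approx(-r2.bias)
        assert (r1.loa_high - r1.loa_low) == \
            pytest.approx(r2.loa_high - r2.loa_low)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1], [2])


class TestAgreementReport:
    def test_identical_raters_all_perfect(self):
        counts = np.column_stack([[50, 150, 350, 90, 220]] * 3).astype(float)
        rep = agreement_report(RatingsMatrix(counts,
                                             ["expert1", "expert2", "pipeline"]))
        assert rep.icc.estimate == pytest.approx(1.0)
        assert rep.icc.strength == "excellent"
        assert rep.fleiss.estimate == 1.0
        for k in rep.kappa_pairwise.values():
            assert k.estimate == 1.0 and k.strength == "almost perfect"
        for ba in rep.bland_altman.values():
            assert ba.bias == 0.0

    def test_strength_bands(self):
        from tilscope.tils_quant import icc_strength, kappa_strength
        assert icc_strength(0.75) == "excellent"
        assert icc_strength(0.74) == "good"
        assert icc_strength(0.40) == "fair"
        assert icc_strength(0.39) == "poor"
        assert kappa_strength(0.45) == "moderate"
        assert kappa_strength(0.85) == "almost perfect"
        assert kappa_strength(0.10) == "slight"
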