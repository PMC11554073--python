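"""Synthetic cohort generator: marginals, tumors, resection, planted signal."""

import numpy as np
import pandas as pd
import pytest

from kpsfusion import schema
from kpsfusion.synthetic import (CohortConfig, DEFAULT_BINARY_MARGINALS,
                                 OutcomeModel, TumorGeometry, apply_resection,
                                 simulate_cohort, simulate_tumor_volume)


class TestSimulateCohort:
    def test_cohort_shape_and_columns(self):
        df, studies = simulate_cohort(150, seed=0, make_volumes=False)
        assert len(df) == 150
        assert len(studies) == 0
        for col in schema.CLINICAL_PARAMS:
            assert col in df.columns
        assert len(schema.CLINICAL_PARAMS) == 28
        kps = df[schema.ENDPOINT]
        assert set(kps.unique()) <= set(schema.KPS_GRID)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(5, seed=0)

    def test_unknown_coefficient_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate_cohort(20, OutcomeModel(clinical_coefs={"shoe_size": 1.0}),
                            make_volumes=False, seed=0)

    def test_null_model_prevalence_half(self):
        df, _ = simulate_cohort(600, OutcomeModel(), make_volumes=False, seed=1)
        prev = (df[schema.ENDPOINT] < 70).mean()
        assert abs(prev - 0.5) < 3 * np.sqrt(0.25 / 600)  # binomial 3-sigma

    def test_age_signal_recovered_by_logistic_refit(self):
        from sklearn.linear_model import LogisticRegression
        model = OutcomeModel(clinical_coefs={"age": 2.0})
        df, _ = simulate_cohort(500, model, make_volumes=False, seed=2)
        y = (df[schema.ENDPOINT] < 70).astype(int)
        x = ((df["age"] - df["age"].mean()) / df["age"].std()).to_numpy()[:, None]
        coef = LogisticRegression().fit(x, y).coef_[0, 0]
        assert coef > 0
        old = df["age"] > df["age"].median()
        odds = ((y[old].mean() / (1 - y[old].mean()))
                / (y[~old].mean() / (1 - y[~old].mean())))
        assert odds > 1

    def test_determinism_byte_identical(self):
        df1, st1 = simulate_cohort(15, seed=9)
        df2, st2 = simulate_cohort(15, seed=9)
        pd.testing.assert_frame_equal(df1, df2)
        for (a, b), (c, d) in zip(st1, st2):
            np.testing.assert_array_equal(a.labels, c.labels)
            np.testing.assert_array_equal(b.labels, d.labels)

    def test_marginal_calibration_n1000(self):
        df, _ = simulate_cohort(1000, make_volumes=False, seed=3)
        for name, p in DEFAULT_BINARY_MARGINALS.items():
            if name == "surgery_biopsy":
                continue  # biopsy also forces the lowest resection category
            se = np.sqrt(p * (1 - p) / 1000)
            assert abs(df[name].mean() - p) < 3 * se, name
        assert abs(df["surgery_biopsy"].mean() - 27 / 150) < 3 * np.sqrt(
            0.18 * 0.82 / 1000)

    def test_planted_signal_signs_recovered(self):
        from sklearn.linear_model import LogisticRegression
        model = OutcomeModel(clinical_coefs={"age": 1.0, "preop_kps": -1.0},
                             morphology_coefs={"post_core_volume": 1.0})
        df, _ = simulate_cohort(500, model, make_volumes=False, seed=4)
        y = (df[schema.ENDPOINT] < 70).astype(int)
        X = df[["age", "preop_kps", "post_core_volume"]].to_numpy(float)
        X = (X - X.mean(0)) / X.std(0)
        coefs = LogisticRegression().fit(X, y).coef_[0]
        assert coefs[0] > 0 and coefs[1] < 0 and coefs[2] > 0

    def test_operation_dates_span_window(self):
        cfg = CohortConfig()
        df, _ = simulate_cohort(200, make_volumes=False, seed=5, config=cfg)
        assert df["operation_date"].min() >= cfg.date_start
        assert df["operation_date"].max() <= cfg.date_end

    def test_missingness_flag_injects_nans(self):
        cfg = CohortConfig(missingness_rate=0.1)
        df, _ = simulate_cohort(100, make_volumes=False, seed=6, config=cfg)
        n_missing = df[list(schema.CLINICAL_PARAMS)].isna().sum().sum()
        assert n_missing > 0


class TestSimulateTumorVolume:
    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            TumorGeometry(center=(8, 8, 8), core_radii=(0, 0, 0),
                          edema_margin=1, brain_center=(8, 8, 8),
                          brain_radii=(7, 7, 7))

    def test_geometry_outside_grid_rejected(self, simple_geometry):
        with pytest.raises(ValueError, match="fit"):
            simulate_tumor_volume(simple_geometry, (8, 8, 8), seed=0)

    def test_core_count_matches_bruteforce_ellipsoid(self):
        geom = TumorGeometry(center=(10, 20, 20), core_radii=(3, 5, 5),
                             edema_margin=2, brain_center=(10, 20, 20),
                             brain_radii=(9, 18, 18))
        v = simulate_tumor_volume(geom, (21, 41, 41), seed=0)
        expected = 0
        for s in range(21):
            for r in range(41):
                for c in range(41):
                    q = ((s - 10) / 3) ** 2 + ((r - 20) / 5) ** 2 + ((c - 20) / 5) ** 2
                    expected += q <= 1.0
        assert (v.labels == 3).sum() == expected

    def test_label_histogram(self, simple_geometry):
        v = simulate_tumor_volume(simple_geometry, (32, 48, 48), seed=7)
        present = set(np.unique(v.labels))
        assert present == {0, 1, 2, 3}
        assert (v.labels == 1).sum() >= (v.labels == 2).sum()


class TestApplyResection:
    @pytest.fixture()
    def pre(self, simple_geometry):
        return simulate_tumor_volume(simple_geometry, (32, 48, 48), seed=8)

    def test_complete_resection(self, pre):
        post = apply_resection(pre, "100%", seed=0)
        assert (post.labels == 3).sum() == 0
        assert post.timepoint == "post"

    @pytest.mark.parametrize("extent,lo,hi", [
        ("90-99%", 0.01, 0.10),
        ("50-89%", 0.11, 0.50),
        ("1-49%", 0.51, 0.99),
    ])
    def test_remaining_fraction_in_band(self, pre, extent, lo, hi):
        n_pre = (pre.labels == 3).sum()
        post = apply_resection(pre, extent, seed=5)
        frac = (post.labels == 3).sum() / n_pre
        assert lo - 0.01 <= frac <= hi + 0.01

    def test_unknown_category_rejected(self, pre):
        with pytest.raises(ValueError, match="extent"):
            apply_resection(pre, "most of it", seed=0)

    def test_core_free_volume_rejected(self):
        from kpsfusion.volumes import LabelVolume
        v = LabelVolume(labels=np.ones((4, 4, 4), dtype=np.int16),
                        spacing=(3, 1, 1))
        with pytest.raises(ValueError, match="core"):
            apply_resection(v, "100%", seed=0)

    def test_resection_only_touches_core(self, pre):
        post = apply_resection(pre, "50-89%", seed=1)
        changed = pre.labels != post.labels
        assert (pre.labels[changed] == 3).all()
        assert (post.labels[changed] == 1).all()
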