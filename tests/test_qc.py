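import numpy as np
import pandas as pd
import pytest

from morphoscreen.qc import (
    ConsistencyError,
    MissingControlsError,
    QCReport,
    aggregate_to_well,
    anova_filter,
    drop_degenerate,
    drop_redundant,
    normalize_to_controls,
)


def _image_table(values, genotypes=None, plates=None):
    """1-feature image-level table; one row per (well, field) value list."""
    rows = []
    for w, vals in enumerate(values):
        for f, v in enumerate(vals, start=1):
            rows.append(
                {
                    "plate_id": plates[w] if plates else "P01",
                    "well": f"A{w + 1:02d}",
                    "subclone_id": "SC1",
                    "genotype": genotypes[w] if genotypes else "KO",
                    "treatment": "VEHICLE",
                    "concentration_nM": 0.0,
                    "field": f,
                    "F001": v,
                }
            )
    return pd.DataFrame(rows)


class TestAggregate:
    def test_median_of_four_fields(self):
        well = aggregate_to_well(_image_table([[1.0, 2.0, 3.0, 100.0]]))
        assert well.loc[0, "F001"] == 2.5
        assert "field" not in well.columns

    def test_single_field_unchanged(self):
        well = aggregate_to_well(_image_table([[7.25]]))
        assert well.loc[0, "F001"] == 7.25

    def test_missing_field_value_ignored(self):
        well = aggregate_to_well(_image_table([[1.0, np.nan, 3.0, 5.0]]))
        assert well.loc[0, "F001"] == 3.0  # median of the remaining 3

    def test_inconsistent_metadata_rejected(self):
        t = _image_table([[1.0, 2.0]])
        t.loc[1, "genotype"] = "WT"
        with pytest.raises(ConsistencyError):
            aggregate_to_well(t)


class TestNormalize:
    def test_ko_vehicle_anchor_defines_zero_and_unit_scale(self, toy_well_table):
        norm, degenerate = normalize_to_controls(toy_well_table)
        assert degenerate == []
        feats = [c for c in norm.columns if c.startswith("F")]
        ko = norm[(norm["genotype"] == "KO") & (norm["treatment"] == "VEHICLE")]
        for plate, sub in ko.groupby("plate_id"):
            med = sub[feats].median()
            mad = (sub[feats] - med).abs().median() * 1.4826
            assert np.allclose(med, 0.0, atol=1e-12)
            assert np.allclose(mad, 1.0, atol=1e-12)

    def test_constant_feature_flagged_not_divided(self, toy_well_table):
        t = toy_well_table.copy()
        t["F000"] = 3.0
        norm, degenerate = normalize_to_controls(t)
        assert "F000" in degenerate
        assert np.allclose(norm["F000"], 0.0)  # centred on its median only

    def test_additive_plate_shift_removed(self, toy_well_table):
        shifted = toy_well_table.copy()
        feats = [c for c in shifted.columns if c.startswith("F")]
        shifted.loc[shifted["plate_id"] == "P02", feats] += 5.0
        a, _ = normalize_to_controls(toy_well_table)
        b, _ = normalize_to_controls(shifted)
        pd.testing.assert_frame_equal(a, b)

    def test_plate_without_anchor_wells_named(self, toy_well_table):
        t = toy_well_table.copy()
        t.loc[t["plate_id"] == "P02", "genotype"] = "WT"
        with pytest.raises(MissingControlsError, match="P02"):
            normalize_to_controls(t)


class TestDropDegenerate:
    def _table(self, X, names):
        meta = pd.DataFrame(
            {
                "plate_id": "P01", "well": [f"A{i:02d}" for i in range(len(X))],
                "subclone_id": "SC1", "genotype": "KO", "treatment": "VEHICLE",
                "concentration_nM": 0.0,
            }
        )
        return pd.concat([meta, pd.DataFrame(X, columns=names)], axis=1)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.standard_normal(8), np.full(8, 2.0)])
        out, dropped = drop_degenerate(self._table(X, ["A", "B"]))
        assert dropped == ["B"]

    def test_exact_linear_combination_dropped(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        X = np.column_stack([a, b, a + b])
        out, dropped = drop_degenerate(self._table(X, ["A", "B", "C"]))
        assert dropped == ["C"]
        assert np.linalg.matrix_rank(X - X.mean(0)) == 2  # oracle

    def test_full_rank_matrix_untouched(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 10))
        assert np.linalg.matrix_rank(X - X.mean(0)) == 10  # oracle
        _, dropped = drop_degenerate(self._table(X, [f"F{i}" for i in range(10)]))
        assert dropped == []


class TestDropRedundant:
    def test_duplicate_column_dropped(self, toy_well_table):
        t = toy_well_table.copy()
        t["F999"] = t["F000"]
        out, dropped = drop_redundant(t)
        assert len(dropped) == 1
        assert dropped[0] in ("F000", "F999")

    def test_high_correlation_pair_mean_r_rule(self):
        rng = np.random.default_rng(3)
        n = 300
        a = rng.standard_normal(n)
        b = a + 0.05 * rng.standard_normal(n)       # r(A,B) ~ 0.999
        c = b + 1.5 * rng.standard_normal(n)        # r(B,C) > r(A,C)
        d = rng.standard_normal(n)
        meta = pd.DataFrame(
            {"plate_id": "P01", "well": [f"A{i:03d}" for i in range(n)],
             "subclone_id": "SC1", "genotype": "KO", "treatment": "VEHICLE",
             "concentration_nM": 0.0}
        )
        t = pd.concat([meta, pd.DataFrame({"A": a, "B": b, "C": c, "D": d})], axis=1)
        # B's mean |r| (to A and C) exceeds A's, so B is dropped
        _, dropped = drop_redundant(t, r_threshold=0.95)
        assert dropped == ["B"]

    def test_orthogonal_columns_kept(self, toy_well_table):
        _, dropped = drop_redundant(toy_well_table, r_threshold=0.95)
        assert dropped == []

    def test_idempotent_on_own_output(self, toy_well_table):
        t = toy_well_table.copy()
        t["F999"] = t["F000"] + 0.01 * np.random.default_rng(4).standard_normal(len(t))
        once, dropped1 = drop_redundant(t)
        twice, dropped2 = drop_redundant(once)
        assert dropped1 and not dropped2
        pd.testing.assert_frame_equal(once, twice)


class TestAnovaFilter:
    def test_strong_effect_retained_with_tiny_q(self):
        rng = np.random.default_rng(5)
        n = 20
        t = pd.DataFrame(
            {
                "plate_id": "P01", "well": [f"A{i:02d}" for i in range(2 * n)],
                "subclone_id": "SC1",
                "genotype": ["WT"] * n + ["KO"] * n,
                "treatment": "VEHICLE", "concentration_nM": 0.0,
                "F001": np.r_[rng.normal(0, 1, n), rng.normal(5, 1, n)],
                "F002": rng.standard_normal(2 * n),
            }
        )
        rep = anova_filter(t, t["genotype"])
        assert rep.q_value["F001"] < 1e-10
        assert rep.q_value["F002"] > 0.05

    def test_constant_feature_untestable(self, toy_well_table):
        t = toy_well_table.copy()
        t["F000"] = 1.0
        rep = anova_filter(t, t["genotype"])
        assert "F000" in rep.untestable
        assert "F000" not in rep.q_value

    def test_small_group_rejected(self, toy_well_table):
        labels = toy_well_table["genotype"].copy()
        labels.iloc[0] = "ODD"
        with pytest.raises(ValueError, match="ODD"):
            anova_filter(toy_well_table, labels)

    def test_null_false_positive_rate_consistent_with_bh(self):
        """Two identical groups, 1000 features: the BH-significant
        fraction stays near the nominal false-discovery level."""
        rng = np.random.default_rng(6)
        n, m = 30, 1000
        meta = pd.DataFrame(
            {"plate_id": "P01", "well": [f"A{i:03d}" for i in range(2 * n)],
             "subclone_id": "SC1", "genotype": ["WT"] * n + ["KO"] * n,
             "treatment": "VEHICLE", "concentration_nM": 0.0}
        )
        X = pd.DataFrame(rng.standard_normal((2 * n, m)),
                         columns=[f"F{j:04d}" for j in range(m)])
        rep = anova_filter(pd.concat([meta, X], axis=1), meta["genotype"])
        assert rep.n_significant <= 0.01 * m  # BH under a global null


class TestQCReportInvariants:
    def test_count_identity_enforced(self):
        with pytest.raises(ValueError):
            QCReport(
                n_input_features=5, dropped_degenerate=["a"],
                dropped_redundant=[], n_retained=5,
            )

    def test_overlapping_drop_lists_rejected(self):
        with pytest.raises(ValueError):
            QCReport(
                n_input_features=3, dropped_degenerate=["a"],
                dropped_redundant=["a"], n_retained=1,
            )
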