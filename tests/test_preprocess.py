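"""Omics loading, MAF filtering, harmonization, staging labels and fold transforms."""

import numpy as np
import pandas as pd
import pytest

from pathfuse.preprocess import (
    EXCLUDED,
    OmicsMatrix,
    apply_fold_transform,
    binarize_stage,
    borderline_smote,
    fit_fold_transform,
    harmonize,
    load_expression,
    maf_to_binary_matrix,
)


class TestLoadExpression:
    def test_mt_genes_removed_and_log1p(self, tmp_path, rng):
        raw = pd.DataFrame(
            {"MT-CO1": [5.0, 2.0], "TP53": [0.0, 3.0]},
            index=["S1", "S2"],
        )
        path = tmp_path / "expr.tsv"
        raw.to_csv(path, sep="\t")
        m = load_expression(path)
        assert m.gene_ids == ["TP53"]
        np.testing.assert_allclose(m.values[:, 0], np.log1p([0.0, 3.0]))

    def test_elementwise_log1p_recompute(self, tmp_path, rng):
        vals = rng.uniform(0, 50, size=(5, 4))
        df = pd.DataFrame(vals, index=[f"S{i}" for i in range(5)],
                          columns=[f"G{j}" for j in range(4)])
        path = tmp_path / "expr.tsv"
        df.to_csv(path, sep="\t")
        m = load_expression(path)
        np.testing.assert_allclose(m.values, np.log(1.0 + vals))

    def test_negative_values_error(self, tmp_path):
        pd.DataFrame({"G1": [-1.0]}, index=["S1"]).to_csv(tmp_path / "e.tsv", sep="\t")
        with pytest.raises(ValueError, match="negative"):
            load_expression(tmp_path / "e.tsv")

    def test_empty_after_filter_error(self, tmp_path):
        pd.DataFrame({"MT-ND1": [1.0]}, index=["S1"]).to_csv(tmp_path / "e.tsv", sep="\t")
        with pytest.raises(ValueError, match="no genes"):
            load_expression(tmp_path / "e.tsv")


def maf_frame(rows):
    return pd.DataFrame(
        rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol",
                       "Variant_Classification", "t_alt_count"]
    )


class TestMafToBinary:
    def test_nonfunctional_dropped_alt_count_boundary_and_dedup(self):
        df = maf_frame([
            ("S1", "KRAS", "Silent", 30),        # non-functional -> dropped
            ("S1", "TP53", "Missense_Mutation", 5),   # alt count not > 5 -> dropped
            ("S1", "TP53", "Missense_Mutation", 6),   # kept
            ("S2", "EGFR", "Nonsense_Mutation", 40),  # kept
            ("S2", "EGFR", "Frame_Shift_Del", 22),    # duplicate pair -> single 1
        ])
        m = maf_to_binary_matrix(df)
        frame = m.to_frame()
        assert "KRAS" not in frame.columns
        assert frame.loc["S1", "TP53"] == 1
        assert frame.loc["S2", "EGFR"] == 1
        assert frame.to_numpy().sum() == 2

    def test_missing_mandatory_column_named(self):
        df = maf_frame([("S1", "TP53", "Missense_Mutation", 9)]).drop(
            columns=["Hugo_Symbol"]
        )
        with pytest.raises(ValueError, match="Hugo_Symbol"):
            maf_to_binary_matrix(df)

    def test_no_alt_count_column_filter_skipped(self, caplog):
        df = maf_frame([("S1", "TP53", "Missense_Mutation", 1)]).drop(
            columns=["t_alt_count"]
        )
        with caplog.at_level("INFO"):
            m = maf_to_binary_matrix(df)
        assert m.to_frame().loc["S1", "TP53"] == 1  # low support kept: filter skipped
        assert any("skipped" in r.message for r in caplog.records)


class TestHarmonize:
    def expr(self, ids, vals):
        return OmicsMatrix(ids, ["G1", "G2"], np.asarray(vals, float), "expression")

    def test_aliquots_averaged_to_short_id(self):
        m = self.expr(["TCGA-AA-0001-01A", "TCGA-AA-0001-01B"], [[1, 2], [3, 4]])
        (out,), _ = harmonize([m])
        assert out.sample_ids == ["TCGA-AA-0001"]
        np.testing.assert_allclose(out.values, [[2.0, 3.0]])

    def test_snv_rebinarized_after_averaging(self):
        m = OmicsMatrix(
            ["TCGA-AA-0001-01A", "TCGA-AA-0001-01B"], ["G1", "G2"],
            np.array([[1.0, 0.0], [0.0, 0.0]]), "snv",
        )
        (out,), _ = harmonize([m])
        np.testing.assert_array_equal(out.values, [[1.0, 0.0]])

    def test_disjoint_samples_error(self):
        a = self.expr(["TCGA-AA-0001"], [[1, 2]])
        b = self.expr(["TCGA-BB-0002"], [[1, 2]])
        with pytest.raises(ValueError, match="no samples shared"):
            harmonize([a, b])

    def test_intersection_matches_set_oracle(self, rng):
        ids = [f"TCGA-{i:02d}-0000" for i in range(12)]
        subsets = [sorted(rng.choice(ids, size=8, replace=False)) for _ in range(3)]
        mats = [self.expr(s, rng.normal(size=(8, 2))) for s in subsets]
        out, _ = harmonize(mats)
        expected = sorted(set(subsets[0]) & set(subsets[1]) & set(subsets[2]))
        for m in out:
            assert m.sample_ids == expected

    def test_idempotent(self, rng):
        m = self.expr(["TCGA-AA-0001-01A", "TCGA-AA-0001-01B", "TCGA-BB-0002"],
                      rng.normal(size=(3, 2)))
        (once,), _ = harmonize([m])
        (twice,), _ = harmonize([once])
        assert once.sample_ids == twice.sample_ids
        np.testing.assert_allclose(once.values, twice.values)


class TestBinarizeStage:
    @pytest.mark.parametrize(
        "raw,endpoint,expected",
        [
            ("T2a", "T", 0), ("T3", "T", 1), ("Tis", "T", 0), ("T1b", "T", 0),
            ("T4a", "T", 1), ("t2", "T", 0),
            ("N0", "N", 0), ("N1", "N", 1), ("N2a", "N", 1), ("N3", "N", 1),
            ("M0", "M", 0), ("M1b", "M", 1),
            ("NX", "N", EXCLUDED), ("TX", "T", EXCLUDED), ("MX", "M", EXCLUDED),
            ("not reported", "T", EXCLUDED),
        ],
    )
    def test_binarization_table(self, raw, endpoint, expected):
        assert binarize_stage(raw, endpoint) == expected

    def test_unrecognized_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="unrecognized"):
            assert binarize_stage("stage shrug", "T") == EXCLUDED

    @pytest.mark.filterwarnings("ignore:unrecognized")
    def test_partition_no_fallthrough(self):
        observed = ["Tis", "T1", "T1a", "T2b", "T3", "T4", "TX", "weird", ""]
        outs = {binarize_stage(s, "T") for s in observed}
        assert outs <= {0, 1, EXCLUDED}


class TestFoldTransform:
    def make(self, vals, modality="expression"):
        ids = [f"S{i}" for i in range(len(vals))]
        return OmicsMatrix(ids, ["G1"], np.asarray(vals, float).reshape(-1, 1), modality)

    def test_mean2_sd1_example(self):
        t = fit_fold_transform(self.make([[1], [3]]))
        val = apply_fold_transform(t, self.make([[2]]))
        assert val.values[0, 0] == pytest.approx(0.0)

    def test_missing_imputed_with_training_mean(self):
        t = fit_fold_transform(self.make([[1], [3]]))
        val = apply_fold_transform(t, self.make([[np.nan]]))
        # imputed to training mean 2 then standardized to 0 — never the val mean
        assert val.values[0, 0] == pytest.approx(0.0)

    def test_training_columns_centered(self, rng):
        vals = rng.normal(2, 3, size=(20, 1))
        tr = self.make(vals)
        t = fit_fold_transform(tr)
        out = apply_fold_transform(t, tr)
        assert abs(out.values.mean()) < 1e-9

    def test_zero_variance_scale_one(self):
        with pytest.warns(UserWarning, match="zero training variance"):
            t = fit_fold_transform(self.make([[5], [5]]))
        assert t.scales[0] == 1.0

    def test_snv_not_scaled(self):
        t = fit_fold_transform(self.make([[0], [1]], modality="snv"))
        out = apply_fold_transform(t, self.make([[1], [1]], modality="snv"))
        np.testing.assert_array_equal(out.values, [[1.0], [1.0]])

    def test_validation_sentinel_never_leaks(self, rng):
        train = self.make(rng.normal(size=(10, 1)))
        t1 = fit_fold_transform(train)
        # corrupting validation data after the fit must change nothing
        val = self.make(np.full((3, 1), 1e9))
        t2 = fit_fold_transform(train)
        np.testing.assert_array_equal(t1.means, t2.means)
        np.testing.assert_array_equal(t1.scales, t2.scales)
        out = apply_fold_transform(t1, val)
        expected = (1e9 - t1.means[0]) / t1.scales[0]
        np.testing.assert_allclose(out.values, np.full((3, 1), expected))


class TestBorderlineSmote:
    def imbalanced(self, rng, n_min=20, n_maj=80, p=4):
        x_min = rng.normal(0, 1, size=(n_min, p))
        x_maj = rng.normal(1.0, 1, size=(n_maj, p))
        x = np.vstack([x_min, x_maj])
        y = np.array([1] * n_min + [0] * n_maj)
        return x, y

    def test_cap_respected(self, rng):
        x, y = self.imbalanced(rng)
        ax, ay = borderline_smote(x, y, seed=0)
        assert len(ay) - len(y) <= int(0.15 * len(y))
        np.testing.assert_array_equal(ax[: len(y)], x)  # originals untouched, retained

    def test_balanced_classes_no_synthesis(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.array([0] * 20 + [1] * 20)
        ax, ay = borderline_smote(x, y, seed=0)
        assert len(ay) == 40

    def test_synthetic_rows_collinear_with_minority_pairs(self, rng):
        x, y = self.imbalanced(rng)
        ax, ay = borderline_smote(x, y, seed=1)
        x_min = x[y == 1]
        for row in ax[len(y):]:
            # solve for an interpolation coefficient against every minority pair
            found = False
            for i in range(len(x_min)):
                d = row - x_min[i]
                for j in range(len(x_min)):
                    if i == j:
                        continue
                    e = x_min[j] - x_min[i]
                    denom = float(e @ e)
                    if denom == 0:
                        continue
                    lam = float(d @ e) / denom
                    if 0 <= lam <= 1 and np.allclose(row, x_min[i] + lam * e, atol=1e-8):
                        found = True
                        break
                if found:
                    break
            assert found, "synthetic row not on a minority-minority segment"

    def test_imbalance_weakly_reduced(self, rng):
        x, y = self.imbalanced(rng)
        _, ay = borderline_smote(x, y, seed=2)
        before = min((y == 0).sum(), (y == 1).sum()) / max((y == 0).sum(), (y == 1).sum())
        after = min((ay == 0).sum(), (ay == 1).sum()) / max((ay == 0).sum(), (ay == 1).sum())
        assert after >= before

    def test_non_binary_error(self, rng):
        with pytest.raises(ValueError, match="binary"):
            borderline_smote(rng.normal(size=(9, 2)), np.array([0, 1, 2] * 3))

    def test_tiny_minority_skipped_with_warning(self, rng):
        x = rng.normal(size=(20, 2))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.warns(UserWarning, match="skipped"):
            ax, ay = borderline_smote(x, y, k=5, seed=0)
        assert len(ay) == 20
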