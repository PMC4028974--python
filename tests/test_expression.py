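"""Ct loading, interplate calibration, global-mean dCt and 2^-ddCt folds."""

import math

import numpy as np
import pandas as pd
import pytest

from mirdegree import errors
from mirdegree.expression import (
    estimate_plate_offsets,
    dysregulation_report,
    fold_changes,
    global_mean_normalize,
    interplate_calibrate,
    load_ct,
    write_ct,
)
from mirdegree.synthetic import (
    CALIBRATOR_ID,
    CASE_SAMPLE,
    REFERENCE_SAMPLE,
    SyntheticSpec,
    balanced_log2fc,
    generate_plates,
)


def _ct_frame(rows):
    return pd.DataFrame(rows, columns=["plate_id", "sample_id", "replicate_id", "mirna_id", "ct"])


class TestLoadCt:
    def test_undetected_markers(self, tmp_path):
        f = tmp_path / "ct.tsv"
        f.write_text(
            "plate_id\tsample_id\treplicate_id\tmirna_id\tct\n"
            "p1\ts1\tr1\tmiR-1\tUndetermined\n"
            "p1\ts1\tr1\tmiR-2\t38\n"
            "p1\ts1\tr1\tmiR-3\t25.5\n"
        )
        df = load_ct(f, detection_limit=37.0)
        by = df.set_index("mirna_id")["ct"]
        assert math.isnan(by["miR-1"]) and math.isnan(by["miR-2"])
        assert by["miR-3"] == pytest.approx(25.5)

    def test_duplicate_key_rejected(self, tmp_path):
        f = tmp_path / "ct.tsv"
        f.write_text(
            "plate_id\tsample_id\treplicate_id\tmirna_id\tct\n"
            "p1\ts1\tr1\tmiR-1\t20\np1\ts1\tr1\tmiR-1\t21\n"
        )
        with pytest.raises(errors.FormatError, match="duplicate"):
            load_ct(f)

    def test_out_of_range_ct_rejected(self, tmp_path):
        f = tmp_path / "ct.tsv"
        f.write_text("plate_id\tsample_id\treplicate_id\tmirna_id\tct\np1\ts1\tr1\tm\t55\n")
        with pytest.raises(errors.FormatError):
            load_ct(f)

    def test_roundtrip_through_writer(self, tmp_path):
        spec = SyntheticSpec(n_nodes=20, n_mirnas=8, targets_per_mirna=3, seed=4)
        plates = generate_plates(spec)
        path = tmp_path / "ct.tsv"
        write_ct(plates, path)
        back = load_ct(path)
        merged = plates.merge(back, on=["plate_id", "sample_id", "replicate_id", "mirna_id"])
        assert len(merged) == len(plates)
        both = merged[["ct_x", "ct_y"]].dropna()
        assert np.allclose(both["ct_x"], both["ct_y"])
        assert (merged["ct_x"].isna() == merged["ct_y"].isna()).all()


class TestCalibration:
    def test_single_plate_is_identity(self):
        df = _ct_frame(
            [("p1", "s1", "r1", "cal", 20.0), ("p1", "s1", "r1", "miR-1", 30.0)]
        )
        out = interplate_calibrate(df, "cal")
        assert out["ct"].tolist() == [30.0]
        assert "cal" not in out["mirna_id"].tolist()

    def test_two_plate_worked_example(self):
        # calibrator at 20 and 22 -> grand mean 21, offsets -1 and +1
        df = _ct_frame(
            [
                ("p1", "s1", "r1", "cal", 20.0),
                ("p1", "s1", "r1", "miR-1", 25.0),
                ("p2", "s2", "r1", "cal", 22.0),
                ("p2", "s2", "r1", "miR-1", 30.0),
            ]
        )
        offsets = estimate_plate_offsets(df, "cal")
        assert offsets["p1"] == pytest.approx(-1.0)
        assert offsets["p2"] == pytest.approx(1.0)
        out = interplate_calibrate(df, "cal").set_index("plate_id")["ct"]
        assert out["p1"] == pytest.approx(26.0)
        assert out["p2"] == pytest.approx(29.0)

    def test_missing_calibrator_names_plate(self):
        df = _ct_frame([("p1", "s1", "r1", "cal", 20.0), ("p2", "s1", "r2", "miR-1", 30.0)])
        with pytest.raises(errors.ConfigError, match="p2"):
            interplate_calibrate(df, "cal")

    def test_injected_offsets_recovered_to_machine_precision(self, rng):
        offsets = {"P69_rep25": 1.3, "P69_rep50": -0.7, "M12_rep25": 0.2, "M12_rep50": -0.8}
        spec = SyntheticSpec(
            n_nodes=20, n_mirnas=10, targets_per_mirna=3, plate_offsets=offsets, seed=9
        )
        plates = generate_plates(spec)
        est = estimate_plate_offsets(plates, CALIBRATOR_ID)
        centred = {p: v - np.mean(list(offsets.values())) for p, v in offsets.items()}
        for plate, val in centred.items():
            assert est[plate] == pytest.approx(val, abs=1e-12)


class TestNormalization:
    def test_hand_case_and_constant_shift_invariance(self):
        df = _ct_frame(
            [("p1", "s1", "r1", f"m{i}", ct) for i, ct in enumerate([20.0, 22.0, 24.0])]
        )
        dct = global_mean_normalize(df)
        assert dct["dct"].tolist() == [-2.0, 0.0, 2.0]
        shifted = df.copy()
        shifted["ct"] += 5.0
        assert global_mean_normalize(shifted)["dct"].tolist() == [-2.0, 0.0, 2.0]

    def test_all_undetected_sample_rejected(self):
        df = _ct_frame([("p1", "sX", "r1", "m1", np.nan)])
        with pytest.raises(errors.ConfigError, match="sX"):
            global_mean_normalize(df)

    def test_undetected_propagates(self):
        df = _ct_frame(
            [("p1", "s1", "r1", "m1", 20.0), ("p1", "s1", "r1", "m2", np.nan)]
        )
        dct = global_mean_normalize(df).set_index("mirna_id")["dct"]
        assert dct["m1"] == 0.0 and math.isnan(dct["m2"])


def _two_sample_dct(folds_by_rep):
    """Build a dCt frame planting given per-replicate log2 folds for one miRNA
    against a backdrop of two null miRNAs."""
    rows = []
    for rep, lfc in folds_by_rep.items():
        for sample in ("REF", "CASE"):
            rows.append((f"{sample}_{rep}", sample, rep, "null-1", 1.0))
            rows.append((f"{sample}_{rep}", sample, rep, "null-2", -1.0))
            rows.append((f"{sample}_{rep}", sample, rep, "target", -lfc if sample == "CASE" else 0.0))
    return _ct_frame(rows).rename(columns={"ct": "dct"})


class TestFoldChanges:
    @pytest.mark.parametrize("lfc, expected", [(0.0, 1.0), (3.0, 8.0), (-1.0, 0.5)])
    def test_ddct_model(self, lfc, expected):
        dct = _two_sample_dct({"r1": lfc, "r2": lfc})
        fct = fold_changes(dct, "REF", "CASE")
        assert fct.summary.loc["target", "fc_consensus"] == pytest.approx(expected)

    def test_reference_vs_itself_is_unity(self):
        dct = _two_sample_dct({"r1": 2.0, "r2": 2.0})
        fct = fold_changes(dct, "REF", "REF")
        assert np.allclose(fct.summary["fc_consensus"], 1.0)

    def test_concordance_filter(self):
        # both replicates >= 2-fold up -> dysregulated; discordant -> not
        up = fold_changes(_two_sample_dct({"r1": 1.5, "r2": 1.1}), "REF", "CASE")
        assert bool(up.summary.loc["target", "dysregulated"])
        assert up.summary.loc["target", "reg_class"] == "oncomiR"
        mixed = fold_changes(_two_sample_dct({"r1": 1.5, "r2": 0.5}), "REF", "CASE")
        assert not bool(mixed.summary.loc["target", "dysregulated"])

    def test_dropout_floor_and_cap(self):
        dct = _two_sample_dct({"r1": 4.0, "r2": 4.0})
        # knock the target out of the case sample on both replicates
        dct.loc[(dct["mirna_id"] == "target") & (dct["sample_id"] == "CASE"), "dct"] = np.nan
        fct = fold_changes(dct, "REF", "CASE")
        row = fct.summary.loc["target"]
        assert row["fc_consensus"] == 0.0
        assert bool(row["dysregulated"])  # 0 counts as concordant loss
        assert row["reg_class"] == "suppressor"
        assert row["log10_fc"] == pytest.approx(-math.log10(fct.fc_cap))
        # reference-side knockout caps instead
        dct2 = _two_sample_dct({"r1": 4.0, "r2": 4.0})
        dct2.loc[(dct2["mirna_id"] == "target") & (dct2["sample_id"] == "REF"), "dct"] = np.nan
        row2 = fold_changes(dct2, "REF", "CASE").summary.loc["target"]
        assert row2["fc_consensus"] == fct.fc_cap and bool(row2["capped"])

    def test_dropout_excluded_from_geomean_when_direction_agrees(self):
        dct = _two_sample_dct({"r1": -2.0, "r2": -2.0})  # fold 0.25 in both
        dct.loc[
            (dct["mirna_id"] == "target")
            & (dct["sample_id"] == "CASE")
            & (dct["replicate_id"] == "r2"),
            "dct",
        ] = np.nan
        row = fold_changes(dct, "REF", "CASE").summary.loc["target"]
        assert row["fc_consensus"] == pytest.approx(0.25)  # geomean of finite folds only
        # conflicting direction leaves consensus undefined
        dct_bad = _two_sample_dct({"r1": 2.0, "r2": 2.0})  # fold 4 in r1
        dct_bad.loc[
            (dct_bad["mirna_id"] == "target")
            & (dct_bad["sample_id"] == "CASE")
            & (dct_bad["replicate_id"] == "r2"),
            "dct",
        ] = np.nan
        row_bad = fold_changes(dct_bad, "REF", "CASE").summary.loc["target"]
        assert math.isnan(row_bad["fc_consensus"])
        assert row_bad["reg_class"] == "unclassified"

    def test_missing_sample_rejected(self):
        with pytest.raises(errors.ConfigError):
            fold_changes(_two_sample_dct({"r1": 1.0}), "REF", "NOPE")

    def test_noiseless_synthetic_recovery_exact(self):
        ids = [f"sim-miR-{i}" for i in range(1, 11)]
        planted = balanced_log2fc(ids, 1, 1, 1.0)  # +1 and -1 cancel in the mean
        spec = SyntheticSpec(
            n_nodes=20, n_mirnas=10, targets_per_mirna=2,
            planted_log2fc=planted, ct_noise_sd=0.0, seed=6,
        )
        plates = generate_plates(spec, ids)
        dct = global_mean_normalize(interplate_calibrate(plates, CALIBRATOR_ID))
        fct = fold_changes(dct, REFERENCE_SAMPLE, CASE_SAMPLE)
        for mirna, lfc in planted.items():
            assert fct.summary.loc[mirna, "fc_consensus"] == pytest.approx(2.0**lfc, abs=1e-9)

    def test_plate_constant_shift_is_invisible_end_to_end(self):
        ids = [f"sim-miR-{i}" for i in range(1, 9)]
        spec = SyntheticSpec(
            n_nodes=20, n_mirnas=8, targets_per_mirna=2,
            planted_log2fc=balanced_log2fc(ids, 1, 1, 2.0), ct_noise_sd=0.1, seed=13,
        )
        plates = generate_plates(spec, ids)
        shifted = plates.copy()
        shifted.loc[shifted["plate_id"] == "M12_rep25", "ct"] += 3.0

        def pipeline(df):
            return fold_changes(
                global_mean_normalize(interplate_calibrate(df, CALIBRATOR_ID)),
                REFERENCE_SAMPLE,
                CASE_SAMPLE,
            ).summary["fc_consensus"]

        pd.testing.assert_series_equal(pipeline(plates), pipeline(shifted))


class TestReport:
    def test_empty_table_counts_zero(self):
        fct = fold_changes(_two_sample_dct({"r1": 0.0, "r2": 0.0}), "REF", "CASE")
        fct.summary = fct.summary.iloc[0:0]
        rep = dysregulation_report(fct)
        assert rep.n_dysregulated == rep.n_oncomirs == rep.n_suppressors == rep.n_extreme == 0

    def test_hand_counts(self):
        # folds 4 (dysregulated oncomiR), 0.1 (dysregulated suppressor, beyond
        # the 8-fold cut since 0.1 <= 1/8) and 1.5 (not dysregulated)
        rows = []
        for rep in ("r1", "r2"):
            for sample in ("REF", "CASE"):
                case = sample == "CASE"
                rows += [
                    (f"{sample}_{rep}", sample, rep, "m-up", -math.log2(4.0) if case else 0.0),
                    (f"{sample}_{rep}", sample, rep, "m-down", -math.log2(0.1) if case else 0.0),
                    (f"{sample}_{rep}", sample, rep, "m-mid", -math.log2(1.5) if case else 0.0),
                    (f"{sample}_{rep}", sample, rep, "m-null1", 1.0),
                    (f"{sample}_{rep}", sample, rep, "m-null2", -1.0),
                ]
        dct = _ct_frame(rows).rename(columns={"ct": "dct"})
        fct = fold_changes(dct, "REF", "CASE")
        rep = dysregulation_report(fct, extreme_threshold=8.0)
        assert rep.n_dysregulated == 2
        assert rep.n_oncomirs == 1
        assert rep.n_suppressors == 1
        assert rep.n_extreme == 1
        assert rep.histogram["count"].sum() == 2
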