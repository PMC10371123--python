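import numpy as np
import pandas as pd
import pytest

from nbnscreen.errors import ConfigError, DomainError, PairingError, SampleError
from nbnscreen.mmc import (
    BarcodeCountTable,
    MMCClass,
    classify_mmc,
    normalize_counts,
    summarize_mmc,
    variant_fold_change,
)
from nbnscreen.simulate import (
    ScreenSimConfig,
    expected_fold_change,
    generate_barcode_screen,
    sensitivities_for_targets,
)


def toy_table(counts: dict, timepoints=("day0", "day14"), barcode_variants=None):
    """Single-replicate table from {sample: {barcode: count}}."""
    counts_df = pd.DataFrame(counts)
    counts_df.index.name = "barcode_id"
    sheet = pd.DataFrame(
        {
            "sample_id": list(counts),
            "replicate": 1,
            "timepoint": list(timepoints),
        }
    ).set_index("sample_id")
    bmap = pd.Series(
        barcode_variants or {b: b for b in counts_df.index}, name="variant_id"
    )
    return BarcodeCountTable(counts=counts_df, sample_sheet=sheet, barcode_map=bmap)


class TestNormalization:
    def test_direct_arithmetic(self):
        table = toy_table({"s0": {"b1": 100, "b2": 900}, "s1": {"b1": 1, "b2": 1}})
        freqs = normalize_counts(table, pseudocount=0)
        assert freqs["s0"].tolist() == [0.1, 0.9]

    def test_columns_sum_to_one(self):
        sens = {f"v{i}": 0.02 * i for i in range(5)}
        table = generate_barcode_screen(sens, ScreenSimConfig(read_depth=10000), seed=2)
        freqs = normalize_counts(table)
        assert np.allclose(freqs.sum(axis=0), 1.0)

    def test_pseudocount_keeps_zero_counts_positive(self):
        table = toy_table({"s0": {"b1": 0, "b2": 1000}, "s1": {"b1": 1, "b2": 1}})
        freqs = normalize_counts(table, pseudocount=0.5)
        assert 0 < freqs.loc["b1", "s0"] < 1e-3

    def test_zero_total_sample_named_in_error(self):
        table = toy_table({"s0": {"b1": 0, "b2": 0}, "s1": {"b1": 1, "b2": 1}})
        with pytest.raises(SampleError, match="s0"):
            normalize_counts(table)


class TestFoldChange:
    def test_hand_computed_two_barcode_table(self):
        # day0 freqs: 0.10 / 0.90; day14 freqs: 0.05 / 0.95 -> fc = 0.5 and ~1.056
        table = toy_table({"d0": {"b1": 100, "b2": 900}, "d14": {"b1": 50, "b2": 950}})
        freqs = normalize_counts(table, pseudocount=0)
        fc = variant_fold_change(freqs, table, "day14")
        assert fc["b1"] == pytest.approx(0.5)
        assert fc["b2"] == pytest.approx(0.95 / 0.9)

    def test_unchanged_frequencies_give_unit_fold_change(self):
        table = toy_table({"d0": {"b1": 300, "b2": 700}, "d14": {"b1": 300, "b2": 700}})
        freqs = normalize_counts(table, pseudocount=0)
        assert np.allclose(variant_fold_change(freqs, table, "day14"), 1.0)

    def test_mean_of_nine_measurements(self):
        """Constant per-barcode fold change v means the variant mean is v."""
        sens = {"v": 0.0, "w": 0.0}
        table = generate_barcode_screen(sens, ScreenSimConfig(read_depth=1000), seed=1)
        freqs = normalize_counts(table)
        fc, detail = variant_fold_change(freqs, table, "day14", detail=True)
        grouped = (
            detail.stack()
            .rename("fc")
            .rename_axis(["barcode_id", "replicate"])
            .reset_index()
        )
        grouped["variant_id"] = grouped["barcode_id"].map(table.barcode_map)
        by_hand = grouped.groupby("variant_id")["fc"].mean()
        assert np.allclose(fc.sort_index(), by_hand.sort_index())
        assert detail.shape == (6, 3)  # 3 barcodes x 2 variants, 3 replicates

    def test_missing_day0_is_a_pairing_error(self):
        table = toy_table(
            {"a": {"b1": 10, "b2": 10}, "b": {"b1": 10, "b2": 10}},
            timepoints=("day10", "day14"),
        )
        freqs = normalize_counts(table)
        with pytest.raises(PairingError):
            variant_fold_change(freqs, table, "day14")

    def test_depth_invariance(self):
        """Scaling one sample's counts leaves fold changes nearly unchanged."""
        base = {"d0": {"b1": 40_000, "b2": 60_000}, "d14": {"b1": 20_000, "b2": 80_000}}
        t1 = toy_table(base)
        scaled = {**base, "d14": {k: v * 7 for k, v in base["d14"].items()}}
        t2 = toy_table(scaled)
        fc1 = variant_fold_change(normalize_counts(t1), t1, "day14")
        fc2 = variant_fold_change(normalize_counts(t2), t2, "day14")
        assert np.allclose(fc1, fc2, rtol=1e-2)


class TestMMCClass:
    @pytest.mark.parametrize(
        "fc, expected",
        [
            (0.5, MMCClass.HIGH),
            (0.749, MMCClass.HIGH),
            (0.75, MMCClass.MODERATE),
            (1.0, MMCClass.MODERATE),
            (1.001, MMCClass.WT_LIKE),
            (1.3, MMCClass.WT_LIKE),
        ],
    )
    def test_class_bins(self, fc, expected):
        assert classify_mmc(fc) is expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            classify_mmc(-0.2)


class TestScreenRecovery:
    def test_tier_recovery_across_seeds(self):
        """Classes assigned by the pipeline match the generating tier at
        tier-midpoint expected fold changes, 20 seeds, depth 1e6."""
        targets = (
            {f"high{i}": 0.4 for i in range(4)}
            | {f"mod{i}": 0.875 for i in range(3)}
            | {f"wt{i}": None for i in range(3)}
        )
        cfg = ScreenSimConfig(read_depth=1_000_000)
        sens = sensitivities_for_targets(targets, cfg)
        expected = expected_fold_change(sens, cfg)
        assert all(v > 1 for k, v in expected.items() if k.startswith("wt"))
        for seed in range(20):
            table = generate_barcode_screen(sens, cfg, seed=seed)
            summaries, _ = summarize_mmc(table)
            for s in summaries:
                want = classify_mmc(expected[s.variant_id])
                assert s.mmc_class is want, f"{s.variant_id} seed {seed}"

    def test_day10_less_depleted_than_day14(self):
        sens = sensitivities_for_targets({"hit": 0.4, "wt": None})
        table = generate_barcode_screen(sens, seed=9)
        summaries, _ = summarize_mmc(table)
        hit = next(s for s in summaries if s.variant_id == "hit")
        assert hit.fold_change_day14 < hit.fold_change_day10 < 1.0

    def test_qc_table_covers_nine_measurements(self):
        sens = {"v": 0.05, "w": 0.0}
        table = generate_barcode_screen(sens, seed=4)
        _, qc = summarize_mmc(table)
        assert (qc["count"] == 9).all()
        assert (qc["min"] <= qc["max"]).all()


def test_table_validation_rejects_unmapped_barcode():
    counts = pd.DataFrame({"s0": [1], "s1": [1]}, index=pd.Index(["bX"], name="barcode_id"))
    sheet = pd.DataFrame(
        {"sample_id": ["s0", "s1"], "replicate": 1, "timepoint": ["day0", "day14"]}
    ).set_index("sample_id")
    with pytest.raises(ConfigError, match="without a variant mapping"):
        BarcodeCountTable(counts=counts, sample_sheet=sheet, barcode_map=pd.Series(dtype=object))
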