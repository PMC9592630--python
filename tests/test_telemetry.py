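"""Detection filtering, environmental annotation, and occupancy accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxytherm as ox
from oxytherm.limnofield import DISSOLVED_OXYGEN, TEMPERATURE


def det_frame(seconds, fish="LW6", depth=6.0, start="2015-06-01"):
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(seconds=s) for s in seconds],
            "fish_id": fish,
            "depth_m": depth,
        }
    )


def meta_frame(fish_ids=("LW6",), cutoff="2015-05-23"):
    return pd.DataFrame(
        {
            "fish_id": list(fish_ids),
            "total_length_mm": 584.0,
            "cutoff_date": pd.Timestamp(cutoff),
        }
    )


class TestDedupe:
    def test_last_kept_rule_hand_trace(self):
        """Gaps 30, 30, 120 s: the second ping is <60 s from the first, the
        third is 60 s from the first kept, the fourth clears easily."""
        raw = det_frame([0, 30, 60, 180])
        kept, report = ox.filter_detections(raw, meta_frame())
        assert list(kept["timestamp"].dt.second + kept["timestamp"].dt.minute * 60) == [0, 60, 180]
        assert report.n_after_dedupe == 3
        assert report.n_duplicates == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        raw = det_frame(np.sort(rng.integers(0, 4000, size=200)))
        once, _ = ox.filter_detections(raw, meta_frame())
        twice, report = ox.filter_detections(once, meta_frame())
        assert len(twice) == len(once)
        assert report.n_duplicates == 0
        assert (twice["timestamp"].to_numpy() == once["timestamp"].to_numpy()).all()

    def test_spacing_guarantee(self):
        rng = np.random.default_rng(4)
        raw = det_frame(np.sort(rng.integers(0, 10_000, size=500)))
        kept, _ = ox.filter_detections(raw, meta_frame())
        gaps = kept["timestamp"].diff().dt.total_seconds().dropna()
        assert (gaps >= 60.0).all()

    def test_per_fish_independence(self):
        a = det_frame([0, 30, 90], fish="LW6")
        b = det_frame([10, 40, 100], fish="LW7")
        raw = pd.concat([a, b], ignore_index=True)
        kept, _ = ox.filter_detections(raw, meta_frame(("LW6", "LW7")))
        assert (kept.groupby("fish_id").size() == 2).all()


class TestQualityFilters:
    def test_deep_detection_dropped(self):
        raw = det_frame([0, 120])
        raw.loc[1, "depth_m"] = 14.5
        kept, report = ox.filter_detections(raw, meta_frame())
        assert report.n_depth_dropped == 1
        assert len(kept) == 1

    def test_unknown_id_dropped(self):
        raw = det_frame([0, 120], fish="XX1")
        kept, report = ox.filter_detections(raw, meta_frame())
        assert report.n_unknown_id == 2
        assert kept.empty

    def test_pre_cutoff_dropped(self):
        raw = det_frame([0, 120], start="2015-05-20")
        kept, report = ox.filter_detections(raw, meta_frame(cutoff="2015-05-23"))
        assert report.n_pre_cutoff == 2
        assert kept.empty

    def test_hpe_reported_not_filtered(self):
        raw = det_frame([0, 120, 240, 360])
        raw["hpe"] = [5.0, 25.0, 10.0, 8.0]
        kept, report = ox.filter_detections(raw, meta_frame())
        assert len(kept) == 4
        assert report.hpe_gt_threshold_frac == pytest.approx(0.25)

    def test_empty_input(self):
        kept, report = ox.filter_detections(det_frame([]), meta_frame())
        assert kept.empty
        assert report.n_raw == 0

    def test_quality_filters_commute(self):
        rng = np.random.default_rng(5)
        raw = det_frame(np.sort(rng.integers(0, 50_000, size=300)),
                        start="2015-05-20")
        raw["depth_m"] = rng.uniform(0, 16, size=len(raw))
        raw.loc[::17, "fish_id"] = "XX9"
        meta = meta_frame(cutoff="2015-05-21")
        kept_canonical, _ = ox.filter_detections(raw, meta)
        # manual re-ordering: depth first, then cutoff, then ID, then dedupe
        alt = raw[raw["depth_m"] <= 14.0]
        alt = alt[alt["timestamp"] >= pd.Timestamp("2015-05-21")]
        alt = alt[alt["fish_id"] == "LW6"]
        kept_alt, _ = ox.filter_detections(alt, meta)
        assert (kept_alt["timestamp"].to_numpy()
                == kept_canonical["timestamp"].to_numpy()).all()


def _mini_fields():
    grid = np.round(np.arange(0, 10.1, 0.1), 6)
    hours = pd.date_range("2015-06-01", periods=48, freq="h")
    temps = np.tile((20.0 - grid)[:, None], (1, 48))
    days = pd.date_range("2015-06-01", periods=2, freq="D")
    do = np.tile((10.0 - grid)[:, None], (1, 2))
    return (
        ox.GriddedField(TEMPERATURE, grid, hours, temps),
        ox.GriddedField(DISSOLVED_OXYGEN, grid, days, do),
    )


class TestAnnotation:
    def test_exact_cell_lookup(self):
        t_field, do_field = _mini_fields()
        det = det_frame([3600], depth=5.0)
        ann = ox.annotate_environment(det, t_field, do_field)
        assert ann["ambient_temp"].iloc[0] == pytest.approx(15.0)
        assert ann["ambient_do"].iloc[0] == pytest.approx(5.0)

    def test_nearest_cell_rule(self):
        t_field, do_field = _mini_fields()
        ann = ox.annotate_environment(det_frame([0], depth=5.04), t_field, do_field)
        assert ann["ambient_temp"].iloc[0] == pytest.approx(15.0)  # cell 5.0

    def test_outside_coverage_flagged(self):
        t_field, do_field = _mini_fields()
        ann = ox.annotate_environment(
            det_frame([0], start="2015-07-01"), t_field, do_field)
        assert ann["coverage_flag"].iloc[0]
        assert np.isnan(ann["ambient_temp"].iloc[0])


class TestOccupancy:
    def _annotated(self, temps, dos):
        df = det_frame(range(0, len(temps) * 120, 120))
        df["ambient_temp"] = temps
        df["ambient_do"] = dos
        return df

    def test_all_inside(self):
        table = ox.occupancy_table(self._annotated([6.0] * 4, [8.0] * 4))
        row = table[table["tier"] == "optimal"].iloc[0]
        assert row["inside_pct"] == 100.0
        assert row["warm_pct"] == 0.0 and row["low_do_pct"] == 0.0

    def test_constructed_counts_with_overlap(self):
        """5 inside, 3 warm-only, 1 low-DO-only, 1 both: 50/40/20, overlap 10."""
        temps = [6] * 5 + [16] * 3 + [6] + [16]
        dos = [8] * 5 + [8] * 3 + [1] + [1]
        table = ox.occupancy_table(self._annotated(temps, dos))
        row = table[table["tier"] == "usable"].iloc[0]
        assert row["inside_pct"] == pytest.approx(50.0)
        assert row["warm_pct"] == pytest.approx(40.0)
        assert row["low_do_pct"] == pytest.approx(20.0)
        assert row["both_pct"] == pytest.approx(10.0)

    def test_doubly_suboptimal_detection_counted_in_both_columns(self):
        table = ox.occupancy_table(self._annotated([11.0], [3.0]))
        row = table[table["tier"] == "optimal"].iloc[0]
        assert row["warm_pct"] == 100.0 and row["low_do_pct"] == 100.0
        assert row["both_pct"] == 100.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            ox.occupancy_table(
                self._annotated([6.0], [8.0]), window=("2016-01-01", "2016-01-02"))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 30), st.floats(0, 12)),
                    min_size=1, max_size=60))
    def test_accounting_identity(self, pairs):
        temps, dos = zip(*pairs)
        table = ox.occupancy_table(self._annotated(list(temps), list(dos)))
        for _, row in table.iterrows():
            total = row["inside_pct"] + row["warm_pct"] + row["low_do_pct"] - row["both_pct"]
            assert total == pytest.approx(100.0, abs=1e-9)


def test_window_presets_are_twenty_days():
    for name, (a, b) in ox.WINDOW_PRESETS.items():
        assert (pd.Timestamp(b) - pd.Timestamp(a)).days == 19  # inclusive
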