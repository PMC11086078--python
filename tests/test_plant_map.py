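"""Boll architecture, lint metrics, per-location aggregation and joins."""

import math

import numpy as np
import pandas as pd
import pytest

from cottonfir.band_indices import AggregatedIndices
from cottonfir.plant_map import (
    BollRecord,
    PlantMap,
    combine_locations,
    format_location,
    join_conventional,
    lint_percentage,
    location_series,
    parse_location,
    plant_totals,
)


def boll(plant_id, node, pos, m_ir=0.8, ci_ir=80.0, lint=2.0, seed_cotton=None):
    return BollRecord(
        plant_id=plant_id, node=node, position=pos, lint_mass=lint,
        seed_cotton_mass=seed_cotton,
        indices=AggregatedIndices(mean_m_ir=m_ir, sem_m_ir=0.01,
                                  mean_ci_ir=ci_ir, sem_ci_ir=1.0,
                                  n_replicates=5))


class TestLabels:
    @pytest.mark.parametrize("label, node, pos", [
        ("16-4", 16, 4), ("6-1", 6, 1), ("0-1", 0, 1)])
    def test_round_trip(self, label, node, pos):
        assert parse_location(label) == (node, pos)
        assert format_location(node, pos) == label

    @pytest.mark.parametrize("label", ["16", "16-0", "-1-2", "a-b"])
    def test_malformed_labels_rejected(self, label):
        with pytest.raises(ValueError):
            parse_location(label)

    def test_duplicate_labels_within_plant_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PlantMap("A", [boll("A", 10, 1), boll("A", 10, 1)])


class TestLintMetrics:
    def test_percentage(self):
        assert lint_percentage(1.0, 4.0) == 25.0
        assert lint_percentage(0.0, 4.0) == 0.0

    def test_zero_seed_cotton_rejected(self):
        with pytest.raises(ValueError):
            lint_percentage(1.0, 0.0)

    @pytest.mark.parametrize("total, count, printed_mean", [
        (47.99, 22, 2.18),   # B-plant row of the yield summary
        (70.73, 27, 2.62),   # C-plant row
    ])
    def test_mean_lint_matches_printed_summary(self, total, count, printed_mean):
        masses = np.full(count, total / count)
        p = PlantMap("X", [boll("X", 6 + i // 5, 1 + i % 5, lint=m)
                           for i, m in enumerate(masses)])
        tot = plant_totals(p)
        assert tot["boll_number"] == count
        assert tot["total_lint"] == pytest.approx(total)
        assert round(tot["mean_lint"], 2) == printed_mean

    def test_totals_conserve_mass(self):
        rng = np.random.default_rng(9)
        masses = rng.uniform(0.8, 3.6, 27)
        p = PlantMap("C", [boll("C", 6 + i // 5, 1 + i % 5, lint=m)
                           for i, m in enumerate(masses)])
        tot = plant_totals(p)
        assert tot["total_lint"] == masses.sum()
        assert tot["mean_lint"] * tot["boll_number"] == pytest.approx(
            tot["total_lint"], abs=1e-9)

    def test_lint_pct_absent_without_seed_cotton(self):
        p = PlantMap("A", [boll("A", 6, 1, lint=1.0),
                           boll("A", 7, 1, lint=1.0, seed_cotton=4.0)])
        assert plant_totals(p)["lint_pct"] is None

    def test_lint_pct_ratio_of_totals(self):
        p = PlantMap("A", [boll("A", 6, 1, lint=1.0, seed_cotton=4.0),
                           boll("A", 7, 1, lint=2.0, seed_cotton=4.0)])
        assert plant_totals(p)["lint_pct"] == pytest.approx(100 * 3.0 / 8.0)

    def test_empty_plant_rejected(self):
        with pytest.raises(ValueError, match="no bolls"):
            plant_totals(PlantMap("A", []))


class TestLocationSeries:
    def test_by_node_at_position_ordered_ascending(self):
        p = PlantMap("A", [boll("A", 12, 1, m_ir=0.9), boll("A", 6, 1, m_ir=0.7),
                           boll("A", 9, 2, m_ir=0.8)])
        ser = location_series(p, "by_node_at_position", fixed=1)
        assert [t[0] for t in ser] == [6, 12]
        assert [t[1] for t in ser] == [0.7, 0.9]

    def test_by_position_means_with_sem(self):
        p = PlantMap("A", [boll("A", 6, 1, m_ir=0.7), boll("A", 7, 1, m_ir=0.9),
                           boll("A", 6, 2, m_ir=0.8)])
        ser = location_series(p, "by_position")
        assert len(ser) == 2
        pos1 = ser[0]
        assert pos1[1] == pytest.approx(0.8)
        assert pos1[2] == pytest.approx(np.std([0.7, 0.9], ddof=1) / math.sqrt(2))
        assert ser[1][2] is None  # single-boll position: SEM undefined

    def test_empty_selection_is_empty_series(self):
        p = PlantMap("A", [boll("A", 6, 1)])
        assert location_series(p, "by_node_at_position", fixed=4) == []


class TestCombineLocations:
    def test_across_plant_mean_and_sem(self):
        plants = [PlantMap(pid, [boll(pid, 10, 1, m_ir=m)])
                  for pid, m in zip("ABC", (0.8, 0.9, 0.7))]
        combined = combine_locations(plants)
        row = combined.set_index("location").loc["10-1"]
        assert row["mean_m_ir"] == pytest.approx(0.8)
        assert row["sem_m_ir"] == pytest.approx(0.1 / math.sqrt(3), abs=1e-4)
        assert row["n_plants"] == 3

    def test_single_plant_location_sem_undefined(self):
        plants = [PlantMap("A", [boll("A", 10, 1), boll("A", 11, 1)]),
                  PlantMap("B", [boll("B", 10, 1)])]
        combined = combine_locations(plants).set_index("location")
        assert np.isnan(combined.loc["11-1", "sem_m_ir"])
        assert combined.loc["11-1", "n_plants"] == 1

    def test_empty_plant_list_rejected(self):
        with pytest.raises(ValueError):
            combine_locations([])

    def test_combining_commutes_with_location_filtering(self):
        rng = np.random.default_rng(23)
        plants = []
        for pid in "ABC":
            bolls = [boll(pid, n, p, m_ir=rng.uniform(0.5, 1.0))
                     for n in range(6, 14) for p in (1, 2)
                     if rng.random() < 0.7]
            plants.append(PlantMap(pid, bolls))
        full = combine_locations(plants)
        filtered_after = full[full["position"] == 1].reset_index(drop=True)
        filtered_plants = [
            PlantMap(p.plant_id, [b for b in p.bolls if b.position == 1])
            for p in plants]
        filtered_before = combine_locations(
            [p for p in filtered_plants if p.bolls])
        pd.testing.assert_frame_equal(filtered_after, filtered_before)


class TestJoinConventional:
    def _combined(self, n=11):
        plants = [PlantMap("A", [boll("A", 6 + i, 1) for i in range(n)])]
        return combine_locations(plants)

    def test_inner_join_passes_conventional_through(self):
        combined = self._combined(11)
        conv = pd.DataFrame({"location": [f"{6 + i}-1" for i in range(11)],
                             "mic": np.linspace(3.5, 5.7, 11)})
        joined = join_conventional(combined, conv)
        assert len(joined) == 11
        assert np.allclose(joined["mic"], conv["mic"])

    def test_disjoint_keys_error(self):
        conv = pd.DataFrame({"location": ["30-1", "31-1", "32-1"], "mic": [4, 5, 6]})
        with pytest.raises(ValueError, match="overlapping"):
            join_conventional(self._combined(5), conv)

    def test_duplicate_conventional_key_named(self):
        conv = pd.DataFrame({"location": ["6-1", "6-1", "7-1"], "mic": [4, 5, 6]})
        with pytest.raises(ValueError, match="6-1"):
            join_conventional(self._combined(5), conv)
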