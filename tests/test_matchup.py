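"""Match-up QA pipeline: filters, time assignment, pairing, pixel purity."""

import numpy as np
import pandas as pd
import pytest

from mergedchl.matchup import (SceneGrid, SatelliteScene, assign_time,
                               build_matchups, extract_pixel, filter_records,
                               temporal_pair)


def make_scene(overpass="2011-07-01 17:30", shape=(11, 11), scene_id="s1",
               chla_value=20.0, flags=None):
    water = np.zeros(shape, dtype=bool)
    water[1:-1, 1:-1] = True
    grid = SceneGrid(shape=shape)
    return SatelliteScene(
        scene_id=scene_id, overpass_utc=pd.Timestamp(overpass, tz="UTC"),
        grid=grid, water_mask=water,
        chla={"merged": np.full(shape, chla_value)},
        flags=flags or {})


def record(lon=None, lat=None, **over):
    grid = SceneGrid(shape=(11, 11))
    if lon is None:
        lon, lat = grid.rowcol_to_lonlat(5, 5)
    base = {"site_id": "A", "latitude": float(lat), "longitude": float(lon),
            "sample_date": "2011-07-01", "sample_time": "11:30",
            "timezone_offset_h": -6.0, "depth_m": 0.5,
            "characteristic": "Chlorophyll a", "value": 20.0,
            "method_id": "EPA 445.0"}
    base.update(over)
    return base


class TestFilterRecords:
    def test_pigment_rule_rejects_other_chlorophylls(self):
        df = pd.DataFrame([record(), record(characteristic="Chlorophyll b"),
                           record(characteristic="Pheophytin a"),
                           record(characteristic="chlorophyll-a")])
        kept, tally = filter_records(df)
        assert tally["rejected_pigment"] == 2
        assert len(kept) == 2

    def test_depth_rule(self):
        df = pd.DataFrame([record(depth_m=0.5), record(depth_m=2.0),
                           record(depth_m=3.0), record(depth_m="surface"),
                           record(depth_m=None)])
        kept, tally = filter_records(df)
        assert tally["rejected_depth"] == 2  # 3 m and missing depth
        assert len(kept) == 3

    def test_nonpositive_and_unparseable_values(self):
        df = pd.DataFrame([record(value=-1.0), record(value="oops"),
                           record(value=5.0)])
        kept, tally = filter_records(df)
        assert tally["rejected_nonpositive_value"] == 2
        assert len(kept) == 1

    def test_implausible_values_flagged_not_dropped(self):
        df = pd.DataFrame([record(value=60000.0), record(value=10.0)])
        kept, tally = filter_records(df)
        assert len(kept) == 2
        assert list(kept["implausible"]) == [True, False]

    def test_constructed_survivor_count(self):
        rows = [record(depth_m=0.5) for _ in range(12)]
        rows += [record(depth_m=5.0) for _ in range(88)]
        kept, tally = filter_records(pd.DataFrame(rows))
        assert len(kept) == 12
        assert tally["input"] == 100

    def test_tallies_conserved_at_each_stage(self, record_table):
        kept, tally = filter_records(record_table)
        assert tally["input"] == (tally["rejected_pigment"]
                                  + tally["rejected_nonpositive_value"]
                                  + tally["rejected_depth"]
                                  + tally["retained"])


class TestAssignTime:
    def test_explicit_time_with_offset(self):
        df = pd.DataFrame([record(sample_time="09:30",
                                  timezone_offset_h=-5.0)])
        out, _ = assign_time(df)
        assert out["sample_utc"].iloc[0] == pd.Timestamp(
            "2011-07-01 14:30", tz="UTC")
        assert not out["time_imputed"].iloc[0]

    def test_missing_time_imputed_at_local_noon(self):
        df = pd.DataFrame([record(sample_time=None, timezone_offset_h=-6.0)])
        out, _ = assign_time(df)
        assert out["sample_utc"].iloc[0] == pd.Timestamp(
            "2011-07-01 18:00", tz="UTC")
        assert out["time_imputed"].iloc[0]

    def test_offset_derived_from_longitude_when_absent(self):
        rec = record(sample_time=None)
        rec.pop("timezone_offset_h")
        out, _ = assign_time(pd.DataFrame([rec]))
        # longitude ~ -90 deg -> offset -6 h -> noon local = 18:00 UTC
        assert out["sample_utc"].iloc[0] == pd.Timestamp(
            "2011-07-01 18:00", tz="UTC")

    def test_missing_date_rejected(self):
        df = pd.DataFrame([record(sample_date=None), record()])
        out, tally = assign_time(df)
        assert tally["rejected_missing_date"] == 1
        assert len(out) == 1


class TestTemporalPair:
    def test_within_window_is_paired(self):
        scene = make_scene("2011-07-01 16:00")
        assert temporal_pair(pd.Timestamp("2011-07-01 11:30", tz="UTC"),
                             [scene]) is scene

    def test_beyond_window_is_not_paired(self):
        scene = make_scene("2011-07-01 18:01")
        assert temporal_pair(pd.Timestamp("2011-07-01 11:30", tz="UTC"),
                             [scene]) is None

    def test_nearest_of_multiple_scenes_wins(self):
        s_plus2 = make_scene("2011-07-01 14:00", scene_id="plus2")
        s_minus5 = make_scene("2011-07-01 07:00", scene_id="minus5")
        best = temporal_pair(pd.Timestamp("2011-07-01 12:00", tz="UTC"),
                             [s_minus5, s_plus2])
        assert best.scene_id == "plus2"

    def test_tightening_window_never_adds_matches(self):
        scenes = [make_scene(f"2011-07-01 {h:02d}:00", scene_id=str(h))
                  for h in (8, 12, 20)]
        t = pd.Timestamp("2011-07-01 12:00", tz="UTC")
        wide = sum(temporal_pair(t, scenes, w) is not None
                   for w in (9.0, 6.0, 3.0, 1.0))
        counts = [temporal_pair(t, scenes, w) is not None
                  for w in (9.0, 6.0, 3.0, 1.0)]
        assert counts == sorted(counts, reverse=True) or all(counts)
        assert wide >= 1


class TestExtractPixel:
    def test_interior_pure_pixel_accepted(self):
        scene = make_scene()
        lon, lat = scene.grid.rowcol_to_lonlat(5, 5)
        hit, reason = extract_pixel(float(lon), float(lat), scene)
        assert reason is None
        assert hit["row"] == 5 and hit["col"] == 5
        assert hit["chla_merged"] == 20.0

    def test_mixed_neighbor_rejected(self):
        scene = make_scene()
        # row 3 is pure only at the very center ring; pixel (3,5) has mixed
        # neighbors at row 2 (within 2 of land border)
        lon, lat = scene.grid.rowcol_to_lonlat(3, 5)
        hit, reason = extract_pixel(float(lon), float(lat), scene)
        assert hit is None and reason == "impure_neighborhood"

    def test_cloud_flag_rejects_neighborhood(self):
        cloud = np.zeros((11, 11), dtype=bool)
        cloud[4, 4] = True
        scene = make_scene(flags={"cloud": cloud})
        lon, lat = scene.grid.rowcol_to_lonlat(5, 5)
        hit, reason = extract_pixel(float(lon), float(lat), scene)
        assert reason == "impure_neighborhood"

    def test_off_grid_rejected(self):
        scene = make_scene()
        hit, reason = extract_pixel(-80.0, 40.0, scene)
        assert reason == "off_grid"

    def test_boundary_point_uses_half_open_convention(self):
        grid = make_scene().grid
        # a point exactly on the shared edge of cols 4 and 5 belongs to col 5
        row, col = grid.xy_to_rowcol(5 * grid.pixel_size, 5.5 * grid.pixel_size)
        assert (row, col) == (5, 5)
        # just inside the lower edge still belongs to col 4
        row, col = grid.xy_to_rowcol(5 * grid.pixel_size - 1e-6,
                                     5.5 * grid.pixel_size)
        assert (row, col) == (5, 4)


class TestBuildMatchups:
    def test_fixture_survivor_count_matches_construction(
            self, record_table, demo_scene, violation_spec):
        matchups, audit = build_matchups(record_table, [demo_scene])
        assert len(matchups) == violation_spec.expected_survivors(100)

    def test_empty_scene_list_keeps_tally(self, record_table):
        matchups, audit = build_matchups(record_table, [])
        assert len(matchups) == 0
        assert audit["pairing"]["rejected_no_scene_in_window"] == \
            audit["pairing"]["input"]

    def test_duplicate_rows_are_deduplicated(self, record_table, demo_scene):
        doubled = pd.concat([record_table, record_table], ignore_index=True)
        m1, audit = build_matchups(doubled, [demo_scene])
        m2, _ = build_matchups(record_table, [demo_scene])
        assert audit["dedupe"]["dropped_duplicates"] == len(record_table)
        assert len(m1) == len(m2)

    def test_stage_tallies_conserved(self, record_table, demo_scene):
        _, audit = build_matchups(record_table, [demo_scene])
        for stage in ("filter", "time", "pairing"):
            tally = audit[stage]
            rejected = sum(v for k, v in tally.items()
                           if k.startswith("rejected_") or k.startswith("dropped"))
            assert tally["input"] == rejected + tally["retained"]

    def test_every_emitted_matchup_repasses_all_predicates(
            self, record_table, demo_scene):
        matchups, _ = build_matchups(record_table, [demo_scene])
        assert len(matchups) > 0
        pure = demo_scene.pure_water()
        for _, m in matchups.iterrows():
            # independent verifier: re-check every predicate on the output
            assert str(m["characteristic"]).lower().replace("-", " ") \
                .startswith("chlorophyll a")
            assert m["value"] > 0
            d = m["depth_m"]
            assert (isinstance(d, str) and d == "surface") or float(d) <= 2.0
            assert abs(m["time_diff_h"]) <= 6.0
            r, c = int(m["row"]), int(m["col"])
            assert pure[r - 1:r + 2, c - 1:c + 2].all()
            rr, cc = demo_scene.grid.lonlat_to_rowcol(m["longitude"],
                                                      m["latitude"])
            assert (int(rr), int(cc)) == (r, c)

    def test_filters_are_order_independent(self, record_table):
        # conjunctive predicates: the retained set is unaffected by whether
        # depth or pigment is applied first
        kept_a, _ = filter_records(record_table)
        pig_ok = record_table["characteristic"].map(
            lambda c: str(c).lower().replace("-", " ").startswith(
                "chlorophyll a"))
        depth_first = record_table[
            record_table["depth_m"].map(
                lambda d: d == "surface" or
                (not isinstance(d, str) and float(d) <= 2.0))]
        kept_b, _ = filter_records(depth_first)
        assert sorted(kept_a["site_id"]) == sorted(kept_b["site_id"])

    def test_per_pixel_averaging_collapses_colocated_records(
            self, demo_scene, truth_field):
        from mergedchl.synthetic import RecordSpec, sample_insitu_records
        gen = np.random.default_rng(3)
        recs = sample_insitu_records(demo_scene, truth_field, 40,
                                     RecordSpec(), gen)
        plain, _ = build_matchups(recs, [demo_scene])
        avg, _ = build_matchups(recs, [demo_scene], average_per_pixel=True)
        assert len(avg) == plain.groupby(["scene_id", "row", "col"]).ngroups
        assert len(avg) <= len(plain)
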