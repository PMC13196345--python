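"""Well model, normalization and replicate aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitoscreen as ms
from mitoscreen.screen import (
    InvalidMeasurementError,
    LayoutError,
    MissingReferenceError,
    ScreenFormatError,
    parse_well,
    read_normalized_csv,
)


def make_well(plate="P1", well="A1", role=ms.WellRole.TREATMENT, ratio=0.7,
              f520=100.0, tid="T1"):
    row, col = well[0], int(well[1:])
    return ms.WellMeasurement(
        plate_id=plate, row=row, col=col, role=role,
        f590=ratio * f520, f520=f520,
        treatment_id=tid if role is ms.WellRole.TREATMENT else None,
    )


class TestWellRatio:
    @pytest.mark.parametrize(
        "f590,f520,expected",
        [(0.6, 0.3, 2.0), (0.3, 0.3, 1.0), (0.52, 0.80, 0.65)],
    )
    def test_examples(self, f590, f520, expected):
        assert ms.well_ratio(f590, f520) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("f520", [0.0, -1.0])
    def test_nonpositive_green_rejected(self, f520):
        with pytest.raises(InvalidMeasurementError):
            ms.well_ratio(1.0, f520)

    def test_negative_red_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            ms.well_ratio(-0.1, 1.0)


class TestWellMeasurement:
    def test_ratio_consistent_with_channels(self):
        w = make_well(ratio=0.73, f520=113.0)
        assert math.isclose(w.ratio, w.f590 / w.f520, rel_tol=1e-9)

    def test_treatment_id_role_coupling(self):
        with pytest.raises(LayoutError):
            ms.WellMeasurement("P1", "A", 1, ms.WellRole.WT_CONTROL,
                               f590=1.0, f520=1.0, treatment_id="T1")
        with pytest.raises(LayoutError):
            ms.WellMeasurement("P1", "A", 1, ms.WellRole.TREATMENT,
                               f590=1.0, f520=1.0, treatment_id=None)

    def test_well_address_canonical(self):
        assert make_well(well="B7").well == "B7"
        assert parse_well("b7") == ("B", 7)
        with pytest.raises(ScreenFormatError):
            parse_well("Z3")


class TestNormalizePlate:
    def test_wt_reference_mean(self):
        wells = [
            make_well(well=f"A{i+1}", role=ms.WellRole.WT_CONTROL, ratio=r, tid=None)
            for i, r in enumerate([0.40, 0.50, 0.60])
        ] + [make_well(well="B1", ratio=0.35)]
        norm = ms.normalize_plate(wells)
        assert norm["B1"] == pytest.approx(0.70, rel=1e-12)

    def test_all_equal_gives_unity(self):
        wells = [
            make_well(well="A1", role=ms.WellRole.WT_CONTROL, ratio=0.5, tid=None),
            make_well(well="A2", role=ms.WellRole.WT_CONTROL, ratio=0.5, tid=None),
            make_well(well="B1", ratio=0.5),
        ]
        assert all(v == pytest.approx(1.0) for v in ms.normalize_plate(wells).values())

    def test_missing_reference_raises(self):
        with pytest.raises(MissingReferenceError):
            ms.normalize_plate([make_well()])

    def test_wt_mean_exactly_one_on_synthetic_screen(self, sirna_pipeline):
        """Per-plate mean of normalized WT wells is 1 to machine precision."""
        ds, norm = sirna_pipeline["dataset"], sirna_pipeline["normalized"]
        for plate in ds.plates:
            wt = [norm[plate.plate_id][w.well]
                  for w in plate.by_role(ms.WellRole.WT_CONTROL)]
            assert np.mean(wt) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.01, 100.0),
           ratios=st.lists(st.floats(0.1, 3.0), min_size=3, max_size=8))
    def test_scale_invariance(self, scale, ratios):
        """Multiplying every raw intensity by c > 0 leaves normalization unchanged."""
        def build(c):
            wells = [
                make_well(well=f"A{i+1}", role=ms.WellRole.WT_CONTROL,
                          ratio=r, f520=100.0 * c, tid=None)
                for i, r in enumerate(ratios[:2])
            ]
            wells += [
                make_well(well=f"B{i+1}", ratio=r, f520=80.0 * c, tid=f"T{i}")
                for i, r in enumerate(ratios[2:])
            ]
            return ms.normalize_plate(wells)
        base, scaled = build(1.0), build(scale)
        for k in base:
            assert scaled[k] == pytest.approx(base[k], rel=1e-9)


class TestAggregateReplicates:
    def _aggregate(self, reps_by_tid):
        plates = []
        for j in range(max(len(r) for r in reps_by_tid.values())):
            wells = [make_well(plate=f"P{j}", well="A1",
                               role=ms.WellRole.WT_CONTROL, ratio=1.0, tid=None),
                     make_well(plate=f"P{j}", well="A2",
                               role=ms.WellRole.WT_CONTROL, ratio=1.0, tid=None)]
            for i, (tid, reps) in enumerate(sorted(reps_by_tid.items())):
                if j < len(reps):
                    wells.append(make_well(plate=f"P{j}", well=f"B{i+1}",
                                           ratio=reps[j], tid=tid))
            plates.append(ms.Plate(f"P{j}", wells))
        ds = ms.ScreenDataset("drug", plates)
        return {v.treatment_id: v
                for v in ms.aggregate_replicates(ds, ms.normalize_screen(ds))}

    def test_duplicate_mean_and_cv(self):
        v = self._aggregate({"T1": (0.70, 0.74)})["T1"]
        assert v.aggregate == pytest.approx(0.72, rel=1e-9)
        assert v.cv_percent == pytest.approx(3.928, abs=1e-2)

    def test_identical_replicates_zero_cv(self):
        v = self._aggregate({"T1": (0.5, 0.5)})["T1"]
        assert v.aggregate == pytest.approx(0.5)
        assert v.cv_percent == 0.0

    def test_single_replicate_flagged_not_dropped(self):
        v = self._aggregate({"T1": (0.8,)})["T1"]
        assert v.aggregate == pytest.approx(0.8)
        assert v.cv_percent == 0.0
        assert v.flagged_single


class TestScreenCsv:
    def test_round_trip_preserves_values(self, tmp_path, drug_pipeline):
        ds = drug_pipeline["dataset"]
        path = tmp_path / "plates.csv"
        ms.write_screen_csv(ds, path)
        back = ms.read_screen_csv(path, "drug")
        assert back.n_treatments == ds.n_treatments
        orig = {(w.plate_id, w.well): w for p in ds.plates for w in p.wells}
        for plate in back.plates:
            for w in plate.wells:
                o = orig[(w.plate_id, w.well)]
                assert w.f590 == o.f590 and w.f520 == o.f520
                assert w.role is o.role and w.treatment_id == o.treatment_id

    def test_synthetic_screen_counts(self, drug_pipeline):
        ds = drug_pipeline["dataset"]
        assert ds.n_treatments == 1134
        assert len(ds.plates) == 26  # 13 layouts, duplicated
        assert not ds.validate_layouts()

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ScreenFormatError):
            ms.read_screen_csv(p, "drug")

    def test_duplicate_well_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "plate_id,well,role,treatment_id,f590,f520\n"
            "P1,A1,wt_control,,1.0,1.0\n"
            "P1,A1,wt_control,,1.1,1.0\n"
        )
        with pytest.raises(ScreenFormatError):
            ms.read_screen_csv(p, "drug")

    def test_inconsistent_ratio_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "plate_id,well,role,treatment_id,f590,f520,ratio\n"
            "P1,A1,wt_control,,1.0,2.0,0.9\n"
        )
        with pytest.raises(ScreenFormatError):
            ms.read_screen_csv(p, "drug", strict_layout=False)

    def test_normalized_csv_round_trip(self, tmp_path, sirna_pipeline):
        agg = sirna_pipeline["aggregated"]
        path = tmp_path / "norm.csv"
        ms.write_normalized_csv(agg, path)
        back = {v.treatment_id: v for v in read_normalized_csv(path)}
        for v in agg:
            assert back[v.treatment_id].aggregate == pytest.approx(v.aggregate, rel=1e-12)
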