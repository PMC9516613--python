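"""Dentition model, surface enumeration, and surface-CSV ingestion."""

import numpy as np
import pandas as pd
import pytest

from caripheno.dentition import (
    INDEX_TEETH,
    SubjectRecord,
    SurfaceDataError,
    SurfaceStatus,
    enumerate_index_surfaces,
    make_uniform_record,
    read_surface_csv,
    surfaces_for_tooth,
    universal_to_fdi,
    validate_subject_record,
    write_surface_csv,
)

from conftest import random_record


class TestEnumeration:
    def test_universe_has_128_surfaces_and_no_third_molars(self, universe):
        assert len(universe) == 128
        assert all(t % 10 != 8 for t, _ in universe)
        assert len(set(universe)) == 128

    def test_ordering_is_fdi_then_canonical_surface(self, universe):
        teeth = [t for t, _ in universe]
        assert teeth == sorted(teeth)
        # within tooth 46: O,M,D,B,L
        surfs_46 = [s for t, s in universe if t == 46]
        assert surfs_46 == ["O", "M", "D", "B", "L"]

    @pytest.mark.parametrize(
        "tooth,expected",
        [(11, ("M", "D", "B", "L")), (46, ("O", "M", "D", "B", "L")),
         (33, ("M", "D", "B", "L")), (25, ("O", "M", "D", "B", "L"))],
    )
    def test_surface_convention(self, tooth, expected):
        assert surfaces_for_tooth(tooth) == expected

    def test_universal_numbering_maps_to_fdi(self):
        # corners of each arch plus midline teeth
        assert universal_to_fdi(1) == 18
        assert universal_to_fdi(8) == 11
        assert universal_to_fdi(9) == 21
        assert universal_to_fdi(16) == 28
        assert universal_to_fdi(17) == 38
        assert universal_to_fdi(24) == 31
        assert universal_to_fdi(25) == 41
        assert universal_to_fdi(32) == 48
        assert sorted(universal_to_fdi(u) for u in range(1, 33)) == sorted(
            list(INDEX_TEETH) + [18, 28, 38, 48])


def _write(tmp_path, rows, header="subject_id,age,sex,tooth_fdi,surface,status"):
    path = tmp_path / "surf.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReader:
    @pytest.mark.parametrize("icdas,expected", [
        (4, SurfaceStatus.DECAYED), (3, SurfaceStatus.DECAYED),
        (2, SurfaceStatus.SOUND), (0, SurfaceStatus.SOUND),
    ])
    def test_icdas_threshold(self, tmp_path, icdas, expected):
        path = _write(tmp_path, [f"s1,30,female,16,O,{icdas}"])
        (rec,) = read_surface_csv(path, unlisted_policy="sound")
        assert rec.status(16, "O") is expected

    def test_threshold_is_monotone(self, tmp_path):
        rows = [f"s1,30,female,16,{s},{i}" for s, i in
                zip("OMDBL", [0, 2, 3, 5, 6])]
        path = _write(tmp_path, rows)
        n_decayed = []
        for thr in range(1, 7):
            (rec,) = read_surface_csv(path, icdas_threshold=thr,
                                      unlisted_policy="sound")
            n_decayed.append(sum(s is SurfaceStatus.DECAYED
                                 for s in rec.surfaces.values()))
        assert n_decayed == sorted(n_decayed, reverse=True)

    def test_missing_tooth_propagates_to_all_surfaces(self, tmp_path):
        path = _write(tmp_path, ["s1,30,female,46,M,MISSING"])
        (rec,) = read_surface_csv(path, unlisted_policy="sound")
        assert rec.is_tooth_missing(46)
        assert all(rec.status(46, s) is SurfaceStatus.MISSING_TOOTH
                   for s in "OMDBL")
        assert rec.status(45, "O") is SurfaceStatus.SOUND

    def test_third_molar_rows_are_dropped_not_rejected(self, tmp_path):
        path = _write(tmp_path, ["s1,30,female,18,O,DECAYED",
                                 "s1,30,female,16,O,DECAYED"])
        (rec,) = read_surface_csv(path, unlisted_policy="sound")
        assert rec.status(16, "O") is SurfaceStatus.DECAYED
        assert (18, "O") not in rec.surfaces

    def test_unlisted_policy_error_reports_each_uncovered_surface(self, tmp_path):
        path = _write(tmp_path, ["s1,30,female,16,O,DECAYED"])
        with pytest.raises(SurfaceDataError) as exc:
            read_surface_csv(path, unlisted_policy="error")
        assert sum(v.code == "uncovered_surface"
                   for v in exc.value.violations) == 127

    @pytest.mark.parametrize("row,code", [
        ("s1,30,female,99,O,SOUND", "malformed_tooth"),
        ("s1,30,female,11,O,SOUND", "invalid_surface"),  # no occlusal on incisor
        ("s1,30,female,16,O,7", "malformed_status"),
        ("s1,30,female,16,O,WEIRD", "malformed_status"),
    ])
    def test_distinct_error_codes(self, tmp_path, row, code):
        path = _write(tmp_path, [row])
        with pytest.raises(SurfaceDataError) as exc:
            read_surface_csv(path, unlisted_policy="sound")
        assert any(v.code == code for v in exc.value.violations)

    def test_conflicting_status_and_partial_missing_are_errors(self, tmp_path):
        path = _write(tmp_path, ["s1,30,female,16,O,DECAYED",
                                 "s1,30,female,16,O,FILLED",
                                 "s1,30,female,46,M,MISSING",
                                 "s1,30,female,46,O,SOUND"])
        with pytest.raises(SurfaceDataError) as exc:
            read_surface_csv(path, unlisted_policy="sound")
        codes = {v.code for v in exc.value.violations}
        assert "conflicting_status" in codes
        assert "partial_missing_tooth" in codes

    def test_universal_numbering_option(self, tmp_path):
        # Universal 3 is the upper-right first molar, FDI 16
        path = _write(tmp_path, ["s1,30,female,3,O,DECAYED"])
        (rec,) = read_surface_csv(path, unlisted_policy="sound",
                                  tooth_numbering="universal")
        assert rec.status(16, "O") is SurfaceStatus.DECAYED


class TestRoundTripAndValidation:
    def test_write_read_round_trip_is_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        records = [random_record(rng, f"s{i}") for i in range(5)]
        path = tmp_path / "out.csv"
        write_surface_csv(records, path)
        back = read_surface_csv(path, unlisted_policy="error")
        assert len(back) == 5
        by_id = {r.subject_id: r for r in back}
        for rec in records:
            assert by_id[rec.subject_id].surfaces == rec.surfaces

    def test_valid_record_has_empty_report(self, all_sound):
        assert validate_subject_record(all_sound) == []

    def test_partial_missing_tooth_violation(self, all_sound):
        all_sound.surfaces[(46, "O")] = SurfaceStatus.MISSING_TOOTH
        report = validate_subject_record(all_sound)
        assert [v.code for v in report] == ["partial_missing_tooth"]
        assert report[0].tooth == 46

    def test_uncovered_surfaces_counted(self, all_sound):
        for key in [(11, "M"), (24, "O"), (47, "L")]:
            del all_sound.surfaces[key]
        report = validate_subject_record(all_sound)
        assert sum(v.code == "uncovered_surface" for v in report) == 3
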