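import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macronull import (
    BandDomain,
    IncidenceMatrix,
    OccurrenceRecord,
    RangeEntry,
    derive_ranges,
    pack_matrix,
    ranges_to_incidence,
    read_covariates_csv,
    read_matrix_csv,
    read_ranges_csv,
    read_records_csv,
    records_to_incidence,
    richness_per_band,
    write_matrix_csv,
    write_ranges_csv,
)
from macronull.core_io import write_records_csv

from .conftest import random_ranges


class TestBandDomain:
    def test_band_count_and_labels(self, domain):
        assert domain.n_bands == 38
        assert domain.band_labels[0] == 18
        assert domain.band_labels[-1] == 55

    def test_south_limit_clamps_into_last_band(self, domain):
        assert domain.band_index(56.0) == 37
        assert domain.band_index(55.9) == 37
        assert domain.band_index(18.0) == 0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            BandDomain(56, 18)

    def test_latitude_outside_domain_rejected(self, domain):
        with pytest.raises(ValueError, match="outside domain"):
            domain.band_index(57.0)


class TestRangeEntry:
    def test_midpoint_and_extent(self):
        r = RangeEntry("x", 38, 41)
        assert r.midpoint == 39.5
        assert r.extent == 3

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            RangeEntry("x", 41, 38)


class TestRangesToIncidence:
    @pytest.mark.parametrize(
        "lo,hi,expected_bands",
        [
            (38, 41, [38, 39, 40, 41]),  # closed range touches 4 bands
            (55, 56, [55]),  # south edge clamps, no phantom band 56
            (56, 56, [55]),  # point range at the limit
            (20.5, 20.9, [20]),  # sub-band range occupies one band
            (20.5, 21.0, [20, 21]),  # crossing a boundary adds a band
        ],
    )
    def test_band_occupancy(self, domain, lo, hi, expected_bands):
        m = ranges_to_incidence([RangeEntry("x", lo, hi)], domain)
        occupied = list(m.col_labels[m.values[0] == 1])
        assert occupied == expected_bands

    def test_out_of_domain_names_species(self, domain):
        with pytest.raises(ValueError, match="bad_sp"):
            ranges_to_incidence([RangeEntry("bad_sp", 10, 20)], domain)

    def test_shape_for_fauna_scale_input(self, domain):
        ranges = random_ranges(84, domain, seed=5)
        m = ranges_to_incidence(ranges, domain)
        assert m.shape == (84, 38)
        assert (m.row_sums >= 1).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rows_are_contiguous_runs(self, seed):
        domain = BandDomain(18, 56)
        m = ranges_to_incidence(random_ranges(12, domain, seed), domain)
        for row in m.values:
            on = np.flatnonzero(row)
            assert len(on) >= 1
            assert on[-1] - on[0] + 1 == len(on)  # no internal gaps


class TestRecordsToIncidence:
    def test_fill_false_marks_only_record_bands(self, domain):
        recs = [OccurrenceRecord("x", 39.2), OccurrenceRecord("x", 41.7)]
        m = records_to_incidence(recs, domain, fill=False)
        assert list(m.col_labels[m.values[0] == 1]) == [39, 41]

    def test_fill_true_interval_fills(self, domain):
        recs = [OccurrenceRecord("x", 39.2), OccurrenceRecord("x", 41.7)]
        m = records_to_incidence(recs, domain, fill=True)
        assert list(m.col_labels[m.values[0] == 1]) == [39, 40, 41]

    def test_single_record_one_band_both_modes(self, domain):
        recs = [OccurrenceRecord("x", 30.4)]
        for fill in (False, True):
            m = records_to_incidence(recs, domain, fill=fill)
            assert m.row_sums.tolist() == [1]

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fill_equals_range_construction(self, seed):
        domain = BandDomain(18, 56)
        rng = np.random.default_rng(seed)
        recs = [
            OccurrenceRecord(f"s{rng.integers(4)}", float(rng.uniform(18, 56)))
            for _ in range(20)
        ]
        via_records = records_to_incidence(recs, domain, fill=True)
        via_ranges = ranges_to_incidence(derive_ranges(recs), domain)
        assert np.array_equal(via_records.values, via_ranges.values)
        assert via_records.row_labels == via_ranges.row_labels


class TestPackMatrix:
    def test_rows_sorted_by_decreasing_sum(self):
        m = IncidenceMatrix(np.array([[1, 0], [1, 1]]), ["a", "b"])
        packed = pack_matrix(m)
        assert packed.values.tolist() == [[1, 1], [1, 0]]
        assert packed.row_labels == ["b", "a"]

    def test_idempotent(self):
        m = IncidenceMatrix(np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]]), list("abc"))
        packed = pack_matrix(m)
        assert np.array_equal(packed.values, m.values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sorted_marginals_and_preserved_content(self, seed):
        rng = np.random.default_rng(seed)
        m = IncidenceMatrix(
            (rng.random((6, 6)) < 0.5).astype(int), [f"s{i}" for i in range(6)]
        )
        packed = pack_matrix(m)
        assert (np.diff(packed.row_sums) <= 0).all()
        assert (np.diff(packed.col_sums) <= 0).all()
        assert sorted(packed.row_sums) == sorted(m.row_sums)
        assert sorted(packed.col_sums) == sorted(m.col_sums)
        assert packed.values.sum() == m.values.sum()


class TestRichnessPerBand:
    def test_identity_and_full(self):
        eye = IncidenceMatrix(np.eye(3, dtype=int), list("abc"))
        assert richness_per_band(eye).tolist() == [1, 1, 1]
        ones = IncidenceMatrix(np.ones((5, 4), dtype=int), list("abcde"))
        assert richness_per_band(ones).tolist() == [5, 5, 5, 5]

    def test_matches_interval_enumeration(self, domain):
        ranges = random_ranges(30, domain, seed=11)
        m = ranges_to_incidence(ranges, domain)
        # oracle: count ranges whose closed interval intersects each band
        expected = []
        for k in domain.band_labels:
            lo_band, hi_band = k, k + 1
            n = sum(
                1
                for r in ranges
                if min(r.lat_max, domain.south_limit - 1e-12) >= lo_band
                and r.lat_min < hi_band
            )
            expected.append(n)
        assert richness_per_band(m).tolist() == expected


class TestCsvRoundTrips:
    def test_ranges_round_trip(self, tmp_path):
        ranges = random_ranges(10, BandDomain(18, 56), seed=3)
        path = tmp_path / "ranges.csv"
        write_ranges_csv(ranges, path)
        back = read_ranges_csv(path)
        assert back == ranges

    def test_signed_latitude_convention(self):
        csv = "species,lat_min,lat_max\nx,-41.0,-38.0\n"
        (entry,) = read_ranges_csv(io.StringIO(csv), signed=True)
        assert entry.lat_min == 38.0
        assert entry.lat_max == 41.0

    def test_records_round_trip(self, tmp_path):
        recs = [OccurrenceRecord("x", 39.2), OccurrenceRecord("y", 41.7)]
        path = tmp_path / "records.csv"
        write_records_csv(recs, path)
        assert read_records_csv(path) == recs

    def test_matrix_round_trip(self, tmp_path, domain):
        m = ranges_to_incidence(random_ranges(8, domain, seed=7), domain)
        path = tmp_path / "matrix.csv"
        write_matrix_csv(m, path)
        back = read_matrix_csv(path)
        assert np.array_equal(back.values, m.values)
        assert back.row_labels == m.row_labels
        assert np.array_equal(back.col_labels, m.col_labels)

    def test_malformed_row_reports_line(self):
        csv = "species,lat_min,lat_max\nx,38,41\ny,,41\n"
        with pytest.raises(ValueError, match="line.*3"):
            read_ranges_csv(io.StringIO(csv))

    def test_missing_required_column(self):
        with pytest.raises(ValueError, match="lat_max"):
            read_ranges_csv(io.StringIO("species,lat_min\nx,38\n"))

    def test_covariates_missing_band_named(self):
        dom = BandDomain(18, 21)
        csv = "band,temp\n18,1.0\n19,2.0\n"
        with pytest.raises(ValueError, match="20"):
            read_covariates_csv(io.StringIO(csv), dom)

    def test_non_binary_matrix_rejected(self):
        csv = "species,18,19\nx,1,2\n"
        with pytest.raises(ValueError, match="non-binary"):
            read_matrix_csv(io.StringIO(csv))
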