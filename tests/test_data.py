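"""Data-layer round-trips, projection semantics and the train/test split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centriodet.data import (DataError, Dataset, FieldStack, FociList,
                             max_project, read_field, read_foci, read_mask,
                             write_field, write_foci, write_mask)


@pytest.fixture()
def stack(rng):
    data = rng.integers(0, 65536, size=(4, 5, 64, 64), dtype=np.uint16)
    return FieldStack("f0", data, pixel_size_nm=102.5)


class TestFieldIO:
    def test_round_trip_identity(self, stack, tmp_path):
        path = tmp_path / "f0.ome.tif"
        write_field(stack, path)
        back = read_field(path)
        np.testing.assert_array_equal(back.intensities, stack.intensities)
        assert back.name == "f0"
        assert back.pixel_size_nm == pytest.approx(102.5)

    def test_axes_override_matches_direct_construction(self, stack, tmp_path):
        import tifffile
        permuted = np.transpose(stack.intensities, (1, 0, 2, 3))  # (z,c,y,x)
        path = tmp_path / "zcyx.tif"
        tifffile.imwrite(path, permuted, photometric="minisblack")
        back = read_field(path, axes="ZCYX")
        np.testing.assert_array_equal(back.intensities, stack.intensities)

    def test_single_z_slice(self, rng, tmp_path):
        data = rng.integers(0, 65536, size=(4, 1, 32, 32), dtype=np.uint16)
        path = tmp_path / "thin.ome.tif"
        write_field(FieldStack("thin", data), path)
        assert read_field(path).intensities.shape[1] == 1

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(DataError, match="nope.tif"):
            read_field(tmp_path / "nope.tif")


class TestMaxProject:
    def test_single_slice_is_identity(self, rng):
        data = rng.integers(0, 65536, size=(2, 1, 8, 8), dtype=np.uint16)
        proj = max_project(FieldStack("s", data))
        np.testing.assert_array_equal(proj.planes, data[:, 0])

    def test_two_slice_hand_example(self):
        z0 = [[0, 5], [7, 1]]
        z1 = [[3, 2], [6, 9]]
        data = np.array([[z0, z1]], dtype=np.uint16)
        proj = max_project(FieldStack("s", data))
        np.testing.assert_array_equal(proj.planes[0], [[3, 5], [7, 9]])

    def test_matches_loop_oracle(self, rng):
        data = rng.integers(0, 65536, size=(3, 4, 8, 8), dtype=np.uint16)
        proj = max_project(FieldStack("s", data))
        for c in range(3):
            for r in range(8):
                for k in range(8):
                    assert proj.planes[c, r, k] == max(data[c, z, r, k] for z in range(4))

    def test_idempotent_and_commutes_with_channel_selection(self, rng):
        data = rng.integers(0, 65536, size=(3, 4, 8, 8), dtype=np.uint16)
        stack = FieldStack("s", data)
        proj = max_project(stack)
        again = max_project(FieldStack("s", proj.planes[:, None]))
        np.testing.assert_array_equal(again.planes, proj.planes)
        one_channel = max_project(FieldStack("s", data[1:2]))
        np.testing.assert_array_equal(one_channel.planes[0], proj.planes[1])


class TestFociCSV:
    def test_empty_round_trip(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_foci(FociList("f", 1), path)
        assert path.read_text() == "x,y\n"
        assert len(read_foci(path)) == 0

    def test_xy_column_convention(self, tmp_path):
        # internal (row, col) = (10, 20) must serialise as "20,10"
        path = tmp_path / "pts.csv"
        write_foci(FociList("f", 1, points=[(10, 20), (30, 40)]), path)
        assert path.read_text().splitlines() == ["x,y", "20,10", "40,30"]
        back = read_foci(path)
        np.testing.assert_allclose(back.points, [(10, 20), (30, 40)])

    def test_random_round_trip_including_subpixel(self, rng, tmp_path):
        pts = rng.uniform(0, 2047, size=(1000, 2))
        pts[::3] = np.round(pts[::3])  # mix integer and sub-pixel rows
        path = tmp_path / "many.csv"
        write_foci(FociList("f", 1, points=pts), path)
        np.testing.assert_allclose(read_foci(path).points, pts, atol=0)

    @given(st.lists(st.tuples(
        st.floats(min_value=0, max_value=2047, allow_nan=False, width=32),
        st.floats(min_value=0, max_value=2047, allow_nan=False, width=32)),
        max_size=30))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_property(self, pts):
        import tempfile
        pts = np.array(pts, dtype=float).reshape(-1, 2)
        with tempfile.TemporaryDirectory() as d:
            path = f"{d}/pts.csv"
            write_foci(FociList("f", 1, points=pts), path)
            back = read_foci(path)
        np.testing.assert_allclose(back.points, pts, rtol=0, atol=1e-9)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y\n1,2\noops,3\n")
        with pytest.raises(DataError, match=r":3"):
            read_foci(path)


class TestMaskIO:
    @pytest.mark.parametrize("ext", ["png", "tif"])
    def test_round_trip(self, rng, tmp_path, ext):
        grid = rng.integers(0, 7, size=(64, 64)).astype(np.uint16)
        path = tmp_path / f"mask.{ext}"
        write_mask(grid, path)
        np.testing.assert_array_equal(read_mask(path), grid)

    def test_all_zero_mask(self, tmp_path):
        path = tmp_path / "zero.png"
        write_mask(np.zeros((16, 16), np.uint16), path)
        assert read_mask(path).max() == 0


class TestSplit:
    @staticmethod
    def _dataset(tmp_path, n_fields=25, markers=(1, 2, 3)):
        return Dataset(root=tmp_path, fields=[f"f{i:02d}" for i in range(n_fields)],
                       marker_channels=markers)

    def test_deterministic_and_disjoint(self, tmp_path):
        ds = self._dataset(tmp_path)
        train1, test1 = ds.make_split(seed=11)
        train2, test2 = ds.make_split(seed=11)
        assert (train1, test1) == (train2, test2)
        assert not {f for f, _ in train1} & {f for f, _ in test1}
        assert len(train1) + len(test1) == 25

    def test_split_sizes_90_10(self, tmp_path):
        ds = self._dataset(tmp_path, markers=(1,))
        train, test = ds.make_split(seed=3)
        assert 2 <= len(test) <= 3
        assert 22 <= len(train) <= 23

    def test_markers_evenly_represented(self, tmp_path):
        ds = self._dataset(tmp_path, n_fields=24, markers=(1, 2, 3))
        train, test = ds.make_split(seed=5)
        for items in (train, test):
            counts = {ch: sum(1 for _, c in items if c == ch) for ch in (1, 2, 3)}
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_one_channel_per_field(self, tmp_path):
        ds = self._dataset(tmp_path)
        train, test = ds.make_split(seed=1)
        fields = [f for f, _ in train + test]
        assert len(fields) == len(set(fields))

    def test_split_round_trips_through_files(self, tmp_path):
        ds = self._dataset(tmp_path)
        train, test = ds.make_split(seed=2)
        assert ds.load_split("train") == sorted(train)
        assert ds.load_split("test") == sorted(test)
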