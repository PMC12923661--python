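import numpy as np
import pytest

from tractshift.core import Grid
from tractshift.gating import (
    GateSpec,
    apply_gates,
    brain_height_mm,
    classify_drtt,
    filter_af,
)
from tractshift.tracking import StreamlineSet


def _line(*points):
    return np.asarray(points, dtype=float)


def _mask_at(grid, *voxels):
    m = np.zeros(grid.shape, dtype=bool)
    for v in voxels:
        m[v] = True
    return m


@pytest.fixture
def grid():
    return Grid((10, 10, 10), 2.0)


def _brute_force_gate(streamlines, include, exclude, grid):
    """Independent set-logic oracle: per-streamline voxel membership loops."""
    kept = []
    for s in streamlines:
        vox = np.floor(s / grid.voxel_size_mm).astype(int)
        ok = np.all((vox >= 0) & (vox < np.array(grid.shape)), axis=1)
        visited = {tuple(v) for v in vox[ok]}
        if all(any(m[v] for v in visited) for m in include.values()) and not any(
            any(m[v] for v in visited) for m in exclude.values()
        ):
            kept.append(s)
    return kept


class TestApplyGates:
    def test_streamline_through_all_includes_kept(self, grid):
        inc = {
            "a": _mask_at(grid, (1, 1, 1)),
            "b": _mask_at(grid, (5, 5, 5)),
            "c": _mask_at(grid, (8, 8, 8)),
        }
        s = _line((3, 3, 3), (11, 11, 11), (17, 17, 17))
        out = apply_gates(StreamlineSet([s]), GateSpec(include=inc), grid)
        assert len(out) == 1

    def test_streamline_touching_exclusion_removed(self, grid):
        inc = {"a": _mask_at(grid, (1, 1, 1))}
        exc = {"cc": _mask_at(grid, (5, 5, 5))}
        s = _line((3, 3, 3), (11, 11, 11))
        out = apply_gates(StreamlineSet([s]), GateSpec(include=inc, exclude=exc), grid)
        assert len(out) == 0
        assert out.meta["reconstruction_failed"]

    def test_matches_brute_force_oracle_on_random_sets(self, grid, rng):
        lines = []
        for _ in range(100):
            n = rng.integers(3, 15)
            start = rng.uniform(0, 20, 3)
            steps = rng.normal(0, 1.5, (n, 3))
            lines.append(start + np.cumsum(steps, axis=0))
        include = {f"i{k}": rng.random(grid.shape) < 0.15 for k in range(2)}
        exclude = {"x": rng.random(grid.shape) < 0.05}
        sls = StreamlineSet(lines)
        got = apply_gates(sls, GateSpec(include=include, exclude=exclude), grid)
        expected = _brute_force_gate(lines, include, exclude, grid)
        assert len(got) == len(expected)
        for a, b in zip(got, expected):
            assert np.array_equal(a, b)

    def test_idempotent(self, grid, rng):
        lines = [rng.uniform(0, 20, (8, 3)) for _ in range(40)]
        gate = GateSpec(include={"i": rng.random(grid.shape) < 0.3})
        once = apply_gates(StreamlineSet(lines), gate, grid)
        twice = apply_gates(once, gate, grid)
        assert len(once) == len(twice)
        for a, b in zip(once, twice):
            assert np.array_equal(a, b)

    def test_orientation_puts_first_roi_at_index_zero(self, grid):
        inc = {"head": _mask_at(grid, (1, 1, 1)), "tail": _mask_at(grid, (8, 8, 8))}
        forward = _line((3, 3, 3), (9, 9, 9), (17, 17, 17))
        backward = forward[::-1].copy()
        out = apply_gates(
            StreamlineSet([forward, backward]),
            GateSpec(include=inc, endpoint_rois=("head", "tail")),
            grid,
        )
        for s in out:
            assert np.linalg.norm(s[0] - 3.0) < np.linalg.norm(s[-1] - 3.0)

    def test_include_exclude_overlap_rejected(self, grid):
        m = _mask_at(grid, (1, 1, 1))
        with pytest.raises(ValueError):
            GateSpec(include={"a": m}, exclude={"a": m})


class TestClassifyDrtt:
    def _motor_masks(self, grid):
        return {
            "left": _mask_at(grid, (2, 5, 8)),
            "right": _mask_at(grid, (7, 5, 8)),
        }

    def test_decussating_bundle_all_d(self, grid):
        motor = self._motor_masks(grid)
        # dentate left, ends in right motor voxel (7,5,8) -> world ~ (15,11,17)
        lines = [_line((5, 5, 3), (9, 9, 9), (15, 11, 17)) for _ in range(10)]
        parts = classify_drtt(StreamlineSet(lines), "left", motor, grid)
        assert len(parts["d_DRTT"]) == 10
        assert len(parts["nd_DRTT"]) == 0

    def test_ipsilateral_bundle_all_nd(self, grid):
        motor = self._motor_masks(grid)
        lines = [_line((5, 5, 3), (5, 9, 9), (5, 11, 17)) for _ in range(10)]
        parts = classify_drtt(StreamlineSet(lines), "left", motor, grid)
        assert len(parts["nd_DRTT"]) == 10

    def test_mixed_set_partitions_exactly(self, grid, rng):
        motor = self._motor_masks(grid)
        d_lines = [_line((5, 5, 3), (15, 11, 17)) for _ in range(50)]
        nd_lines = [_line((5, 5, 3), (5, 11, 17)) for _ in range(50)]
        lines = d_lines + nd_lines
        labels = ["d"] * 50 + ["nd"] * 50
        order = rng.permutation(100)
        shuffled = [lines[i] for i in order]
        parts = classify_drtt(StreamlineSet(shuffled), "left", motor, grid)
        assert len(parts["d_DRTT"]) == 50
        assert len(parts["nd_DRTT"]) == 50
        total = sum(len(p) for p in parts.values())
        assert total == 100

    def test_unclassified_bucket(self, grid):
        motor = self._motor_masks(grid)
        lines = [_line((5, 5, 3), (12, 3, 3))]  # ends in neither motor mask
        parts = classify_drtt(StreamlineSet(lines), "left", motor, grid)
        assert len(parts["unclassified"]) == 1

    def test_invalid_side_rejected(self, grid):
        with pytest.raises(ValueError):
            classify_drtt(StreamlineSet([]), "up", self._motor_masks(grid), grid)


class TestFilterAf:
    def _set_of_lengths(self, lengths):
        return StreamlineSet(
            [np.column_stack([np.zeros(2), np.zeros(2), [0.0, l]]) for l in lengths]
        )

    def test_identical_subjects_nothing_removed(self):
        sets = {f"s{i}": self._set_of_lengths([100.0] * 5) for i in range(10)}
        heights = {f"s{i}": 150.0 for i in range(10)}
        out, thr = filter_af(sets, heights)
        assert thr == pytest.approx(100.0 / 150.0)
        assert all(len(v) == 5 for v in out.values())

    def test_percentile_linear_interpolation(self):
        # 101 medians 1.00 .. 2.00 -> first percentile exactly 1.01
        sets = {f"s{i}": self._set_of_lengths([1.0 + i / 100]) for i in range(101)}
        heights = {f"s{i}": 1.0 for i in range(101)}
        _, thr = filter_af(sets, heights)
        assert thr == pytest.approx(1.01)

    def test_spurious_short_streamlines_removed(self, rng):
        # tracked tract lengths pile up at the full bundle length with an
        # upper-side spread (longer wandering paths); spurious fragments sit
        # far below at ~0.2x. The subject's median is the full length, so
        # the cohort percentile threshold separates the two cleanly.
        sets, heights = {}, {}
        for i in range(20):
            h = rng.uniform(140.0, 160.0)
            full = 0.80 * h
            genuine = [full] * 32 + list(full + rng.uniform(0, 6, 13))
            spurious = list(0.16 * h + rng.normal(0, 2, 5))  # 10% at ~0.2x
            sets[f"s{i}"] = self._set_of_lengths(genuine + spurious)
            heights[f"s{i}"] = h
        out, thr = filter_af(sets, heights)
        kept_norm = np.concatenate(
            [o.lengths_mm / heights[k] for k, o in out.items()]
        )
        n_spurious_kept = int((kept_norm < 0.5).sum())
        n_genuine_kept = int((kept_norm >= 0.5).sum())
        assert n_spurious_kept <= 0.05 * 100  # >= 95% of spurious removed
        assert n_genuine_kept >= 0.99 * 900  # <= 1% of genuine removed

    def test_filter_monotone_in_percentile(self, rng):
        sets = {
            f"s{i}": self._set_of_lengths(rng.uniform(50, 150, 30)) for i in range(12)
        }
        heights = {f"s{i}": 150.0 for i in range(12)}
        kept = []
        for pct in (1.0, 5.0, 25.0, 50.0):
            out, _ = filter_af(sets, heights, percentile=pct)
            kept.append(sum(len(v) for v in out.values()))
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_single_subject_passthrough(self):
        sets = {"s0": self._set_of_lengths([10.0, 100.0])}
        out, thr = filter_af(sets, {"s0": 150.0})
        assert len(out["s0"]) == 2 and thr == 0.0

    def test_zero_brain_height_rejected(self):
        with pytest.raises(ValueError):
            filter_af({"s0": self._set_of_lengths([10.0])}, {"s0": 0.0})


def test_brain_height_feet_head_extent():
    grid = Grid((4, 4, 10), 2.5)
    mask = np.zeros(grid.shape, bool)
    mask[1, 1, 2:7] = True
    assert brain_height_mm(mask, grid) == pytest.approx(5 * 2.5)
    with pytest.raises(ValueError):
        brain_height_mm(np.zeros(grid.shape, bool), grid)
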