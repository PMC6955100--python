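import numpy as np
import pytest

from arborstat.model import Point3, Segment
from arborstat.sholl import (
    ShollConfig,
    ShollProfile,
    aggregate_range,
    common_grid,
    segment_sphere_crossings,
    sholl_profile,
    sholl_profile_sampled,
)

from conftest import build_tree, random_tree

ORIGIN = Point3(0, 0, 0)


def seg(a, b):
    return Segment(Point3.of(a), Point3.of(b), True)


class TestSegmentSphereCrossings:
    def test_radial_ray_crosses_once(self):
        assert segment_sphere_crossings(seg((0, 0, 0), (100, 0, 0)), ORIGIN, 30) == 1

    def test_chord_enters_and_leaves(self):
        # endpoints at sqrt(1025) ~ 32 > 30 outside, closest approach 25 < 30
        assert segment_sphere_crossings(seg((25, -20, 0), (25, 20, 0)), ORIGIN, 30) == 2

    def test_tangent_counts_zero_by_default(self):
        assert segment_sphere_crossings(seg((30, -10, 0), (30, 10, 0)), ORIGIN, 30) == 0

    def test_tangent_counts_one_when_enabled(self):
        assert segment_sphere_crossings(seg((30, -10, 0), (30, 10, 0)), ORIGIN, 30,
                                        tangency_counts=True) == 1

    def test_fully_inside_and_fully_outside_are_zero(self):
        assert segment_sphere_crossings(seg((1, 0, 0), (0, 2, 0)), ORIGIN, 30) == 0
        assert segment_sphere_crossings(seg((100, 0, 0), (0, 100, 0)), ORIGIN, 30) == 0

    def test_endpoint_on_sphere_attributed_to_one_segment(self):
        # node exactly on the shell shared by two consecutive segments:
        # outgoing segment starts at t=0 (counted), incoming ends at t=1 (not)
        inward = seg((20, 0, 0), (30, 0, 0))
        outward = seg((30, 0, 0), (40, 0, 0))
        total = (segment_sphere_crossings(inward, ORIGIN, 30)
                 + segment_sphere_crossings(outward, ORIGIN, 30))
        assert total == 1

    def test_degenerate_segment_warns_and_counts_zero(self, caplog):
        with caplog.at_level("WARNING"):
            n = segment_sphere_crossings(seg((5, 5, 5), (5, 5, 5)), ORIGIN, 30)
        assert n == 0
        assert "degenerate" in caplog.text

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            segment_sphere_crossings(seg((0, 0, 0), (1, 0, 0)), ORIGIN, 0)


class TestShollProfile:
    def test_straight_radial_dendrite(self):
        rows = [(1, None, (0.0, 0.0, 0.0))]
        rows += [(i, i - 1, (10.0 * (i - 1), 0.0, 0.0)) for i in range(2, 12)]
        # farthest node at 100 µm -> outermost shell is the next multiple, 120
        prof = sholl_profile(build_tree(rows), ShollConfig(step_um=30))
        assert prof.radii_um == (30.0, 60.0, 90.0, 120.0)
        assert prof.intersections == (1, 1, 1, 0)

    def test_fixed_max_radius_pads_with_zeros(self):
        tree = build_tree([(1, None, (0, 0, 0)), (2, 1, (50, 0, 0))])
        prof = sholl_profile(tree, ShollConfig(step_um=30, max_radius_um=120))
        assert prof.radii_um == (30.0, 60.0, 90.0, 120.0)
        assert prof.intersections == (1, 0, 0, 0)

    def test_known_radial_layout(self):
        # one stem to radius 40, two children out to radius 70:
        # N(30)=1 stem crossing, N(60)=2 child crossings
        tree = build_tree([
            (1, None, (0, 0, 0)),
            (2, 1, (40, 0, 0)),
            (3, 2, (70, 10, 0)),
            (4, 2, (70, -10, 0)),
        ])
        prof = sholl_profile(tree, ShollConfig(step_um=30))
        assert prof.intersections[:2] == (1, 2)

    def test_soma_only_profile_is_empty(self):
        prof = sholl_profile(build_tree([(1, None, (0, 0, 0))]))
        assert prof.radii_um == ()

    def test_profile_centered_on_soma_not_origin(self):
        tree = build_tree([(1, None, (1000, 0, 0)), (2, 1, (1050, 0, 0))])
        prof = sholl_profile(tree, ShollConfig(step_um=30))
        assert prof.radii_um == (30.0, 60.0)
        assert prof.intersections == (1, 0)

    def test_matches_dense_sampling_oracle_on_random_trees(self):
        for seed in range(25):
            tree = random_tree(seed)
            exact = sholl_profile(tree)
            sampled = sholl_profile_sampled(tree, sample_um=0.01)
            assert exact.intersections == sampled.intersections

    def test_rotation_about_soma_preserves_profile(self, rng):
        from scipy.spatial.transform import Rotation
        from arborstat.model import NeuronTree

        tree = random_tree(42)
        _, pos, par = tree.as_arrays()
        center = pos[par < 0][0]
        R = Rotation.random(rng=rng).as_matrix()
        rotated = NeuronTree.from_arrays((pos - center) @ R.T + center, par)
        assert sholl_profile(rotated).intersections == sholl_profile(tree).intersections

    def test_monotone_outward_path_crosses_each_shell_at_most_once(self):
        for seed in range(10):
            tree = random_tree(seed, n_stems=1, branch_prob=0.0, angle_spread_deg=10.0)
            prof = sholl_profile(tree)
            assert all(c in (0, 1) for c in prof.intersections)

    def test_total_crossings_bounded(self):
        tree = random_tree(9)
        prof = sholl_profile(tree)
        n_segments = len(tree) - 1
        assert sum(prof.intersections) <= 2 * n_segments * len(prof.radii_um)


class TestAggregateRange:
    def make_profile(self):
        return ShollProfile((30.0, 60.0, 90.0), (1, 1, 1))

    def test_full_range(self):
        assert aggregate_range(self.make_profile(), 30, 90) == 3

    def test_single_shell(self):
        assert aggregate_range(self.make_profile(), 60, 60) == 1

    def test_snaps_outward_with_warning(self):
        # [40, 70] grows outward to [30, 90], covering all three shells
        with pytest.warns(UserWarning, match="snapped"):
            assert aggregate_range(self.make_profile(), 40, 70) == 3

    def test_empty_range_returns_zero_with_warning(self):
        prof = self.make_profile()
        with pytest.warns(UserWarning, match="no shells"):
            assert aggregate_range(prof, 120, 150) == 0

    def test_matches_filter_and_sum_oracle(self, rng):
        for _ in range(20):
            counts = tuple(int(c) for c in rng.integers(0, 10, size=8))
            radii = tuple(30.0 * (i + 1) for i in range(8))
            prof = ShollProfile(radii, counts)
            lo, hi = sorted(30.0 * rng.integers(1, 9, size=2))
            expected = sum(c for r, c in zip(radii, counts) if lo <= r <= hi)
            assert aggregate_range(prof, lo, hi) == expected


def test_common_grid_takes_longest():
    p1 = ShollProfile((30.0, 60.0), (1, 2))
    p2 = ShollProfile((30.0, 60.0, 90.0), (1, 2, 3))
    grid = common_grid([p1, p2])
    assert grid == (30.0, 60.0, 90.0)
    assert p1.padded(grid).intersections == (1, 2, 0)


def test_mixed_steps_rejected():
    with pytest.raises(ValueError):
        common_grid([ShollProfile((30.0,), (1,)), ShollProfile((25.0,), (1,))])


class TestCrossingPropertyBased:
    from hypothesis import assume, given, settings
    from hypothesis import strategies as st

    coord = st.floats(-120, 120, allow_nan=False, allow_infinity=False)

    @staticmethod
    def _sign_change_oracle(a, b, r, n=20000):
        """Count sign changes of |p(t)| - r along a dense sample of t."""
        t = np.linspace(0.0, 1.0, n)
        pts = np.asarray(a)[None, :] + t[:, None] * (np.asarray(b) - np.asarray(a))
        s = np.sign(np.linalg.norm(pts, axis=1) - r)
        return int(np.sum(s[:-1] * s[1:] < 0))

    @given(ax=coord, ay=coord, az=coord, bx=coord, by=coord, bz=coord,
           r=st.floats(5, 150))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_exact_crossings_equal_sign_changes(self, ax, ay, az, bx, by, bz, r):
        from hypothesis import assume

        a, b = np.array([ax, ay, az]), np.array([bx, by, bz])
        assume(np.linalg.norm(b - a) > 1e-6)
        # keep clear of measure-zero events the discrete oracle cannot decide
        assume(abs(np.linalg.norm(a) - r) > 1e-3)
        assume(abs(np.linalg.norm(b) - r) > 1e-3)
        d = b - a
        t_star = float(np.clip(-np.dot(a, d) / np.dot(d, d), 0.0, 1.0))
        assume(abs(np.linalg.norm(a + t_star * d) - r) > 1e-3)
        n = segment_sphere_crossings(seg(tuple(a), tuple(b)), ORIGIN, r)
        assert n == self._sign_change_oracle(a, b, r)


def test_config_validation():
    with pytest.raises(ValueError):
        ShollConfig(step_um=0)
    with pytest.raises(ValueError):
        ShollConfig(step_um=30, max_radius_um=10)
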