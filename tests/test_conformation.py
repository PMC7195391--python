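"""Gating descriptors and the kinked/bent classifier."""

import numpy as np
import pytest

from kinkgate import conformation as conf
from kinkgate.synthetic import SyntheticSpec, generate, simulate_state_dynamics
from kinkgate.trajectory_io import FrameSeries

from conftest import build_topology, make_frames, tetramer_points


def _hbond_fixture(d_by_subunit, box=(10.0, 10.0, 9.2)):
    """4 subunits, each with Val81 O at a corner and Gly85 H offset in z."""
    rows, coords = [], []
    corners = [(1, 1), (1, 8), (8, 8), (8, 1)]
    for sub, (x, y) in zip("ABCD", corners):
        rows += [("O", "VAL", 81, sub), ("H", "GLY", 85, sub)]
        coords += [[x, y, 3.0], [x, y, 3.0 + d_by_subunit[sub]]]
    return build_topology(rows), make_frames(coords, box=box)


class TestHbondDistance:
    def test_plain_distance(self):
        topo, frames = _hbond_fixture({s: 0.2 for s in "ABCD"})
        d = conf.hbond_distance(frames, topo)
        assert d == pytest.approx(np.full((1, 4), 0.2))

    def test_minimum_image_across_boundary(self):
        rows = []
        coords = []
        corners = [(1, 1), (1, 8), (8, 8), (8, 1)]
        for sub, (x, y) in zip("ABCD", corners):
            rows += [("O", "VAL", 81, sub), ("H", "GLY", 85, sub)]
            coords += [[x, y, 0.1], [x, y, 9.2 - 0.05]]
        topo = build_topology(rows)
        frames = make_frames(coords, box=(10, 10, 9.2))
        d = conf.hbond_distance(frames, topo)
        assert d == pytest.approx(np.full((1, 4), 0.15))

    def test_integer_box_translation_leaves_value(self):
        topo, frames = _hbond_fixture({s: 0.3 for s in "ABCD"})
        moved = frames.coordinates.copy()
        moved[0, 1, :] += np.array([10.0, -20.0, 9.2 * 3])  # one H atom
        frames2 = make_frames(moved, box=(10, 10, 9.2))
        assert conf.hbond_distance(frames2, topo) == pytest.approx(
            conf.hbond_distance(frames, topo)
        )

    def test_missing_hydrogen_message_and_fallback(self):
        rows, coords = [], []
        for sub, x in zip("ABCD", (1, 3, 5, 7)):
            rows += [("O", "VAL", 81, sub), ("N", "GLY", 85, sub)]
            coords += [[x, 1, 3.0], [x, 1, 3.5]]
        topo = build_topology(rows)
        frames = make_frames(coords)
        with pytest.raises(ValueError, match="use_nitrogen"):
            conf.hbond_distance(frames, topo)
        d = conf.hbond_distance(frames, topo, use_nitrogen=True)
        assert d == pytest.approx(np.full((1, 4), 0.5))

    def test_planted_kinked_value_recovered(self, default_system):
        topo, frames, truth = default_system
        d = conf.hbond_distance(frames, topo)
        kinked = d[truth.states == 0]
        assert kinked.mean() == pytest.approx(0.55, abs=0.02)
        assert d[truth.states == 1].mean() == pytest.approx(0.20, abs=0.02)


def _helix_fixture(theta_deg):
    """Two 8-residue straight segments per subunit subtending theta."""
    rows, coords = [], []
    t = np.deg2rad(theta_deg)
    u1 = np.array([0.0, 0.0, 1.0])
    u2 = np.array([np.sin(t), 0.0, np.cos(t)])
    for sub, x0 in zip("ABCD", (1.0, 3.0, 5.0, 7.0)):
        origin = np.array([x0, 5.0, 2.0])
        for i in range(71, 99):
            rows.append(("CA", "ALA", i, sub))
            if i < 83:
                coords.append(origin + 0.15 * (i - 71) * u1)
            elif i == 83:
                coords.append(origin + 0.15 * 12 * u1)
            else:
                coords.append(origin + 0.15 * 12 * u1 + 0.15 * (i - 83) * u2)
    return build_topology(rows), make_frames(coords)


class TestBendingAngle:
    def test_collinear_gives_zero(self):
        topo, frames = _helix_fixture(0.0)
        assert conf.bending_angle(frames, topo) == pytest.approx(
            np.zeros((1, 4)), abs=1e-6
        )

    def test_constructed_43_degrees(self):
        topo, frames = _helix_fixture(43.0)
        assert conf.bending_angle(frames, topo) == pytest.approx(
            np.full((1, 4), 43.0), abs=1.0
        )

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        topo, frames = _helix_fixture(37.0)
        ref = conf.bending_angle(frames, topo)
        rng = np.random.default_rng(5)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-3, 3, 3)
            moved = frames.coordinates[0] @ R.T + t
            assert conf.bending_angle(make_frames(moved), topo) == pytest.approx(
                ref, abs=1e-6
            )

    def test_planted_state_angles(self, default_system):
        topo, frames, truth = default_system
        theta = conf.bending_angle(frames, topo)
        assert theta[truth.states == 0].mean() == pytest.approx(43.0, abs=1.0)
        assert theta[truth.states == 1].mean() == pytest.approx(30.0, abs=1.0)


class TestClassifyState:
    def test_constant_series(self):
        assert conf.classify_state(np.full((10, 4), 0.20)).f_bent == 1.0
        assert conf.classify_state(np.full((10, 4), 0.55)).f_bent == 0.0

    def test_one_permanently_bent_subunit_is_25_percent(self):
        d = np.full((50, 4), 0.55)
        d[:, 2] = 0.20
        trace = conf.classify_state(d)
        assert trace.f_bent == 0.25
        assert np.all(trace.n_bent_config == 1)

    def test_hysteresis_trace(self):
        d = np.array([0.20, 0.35, 0.55, 0.35])[:, None]
        labels = conf.classify_state(d).labels[:, 0]
        assert labels.tolist() == [conf.BENT, conf.BENT, conf.KINKED, conf.KINKED]

    def test_first_frame_in_band_takes_nearer_threshold(self):
        # 0.30 is nearer t_low=0.27 than t_high=0.45 -> bent; 0.40 -> kinked
        assert conf.classify_state(np.array([[0.30]])).labels[0, 0] == conf.BENT
        assert conf.classify_state(np.array([[0.40]])).labels[0, 0] == conf.KINKED
        # exact midpoint (representable in binary) ties to kinked
        mid = np.array([[0.5]])
        assert (
            conf.classify_state(mid, t_low=0.25, t_high=0.75).labels[0, 0]
            == conf.KINKED
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            conf.classify_state(np.array([[0.3, np.nan]]))

    def test_single_threshold_mode(self):
        d = np.array([0.20, 0.35, 0.55])[:, None]
        labels = conf.classify_state(d, hysteresis=False).labels[:, 0]
        assert labels.tolist() == [conf.BENT, conf.BENT, conf.KINKED]

    @pytest.mark.parametrize("f_target", [0.5, 0.30, 0.03])
    def test_stationary_fraction_recovered(self, f_target):
        """Time-average of a stationary two-state chain matches the planted
        fraction within the autocorrelation-aware sampling error."""
        k_tot = 0.05
        spec = SyntheticSpec(
            n_frames=20000, seed=int(f_target * 1000),
            k_kb=k_tot * f_target, k_bk=k_tot * (1 - f_target),
        )
        states = simulate_state_dynamics(spec)
        f_hat = states.mean()
        T = spec.n_frames * spec.dt
        var = 2 * f_target * (1 - f_target) / (k_tot * T) / 4  # 4 chains
        assert abs(f_hat - f_target) <= 3 * np.sqrt(var) + 1e-9

    def test_label_accuracy_on_planted_chain(self, default_system):
        """Templates are separated by far more than 5 sigma of the noise, so
        per-frame labels must match the planted chain >= 99%."""
        topo, frames, truth = default_system
        d = conf.hbond_distance(frames, topo)
        trace = conf.classify_state(d)
        acc = (trace.labels == truth.states).mean()
        assert acc >= 0.99


class TestCrossSubunitDistance:
    def _square(self, side=0.36):
        pts = [
            ("CA", "PRO", 19, (1.0, 1.0, 5.0)),
            ("CA", "PRO", 19, (1.0 + side, 1.0, 5.0)),
            ("CA", "PRO", 19, (1.0 + side, 1.0 + side, 5.0)),
            ("CA", "PRO", 19, (1.0, 1.0 + side, 5.0)),
        ]
        rows = [(n, rn, ri) for n, rn, ri, _ in pts]
        topo, coords = tetramer_points(pts)
        return topo, make_frames(coords)

    def test_square_diagonal(self):
        topo, frames = self._square()
        d = conf.cross_subunit_distance(frames, topo, "resid 19 and name CA")
        assert d == pytest.approx([0.36 * np.sqrt(2)], abs=1e-9)

    def test_square_all_pairs(self):
        topo, frames = self._square()
        d = conf.cross_subunit_distance(
            frames, topo, "resid 19 and name CA", pairing="all_pairs"
        )
        expected = (4 * 0.36 + 2 * 0.36 * np.sqrt(2)) / 6
        assert d == pytest.approx([expected], abs=1e-9)

    def test_requires_tetramer(self):
        rows = [("CA", "PRO", 19, "A"), ("CA", "PRO", 19, "B")]
        topo = build_topology(rows)
        frames = make_frames([[1, 1, 1], [2, 2, 2]])
        with pytest.raises(ValueError):
            conf.cross_subunit_distance(frames, topo, "resid 19 and name CA")

    def test_planted_all_bent_og_ring(self):
        """All-bent restrained system plants the 0.533 nm filter-gate value."""
        topo, frames, _ = generate(
            SyntheticSpec(n_frames=300, seed=9, fixed_states="bent")
        )
        d = conf.cross_subunit_distance(frames, topo, "resid 59 and name OG1")
        assert d.mean() == pytest.approx(0.533, abs=0.005)


class TestSidechainCOM:
    def test_single_atom_sidechains(self):
        rows = []
        coords = []
        for sub, x in zip("ABCD", (1.0, 3.0, 5.0, 7.0)):
            rows += [("CB", "ILE", 84, sub), ("CB", "THR", 59, sub)]
            coords += [[x, 1, 2.0], [x, 1, 2.54]]
        topo = build_topology(rows)
        d = conf.sidechain_com_distance(make_frames(coords), topo)
        assert d == pytest.approx(np.full((1, 4), 0.54))

    def test_identical_coms_give_zero(self):
        rows, coords = [], []
        for sub, x in zip("ABCD", (1.0, 3.0, 5.0, 7.0)):
            rows += [("CB", "ILE", 84, sub), ("CB", "THR", 59, sub)]
            coords += [[x, 1, 2.0], [x, 1, 2.0]]
        topo = build_topology(rows)
        d = conf.sidechain_com_distance(make_frames(coords), topo)
        assert d == pytest.approx(np.zeros((1, 4)))

    def test_glycine_has_no_sidechain(self):
        rows, coords = [], []
        for sub, x in zip("ABCD", (1.0, 3.0, 5.0, 7.0)):
            rows += [("CA", "GLY", 83, sub), ("CB", "THR", 59, sub)]
            coords += [[x, 1, 2.0], [x, 1, 2.5]]
        topo = build_topology(rows)
        with pytest.raises(ValueError, match="[Gg]lycine|side"):
            conf.sidechain_com_distance(make_frames(coords), topo, 83, 59)

    def test_planted_two_state_means(self, default_system):
        topo, frames, truth = default_system
        d = conf.sidechain_com_distance(frames, topo)
        assert d[truth.states == 0].mean() == pytest.approx(0.54, abs=0.01)
        assert d[truth.states == 1].mean() == pytest.approx(0.59, abs=0.01)


class TestComRing:
    def test_circle_gives_diameter(self):
        pts = []
        r = 0.7
        for ang in (0, 90, 180, 270):
            a = np.deg2rad(ang)
            pts.append(
                ("CB", "ILE", 84, (4 + r * np.cos(a), 4 + r * np.sin(a), 3.0))
            )
        topo, coords = tetramer_points(pts)
        d = conf.com_ring_distance(make_frames(coords), topo)
        assert d == pytest.approx([2 * r], abs=1e-9)

    def test_coincident_coms_give_zero(self):
        pts = [("CB", "ILE", 84, (4.0, 4.0, 3.0)) for _ in range(4)]
        topo, coords = tetramer_points(pts)
        assert conf.com_ring_distance(make_frames(coords), topo) == pytest.approx([0.0])

    def test_planted_restrained_ring(self):
        """Ile84 ring restrained at radius 0.825 nm reads out as 1.65 nm."""
        topo, frames, _ = generate(
            SyntheticSpec(n_frames=100, seed=2, ile84_ring_radius=0.825)
        )
        d = conf.com_ring_distance(frames, topo)
        assert d.mean() == pytest.approx(1.65, abs=0.01)


class TestPheCoF:
    def _fixture(self, radius):
        rows, coords = [], []
        for sub, ang in zip("ABCD", (0, 90, 180, 270)):
            a = np.deg2rad(ang)
            rows.append(("CA", "PHE", 87, sub))
            coords.append([4 + 0.3 * np.cos(a), 4 + 0.3 * np.sin(a), 3.0])
            rows.append(("CB", "PHE", 87, sub))
            coords.append([4 + radius * np.cos(a), 4 + radius * np.sin(a), 3.0])
        return build_topology(rows), make_frames(coords)

    def test_radius_recovered(self):
        topo, frames = self._fixture(0.8)
        assert conf.phe87_cof_distance(frames, topo) == pytest.approx(
            np.full((1, 4), 0.8)
        )

    def test_sidechain_at_center_gives_zero(self):
        topo, frames = self._fixture(0.0)
        assert conf.phe87_cof_distance(frames, topo) == pytest.approx(
            np.zeros((1, 4)), abs=1e-9
        )

    def test_planted_orientation_by_state(self, default_system):
        topo, frames, truth = default_system
        d = conf.phe87_cof_distance(frames, topo)
        assert d[truth.states == 0].mean() == pytest.approx(0.836, abs=0.01)
        assert d[truth.states == 1].mean() == pytest.approx(0.666, abs=0.01)


class TestHistogram2D:
    def test_single_bin(self):
        grid, _, _ = conf.histogram2d([1.0] * 7, [2.0] * 7, bins=(
            np.array([0, 2.0]), np.array([0, 4.0])))
        assert grid.sum() == 7
        assert (grid > 0).sum() == 1

    def test_normalization_and_nan_filtering(self):
        x = [1.0, 1.0, np.nan, 2.0]
        y = [1.0, 2.0, 1.0, np.nan]
        grid, _, _ = conf.histogram2d(x, y, bins=5, normalize=True)
        assert grid.sum() == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            conf.histogram2d([1, 2], [1], bins=3)

    def test_two_state_mixture_shows_two_modes(self, default_system):
        topo, frames, _ = default_system
        from kinkgate.conformation import compute_descriptors

        desc = compute_descriptors(frames, topo)
        theta = np.asarray(desc.theta).ravel()
        d_vg = np.asarray(desc.d_vg).ravel()
        grid, xe, ye = conf.histogram2d(
            theta, d_vg,
            bins=(np.arange(25, 50, 1.0), np.arange(0.1, 0.7, 0.02)),
            normalize=True,
        )

        def mass(theta_win, d_win):
            xm = (xe[:-1] >= theta_win[0]) & (xe[1:] <= theta_win[1])
            ym = (ye[:-1] >= d_win[0]) & (ye[1:] <= d_win[1])
            return grid[np.ix_(xm, ym)].sum()

        kinked = mass((40, 46), (0.48, 0.62))
        bent = mass((27, 33), (0.14, 0.26))
        assert kinked > 0.5  # planted mixture is ~70% kinked
        assert bent > 0.15  # and ~30% bent
        assert kinked + bent > 0.9  # essentially all mass in the two modes
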