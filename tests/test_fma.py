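"""Superposition and PLS functional mode analysis."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinkgate import fma
from kinkgate.conformation import bending_angle
from kinkgate.synthetic import SyntheticSpec, generate
from kinkgate.trajectory_io import select

from conftest import build_topology, make_frames


def _cloud_topology(n=12):
    rows = [("CA", "ALA", i + 1, "A") for i in range(n)]
    return build_topology(rows)


def _quaternion_fit_rmsd(P, Q):
    """Independent oracle: Horn's quaternion method for the optimal
    superposition RMSD of centred point sets."""
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P**2) + np.sum(Q**2) - 2 * lam) / len(P)
    return np.sqrt(max(msd, 0.0))


class TestSuperpose:
    def test_rotated_copy_aligns_exactly(self):
        rng = np.random.default_rng(0)
        topo = _cloud_topology()
        ref = rng.uniform(0, 3, (12, 3))
        R = Rotation.random(rng=rng).as_matrix()
        moved = ref @ R.T + np.array([1.0, -2.0, 0.5])
        frames = make_frames(np.stack([ref, moved]))
        out = fma.superpose(frames, topo, fit_expr="name CA")
        rmsd = np.sqrt(((out.coordinates[1] - ref) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-6

    def test_identity_input_unchanged(self):
        rng = np.random.default_rng(1)
        topo = _cloud_topology()
        ref = rng.uniform(0, 3, (12, 3))
        frames = make_frames(np.stack([ref, ref]))
        out = fma.superpose(frames, topo)
        assert out.coordinates[1] == pytest.approx(ref, abs=1e-12)

    def test_matches_quaternion_oracle_under_noise(self):
        rng = np.random.default_rng(2)
        topo = _cloud_topology()
        ref = rng.uniform(0, 3, (12, 3))
        frames_list = [ref]
        for _ in range(6):
            R = Rotation.random(rng=rng).as_matrix()
            frames_list.append(ref @ R.T + rng.uniform(-2, 2, 3)
                               + rng.normal(0, 0.05, (12, 3)))
        frames = make_frames(np.stack(frames_list))
        out = fma.superpose(frames, topo)
        ref_c = ref - ref.mean(axis=0)
        for f in range(1, 7):
            got = np.sqrt(((out.coordinates[f] - ref) ** 2).sum(axis=1).mean())
            mob = frames.coordinates[f]
            want = _quaternion_fit_rmsd(mob - mob.mean(axis=0), ref_c)
            assert got == pytest.approx(want, abs=1e-9)

    def test_collinear_selection_rejected(self):
        topo = _cloud_topology(5)
        line = np.stack([np.array([0, 0, 0.3 * i]) for i in range(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            fma.superpose(make_frames(np.stack([line, line])), topo)


class TestFitFMA:
    def test_exact_linear_order_parameter(self):
        # a noise-free linear target is fitted exactly once the latent space
        # spans the coordinates; the mode is the planted coordinate
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (400, 9))
        y = 3.0 * X[:, 4]
        m = fma.fit_fma(X, y, n_components=9)
        assert m.r_valid == pytest.approx(1.0, abs=1e-6)
        e = np.zeros(9)
        e[4] = 1.0
        assert abs(np.dot(m.mode, e)) > 0.999

    def test_independent_noise_gives_no_correlation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (500, 30))
        y = rng.normal(0, 1, 500)
        m = fma.fit_fma(X, y, n_components=1)
        assert abs(m.r_valid) < 0.2

    def test_planted_mode_recovery_at_snr5(self):
        rng = np.random.default_rng(5)
        n, p = 600, 60
        mode = rng.normal(0, 1, p)
        mode /= np.linalg.norm(mode)
        t = rng.normal(0, 1, n)
        X = np.outer(t, mode) + rng.normal(0, 1 / 5, (n, p))
        y = t
        m = fma.fit_fma(X, y, n_components=1)
        assert abs(np.dot(m.mode, mode)) >= 0.9
        assert m.r_valid >= 0.9

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError):
            fma.fit_fma(np.random.default_rng(0).normal(size=(50, 3)),
                        np.ones(50))

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            fma.fit_fma(rng.normal(size=(10, 3)), rng.normal(size=10),
                        n_components=8)

    def test_full_rank_limit_equals_ols(self):
        """With n_components = n coordinates, PLS prediction collapses to
        ordinary least squares."""
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (300, 6))
        y = X @ rng.normal(0, 1, 6) + rng.normal(0, 0.1, 300)
        m = fma.fit_fma(X, y, n_components=6)
        tr = slice(0, 150)
        Xc = np.c_[np.ones(150), X[tr]]
        beta = np.linalg.lstsq(Xc, y[tr], rcond=None)[0]
        pred_ols = np.c_[np.ones(150), X[150:]] @ beta
        from scipy import stats

        r_ols = stats.pearsonr(pred_ols, y[150:])[0]
        assert m.r_valid == pytest.approx(r_ols, abs=1e-8)

    def test_mode_invariant_under_training_permutation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (200, 12))
        y = X[:, 3] + rng.normal(0, 0.2, 200)
        m1 = fma.fit_fma(X, y, n_components=2)
        order = rng.permutation(100)
        X2 = X.copy()
        X2[:100] = X[:100][order]
        y2 = y.copy()
        y2[:100] = y[:100][order]
        m2 = fma.fit_fma(X2, y2, n_components=2)
        assert abs(np.dot(m1.mode, m2.mode)) == pytest.approx(1.0, abs=1e-8)


class TestExtremes:
    def test_median_percentiles_return_mean(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (100, 6))
        y = X[:, 0].copy()
        m = fma.fit_fma(X, y, n_components=1)
        # symmetrise the projections around zero
        m.projections = np.concatenate([m.projections, -m.projections])
        lo, hi = fma.extreme_conformations(m, (50.0, 50.0))
        assert lo == pytest.approx(m.mean_structure, abs=1e-9)
        assert hi == pytest.approx(m.mean_structure, abs=1e-9)

    def test_symmetric_projections_give_symmetric_structures(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (100, 6))
        m = fma.fit_fma(X, X[:, 1].copy(), n_components=1)
        m.projections = np.concatenate([m.projections, -m.projections])
        lo, hi = fma.extreme_conformations(m, (1.0, 99.0))
        assert lo + hi == pytest.approx(2 * m.mean_structure, abs=1e-9)

    def test_unfitted_model_rejected(self):
        m = fma.FMAModel(None, None, 1, np.nan, np.nan, None, slice(0, 0))
        with pytest.raises(ValueError):
            fma.extreme_conformations(m)


class TestPipelineOnSyntheticKink:
    @pytest.fixture(scope="class")
    def kink_fma(self):
        topo, frames, truth = generate(SyntheticSpec(n_frames=1500, seed=5))
        aligned = fma.superpose(frames, topo, fit_expr="backbone")
        sel = select(topo, "subunit A and inner_helix and backbone")
        X = aligned.coordinates[:, sel.indices, :].reshape(frames.n_frames, -1)
        y = bending_angle(frames, topo)[:, 0]
        model = fma.fit_fma(X, y, n_components=1)
        return topo, sel, model, y

    def test_mode_tracks_bending_angle(self, kink_fma):
        _, _, model, _ = kink_fma
        assert model.r_valid >= 0.95

    def test_extremes_reproduce_planted_templates(self, kink_fma):
        """The 1st/99th-percentile reconstructions must match the planted
        kinked and bent helix templates within 0.05 nm backbone RMSD
        (after optimal superposition: the extremes live in the aligned
        frame of the mixed trajectory)."""
        topo, sel, model, y = kink_fma
        lo, hi = fma.extreme_conformations(model, (1.0, 99.0))
        templates = {}
        for state in ("kinked", "bent"):
            t_topo, t_frames, _ = generate(
                SyntheticSpec(n_frames=1, seed=1, noise_sigma=0.0,
                              fixed_states=state)
            )
            templates[state] = t_frames.coordinates[0, sel.indices, :]
        # orient: projections correlate with the angle, kinked = large angle
        from scipy import stats

        sign = np.sign(stats.pearsonr(model.projections, y)[0])
        high, low = (hi, lo) if sign > 0 else (lo, hi)

        def fit_rmsd(P, Q):
            Pc, Qc = P - P.mean(0), Q - Q.mean(0)
            R = fma.kabsch_rotation(Pc, Qc)
            return np.sqrt(((Pc @ R.T - Qc) ** 2).sum(1).mean())

        assert fit_rmsd(high, templates["kinked"]) <= 0.05
        assert fit_rmsd(low, templates["bent"]) <= 0.05


class TestCrossValidate:
    def test_selects_planted_single_component(self):
        rng = np.random.default_rng(11)
        mode = rng.normal(0, 1, 20)
        t = rng.normal(0, 1, 300)
        X = np.outer(t, mode) + rng.normal(0, 0.1, (300, 20))
        res = fma.cross_validate(X, t, component_grid=(1, 2, 3), k_folds=5)
        assert res["chosen_n_components"] == 1
        assert res["reliable"]

    def test_pure_noise_flagged_unreliable(self):
        rng = np.random.default_rng(12)
        res = fma.cross_validate(
            rng.normal(size=(200, 10)), rng.normal(size=200),
            component_grid=(1, 2), k_folds=4,
        )
        assert not res["reliable"]

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(150, 8))
        y = X[:, 0] + rng.normal(0, 0.3, 150)
        a = fma.cross_validate(X, y, component_grid=(1, 2, 3), k_folds=3)
        b = fma.cross_validate(X, y, component_grid=(1, 2, 3), k_folds=3)
        assert a == b
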