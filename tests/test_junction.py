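"""Junction domain, force/stress decomposition, anisotropy reporting."""

import numpy as np
import pandas as pd
import pytest

from doubletmech import (
    JunctionDomain,
    StressField,
    TractionField,
    anisotropy_report,
    build_junction_domain,
    decompose_junction_forces,
    junction_stress_components,
    quarter_split,
)


def band_domain(shape=(10, 10), cols=(4, 6), theta=90.0, h=1.0):
    mask = np.zeros(shape, bool)
    mask[:, cols[0]:cols[1]] = True
    mid = np.stack([np.full(shape[0], np.mean(cols) * h),
                    np.arange(shape[0]) * h], axis=1)
    return JunctionDomain(mask=mask, midline=mid, theta=theta, grid_spacing=h)


class TestBuildJunctionDomain:
    def test_abutting_half_planes_give_vertical_band(self):
        m1 = np.zeros((20, 20), bool)
        m2 = np.zeros((20, 20), bool)
        m1[:, :10] = True
        m2[:, 10:] = True
        jd = build_junction_domain(m1, m2, dilation_radius=1)
        cols = np.unique(np.nonzero(jd.mask)[1])
        assert set(cols) == {9, 10}
        assert jd.theta == pytest.approx(90.0)

    def test_disjoint_masks_signal_no_contact(self):
        m1 = np.zeros((20, 20), bool)
        m2 = np.zeros((20, 20), bool)
        m1[:, :5] = True
        m2[:, 15:] = True
        assert build_junction_domain(m1, m2, dilation_radius=0) is None

    def test_scene_junction_orientation_recovered(self, tugging_scene):
        jd = build_junction_domain(tugging_scene.cell_masks[0],
                                   tugging_scene.cell_masks[1],
                                   dilation_radius=2, grid_spacing=0.5)
        assert jd is not None
        diff = abs(((jd.theta - tugging_scene.params.junction_angle)
                    + 90.0) % 180.0 - 90.0)
        assert diff < 5.0

    def test_angled_scene_orientation_recovered(self):
        from doubletmech import SceneParams, make_doublet_scene

        scene = make_doublet_scene(SceneParams(junction_angle=30.0, seed=3))
        jd = build_junction_domain(scene.cell_masks[0], scene.cell_masks[1],
                                   dilation_radius=2, grid_spacing=0.5)
        diff = abs(((jd.theta - 30.0) + 90.0) % 180.0 - 90.0)
        assert diff < 5.0


class TestQuartering:
    def test_quarters_conserve_nodes(self):
        jd = band_domain(shape=(13, 10), cols=(3, 6))
        node_rc, center, periph = quarter_split(jd)
        assert center.sum() + periph.sum() == jd.mask.sum()
        sizes = [center.sum(), periph.sum()]
        assert abs(sizes[0] - sizes[1]) <= 3

    def test_center_is_middle_along_axis(self):
        jd = band_domain(shape=(8, 10), cols=(4, 5), theta=90.0)
        node_rc, center, _ = quarter_split(jd)
        rows = node_rc[:, 0]
        assert set(rows[center]) == {2, 3, 4, 5}


class TestDecomposeForces:
    def test_purely_parallel_traction(self):
        jd = band_domain(theta=90.0)
        vec = np.zeros((10, 10, 2))
        vec[..., 1] = 4.0  # along +y = junction direction
        s = decompose_junction_forces(TractionField(vec, 1.0), jd)
        assert s.T_par_center == pytest.approx(4.0)
        assert s.T_perp_center == 0.0 and s.T_perp_periph == 0.0
        assert s.ratio_par_perp_center == np.inf

    def test_purely_perpendicular_traction(self):
        jd = band_domain(theta=90.0)
        vec = np.zeros((10, 10, 2))
        vec[..., 0] = 7.0
        s = decompose_junction_forces(TractionField(vec, 1.0), jd)
        assert s.T_perp_center == pytest.approx(7.0)
        assert s.T_perp_periph == pytest.approx(7.0)
        assert s.T_par_center == 0.0
        assert s.ratio_par_perp_center == 0.0

    def test_matches_brute_force_loop_exactly(self, rng):
        """Hand-written per-node projection, quartering and means."""
        jd = band_domain(shape=(4, 4), cols=(0, 4), theta=0.0)
        vec = rng.normal(size=(4, 4, 2))
        s = decompose_junction_forces(TractionField(vec, 1.0), jd)

        theta = 0.0
        e_par = np.array([np.cos(theta), np.sin(theta)])
        e_perp = np.array([-np.sin(theta), np.cos(theta)])
        nodes = [(r, c) for r in range(4) for c in range(4)]  # row-major
        ranked = sorted(nodes, key=lambda rc: rc[1])  # along x (θ = 0)
        n = len(nodes)
        base, rem = divmod(n, 4)
        sizes = [base] * 4
        for q in (1, 2, 0, 3):
            if rem == 0:
                break
            sizes[q] += 1
            rem -= 1
        bounds = np.cumsum([0] + sizes)
        quarter_of = {}
        for q in range(4):
            for rc in ranked[bounds[q]:bounds[q + 1]]:
                quarter_of[rc] = q
        # values listed in row-major node order, as a masked mean would
        par = np.array([abs(vec[r, c] @ e_par) for r, c in nodes])
        perp = np.array([abs(vec[r, c] @ e_perp) for r, c in nodes])
        center = np.array([quarter_of[rc] in (1, 2) for rc in nodes])
        assert s.T_par_center == par[center].mean()
        assert s.T_perp_center == perp[center].mean()
        assert s.T_par_periph == par[~center].mean()
        assert s.T_perp_periph == perp[~center].mean()

    def test_tiny_mask_rejected(self):
        jd = band_domain(shape=(10, 10), cols=(4, 5))
        jd.mask[:] = False
        jd.mask[0, 4] = True
        with pytest.raises(ValueError, match="4 nodes"):
            decompose_junction_forces(TractionField(np.zeros((10, 10, 2)), 1.0), jd)

    def test_rotating_inputs_by_90_swaps_summaries(self, rng):
        """θ-consistency: rotating mask and traction by 90° swaps the
        parallel and perpendicular summaries exactly."""
        # quarter boundaries must fall between equal-rank tie groups
        # (2-node rows) or tie-breaking order masks the symmetry
        vec = rng.normal(size=(8, 8, 2))
        jd = band_domain(shape=(8, 8), cols=(3, 5), theta=90.0)
        s = decompose_junction_forces(TractionField(vec, 1.0), jd)
        # clockwise grid rotation: (tx, ty) → (ty, −tx), θ 90° → 0°
        vec_rot = np.stack([np.rot90(vec[..., 1]), -np.rot90(vec[..., 0])],
                           axis=-1)
        jd_rot = JunctionDomain(mask=np.rot90(jd.mask).copy(),
                                midline=jd.midline, theta=0.0,
                                grid_spacing=1.0)
        s_rot = decompose_junction_forces(TractionField(vec_rot, 1.0), jd_rot)
        assert s_rot.T_par_center == pytest.approx(s.T_par_center, abs=1e-12)
        assert s_rot.T_perp_center == pytest.approx(s.T_perp_center, abs=1e-12)
        assert s_rot.T_par_periph == pytest.approx(s.T_par_periph, abs=1e-12)


class TestStressComponents:
    def test_isotropic_invariance(self):
        p = 2.5
        jd = band_domain(theta=37.0)
        sf = StressField(np.full((10, 10), p), np.full((10, 10), p),
                         np.zeros((10, 10)), 1.0)
        s = junction_stress_components(sf, jd)
        assert s.sigma_par == pytest.approx(p)
        assert s.sigma_perp == pytest.approx(p)

    def test_uniaxial_stress_along_theta_zero(self):
        jd = band_domain(theta=0.0)
        sf = StressField(np.full((10, 10), 5.0), np.zeros((10, 10)),
                         np.zeros((10, 10)), 1.0)
        s = junction_stress_components(sf, jd)
        assert s.sigma_par == pytest.approx(5.0)
        assert s.sigma_perp == pytest.approx(0.0)

    def test_matches_tensor_rotation_oracle(self, rng):
        jd = band_domain(theta=30.0)
        sxx, syy, sxy = rng.normal(size=(3, 10, 10))
        sf = StressField(sxx, syy, sxy, 1.0)
        s = junction_stress_components(sf, jd)
        th = np.deg2rad(30.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        par, perp = [], []
        for r, c in np.argwhere(jd.mask):
            m = np.array([[sxx[r, c], sxy[r, c]], [sxy[r, c], syy[r, c]]])
            rotated = R.T @ m @ R
            par.append(rotated[0, 0])
            perp.append(rotated[1, 1])
        assert s.sigma_par == pytest.approx(np.mean(par), abs=1e-12)
        assert s.sigma_perp == pytest.approx(np.mean(perp), abs=1e-12)

    def test_trace_invariance(self, rng):
        jd = band_domain(theta=-54.0)
        sxx, syy, sxy = rng.normal(size=(3, 10, 10))
        sf = StressField(sxx, syy, sxy, 1.0)
        s = junction_stress_components(sf, jd)
        trace = (sxx + syy)[jd.mask].mean()
        assert s.sigma_par + s.sigma_perp == pytest.approx(trace, abs=1e-12)


class TestAnisotropyReport:
    def _series(self, sxx, syy, n=18):
        jd = band_domain(theta=90.0)
        stress = [StressField(np.full((10, 10), sxx),
                              np.full((10, 10), syy),
                              np.zeros((10, 10)), 1.0)] * n
        traction = [TractionField(np.ones((10, 10, 2)), 1.0)] * n
        times = np.arange(n) * 10.0
        return stress, traction, [jd] * n, times

    def test_six_marks_for_18_frame_series(self):
        stress, traction, jds, times = self._series(1.0, 2.0)
        table = anisotropy_report(stress, traction, jds, times,
                                  contact_index=0)
        assert len(table) == 6
        assert list(table.mark_min) == [30.0, 60.0, 90.0, 120.0, 150.0, 180.0]

    def test_parallel_prestress_ratio_above_one(self):
        # θ = 90°: junction-parallel stress is σyy
        stress, traction, jds, times = self._series(1.0, 3.0)
        table = anisotropy_report(stress, traction, jds, times,
                                  contact_index=0)
        assert (table.ratio_par_perp > 1.0).all()

    def test_isotropic_ratio_is_one(self):
        stress, traction, jds, times = self._series(2.0, 2.0)
        table = anisotropy_report(stress, traction, jds, times,
                                  contact_index=0)
        assert np.allclose(table.ratio_par_perp, 1.0, atol=1e-9)

    def test_contact_frame_outside_series_rejected(self):
        stress, traction, jds, times = self._series(1.0, 1.0, n=5)
        with pytest.raises(ValueError, match="contact frame"):
            anisotropy_report(stress, traction, jds, times, contact_index=7)

    def test_returns_dataframe_with_force_columns(self):
        stress, traction, jds, times = self._series(1.0, 2.0)
        table = anisotropy_report(stress, traction, jds, times,
                                  contact_index=0)
        assert isinstance(table, pd.DataFrame)
        assert {"sigma_par", "sigma_perp", "T_par_center",
                "T_perp_periph"} <= set(table.columns)
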