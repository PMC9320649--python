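import numpy as np
import pytest

from cellforce.forward_solver import ControlField, StateTrajectory
from cellforce.geometry import (
    EmptyCellError,
    MembraneContour,
    cell_count_trace,
    centroid,
    euler_number,
    force_summary,
    membrane_contour,
    membrane_length,
)
from cellforce.model_core import GridSpec, PhysicalParams
from cellforce.optimal_control import ObjectiveValue, PairResult
from cellforce.synthetic_data import (
    make_annulus_field,
    make_disk_field,
    make_division_movie,
)


def two_disks(grid, eps=0.02):
    d1 = make_disk_field((0.3, 0.3), 0.12, eps, grid).values
    d2 = make_disk_field((0.7, 0.7), 0.12, eps, grid).values
    return np.maximum(d1, d2)


def fake_pair(states, control, substeps=1):
    """Assemble a PairResult from raw fields for post-processing tests."""
    traj = StateTrajectory(np.asarray(states), np.zeros(len(states) - 1), dt=1.0 / max(len(states) - 1, 1))
    ctrl = ControlField(np.asarray(control), np.ones_like(np.asarray(control), dtype=bool))
    return PairResult(
        control=ctrl, trajectory=traj, objective_history=[], converged=True,
        objective=ObjectiveValue(0.0, 0.0, 0.0), substeps=substeps,
    )


class TestContours:
    def test_disk_gives_one_closed_polyline(self, grid256):
        cont = membrane_contour(make_disk_field((0.5, 0.5), 0.25, 0.02, grid256), grid256)
        assert len(cont.polylines) == 1
        assert np.allclose(cont.polylines[0][0], cont.polylines[0][-1])

    def test_two_disks_give_two_polylines(self, grid256):
        cont = membrane_contour(two_disks(grid256), grid256)
        assert len(cont.polylines) == 2

    def test_disk_arclength_matches_circumference(self, grid256):
        cont = membrane_contour(make_disk_field((0.5, 0.5), 0.25, 0.02, grid256), grid256)
        assert cont.total_length == pytest.approx(2 * np.pi * 0.25, rel=0.01)

    def test_single_sign_field_has_no_contour(self, grid64):
        cont = membrane_contour(np.ones(grid64.shape), grid64)
        assert cont.polylines == [] and cont.total_length == 0.0

    def test_length_converges_under_refinement(self):
        errs = []
        for n in (64, 128, 256):
            grid = GridSpec(n=n)
            cont = membrane_contour(make_disk_field((0.5, 0.5), 0.3, 0.04, grid), grid)
            errs.append(abs(cont.total_length - 2 * np.pi * 0.3))
        assert errs[2] < errs[0]


class TestMembraneLength:
    def test_unit_square_polyline(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
        cont = MembraneContour([square], np.array([4.0]))
        assert membrane_length(cont, L=100.0) == pytest.approx(400.0)

    def test_empty_contour_is_zero(self):
        assert membrane_length(MembraneContour([], np.array([])), L=81.5) == 0.0

    def test_disk_physical_length(self, grid256):
        cont = membrane_contour(make_disk_field((0.5, 0.5), 0.25, 0.02, grid256), grid256)
        assert membrane_length(cont, L=81.5) == pytest.approx(2 * np.pi * 0.25 * 81.5, rel=0.01)


class TestCentroid:
    def test_centred_disk(self, grid256):
        c = centroid(make_disk_field((0.5, 0.5), 0.25, 0.02, grid256), grid256)
        assert c == pytest.approx((0.5, 0.5), abs=1e-10)

    def test_offset_disk_translation_equivariance(self, grid256):
        c = centroid(make_disk_field((0.3, 0.7), 0.2, 0.02, grid256), grid256)
        assert abs(c[0] - 0.3) < 0.5 * grid256.spacing
        assert abs(c[1] - 0.7) < 0.5 * grid256.spacing

    def test_uniform_field(self, grid64):
        assert centroid(np.ones(grid64.shape), grid64) == pytest.approx((0.5, 0.5))

    def test_empty_cell_rejected(self, grid64):
        with pytest.raises(EmptyCellError):
            centroid(-np.ones(grid64.shape), grid64)


class TestEulerNumber:
    def test_disk(self, grid256):
        phi = make_disk_field((0.5, 0.5), 0.25, 0.02, grid256).values
        assert euler_number(phi, 0.8, grid256) == pytest.approx(1.0, abs=0.05)

    def test_two_disks_additive(self, grid256):
        assert euler_number(two_disks(grid256), 0.8, grid256) == pytest.approx(2.0, abs=0.05)

    def test_annulus_zero(self, grid256):
        phi = make_annulus_field((0.5, 0.5), 0.35, 0.2, 0.02, grid256).values
        assert euler_number(phi, 0.8, grid256) == pytest.approx(0.0, abs=0.05)

    def test_band_level_must_be_interior(self, grid64):
        with pytest.raises(ValueError):
            euler_number(np.zeros(grid64.shape), 1.2, grid64)

    def test_matches_labelling_oracle_on_random_blobs(self, grid256):
        from cellforce.verification import euler_benchmark

        out = euler_benchmark(n=256, n_blob_seeds=8, seed=7)
        assert out["blob_max_abs_dev"] < 0.05


class TestCellCountTrace:
    def test_static_disk_trace_constant_one(self, grid256):
        phi = make_disk_field((0.5, 0.5), 0.25, 0.02, grid256).values
        traj = StateTrajectory(np.stack([phi] * 4), np.zeros(3), dt=0.1)
        trace = cell_count_trace(traj, c=0.8, grid=grid256)
        assert np.all(trace.rounded == 1)
        assert len(trace.events) == 0

    def test_division_movie_steps_one_to_two(self, grid256):
        from cellforce.imaging import mask_to_phasefield

        movie = make_division_movie(n_frames=9, seed=0)
        fields = np.stack([mask_to_phasefield(m, grid256, 0.02).values for m in movie.masks])
        traj = StateTrajectory(fields, np.zeros(8), dt=0.125)
        trace = cell_count_trace(traj, c=0.8, grid=grid256)
        k = movie.meta["division_frame"]
        assert trace.rounded[k - 1] == 1 and trace.rounded[k] == 2
        assert list(trace.events) == [k]

    def test_three_blobs_divide_into_six(self, grid256):
        from cellforce.imaging import mask_to_phasefield

        movie = make_division_movie(n_frames=9, max_separation=0.36, radius=0.08, n_cells=3, seed=0)
        first = mask_to_phasefield(movie.masks[0], grid256, 0.02).values
        last = mask_to_phasefield(movie.masks[-1], grid256, 0.02).values
        assert round(euler_number(first, 0.8, grid256)) == 3
        assert round(euler_number(last, 0.8, grid256)) == 6


class TestForceSummary:
    phys = PhysicalParams(L=100.0, F=10.0, T_total=600.0, TI=300.0)

    def contour_length(self, phi, grid):
        return membrane_contour(phi, grid).total_length

    def test_positive_control_is_pure_protrusion(self, grid256):
        phi = make_disk_field((0.5, 0.5), 0.3, 0.02, grid256).values
        pair = fake_pair([phi, phi], np.full((1,) + grid256.shape, 1.5))
        row = force_summary(pair, self.phys, grid=grid256)
        assert row.total_retraction_pN == 0.0
        assert row.protrusion_pct == 100.0

    def test_closed_form_line_integral(self, grid256):
        a, radius = 2.0, 0.3
        phi = make_disk_field((0.5, 0.5), radius, 0.02, grid256).values
        pair = fake_pair([phi, phi], np.full((1,) + grid256.shape, a))
        row = force_summary(pair, self.phys, grid=grid256)
        expected = a * self.phys.F * 2 * np.pi * radius
        assert row.total_protrusion_pN == pytest.approx(expected, rel=0.01)

    def test_percentages_partition_membrane(self, grid256, rng):
        phi = make_disk_field((0.5, 0.5), 0.3, 0.02, grid256).values
        eta = rng.standard_normal((2,) + grid256.shape)
        pair = fake_pair([phi, phi, phi], eta)
        row = force_summary(pair, self.phys, grid=grid256)
        assert row.protrusion_pct + row.retraction_pct == pytest.approx(100.0)
        assert 0 < row.protrusion_pct < 100

    def test_homogeneity_in_control_and_force_scale(self, grid256):
        x, y = grid256.mesh()
        phi = make_disk_field((0.5, 0.5), 0.3, 0.02, grid256).values
        eta = (np.cos(np.arctan2(y - 0.5, x - 0.5)))[None]
        row1 = force_summary(fake_pair([phi, phi], eta), self.phys, grid=grid256)
        row2 = force_summary(fake_pair([phi, phi], 3.0 * eta), self.phys, grid=grid256)
        phys2 = PhysicalParams(L=100.0, F=20.0, T_total=600.0, TI=300.0)
        row3 = force_summary(fake_pair([phi, phi], eta), phys2, grid=grid256)
        assert row2.total_protrusion_pN == pytest.approx(3 * row1.total_protrusion_pN, rel=1e-9)
        assert row3.total_protrusion_pN == pytest.approx(2 * row1.total_protrusion_pN, rel=1e-9)

    def test_rotation_invariance_of_totals(self, grid256):
        x, y = grid256.mesh()
        phi = make_disk_field((0.45, 0.55), 0.25, 0.02, grid256).values
        eta = np.where(np.abs(phi) < 0.95, np.cos(2 * np.arctan2(y - 0.55, x - 0.45)), 0.0)[None]
        row = force_summary(fake_pair([phi, phi], eta), self.phys, grid=grid256)
        phi_r = np.rot90(phi).copy()
        eta_r = np.rot90(eta[0]).copy()[None]
        row_r = force_summary(fake_pair([phi_r, phi_r], eta_r), self.phys, grid=grid256)
        assert row_r.total_protrusion_pN == pytest.approx(row.total_protrusion_pN, rel=1e-3)
        assert row_r.total_retraction_pN == pytest.approx(row.total_retraction_pN, rel=1e-3)

    def test_membraneless_step_is_flagged(self, grid64):
        pair = fake_pair([np.ones(grid64.shape)] * 2, np.zeros((1,) + grid64.shape))
        row = force_summary(pair, self.phys, grid=grid64)
        assert row.flagged
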