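"""Bead matching, affine fits and Green-Lagrange strain kernels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podomech import (
    BeadField, DeformationSpec, EmptyFieldError, InvertedElementError,
    fit_deformation_gradient, generate_bead_field, green_lagrange,
    make_grid, match_beads, principal_strain, strain_pipeline,
)


def rotation(deg):
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


class TestMatchBeads:

    def test_identical_clouds_identity_match(self):
        pts = np.random.default_rng(0).uniform(0, 20, (50, 2))
        field = match_beads(pts, pts, max_disp=1.0)
        assert field.n_beads == 50
        assert np.allclose(field.displacements, 0.0)

    def test_rigid_translation_all_matched(self):
        pts = np.random.default_rng(1).uniform(0, 20, (60, 2))
        field = match_beads(pts, pts + [0.3, 0.0], max_disp=1.0)
        assert field.n_beads == 60
        assert np.allclose(field.displacements, [0.3, 0.0])

    def test_never_double_assigns_ambiguous_beads(self):
        # two reference beads 0.1 um apart, large perturbation: whatever is
        # matched, the assignment must be one-to-one (brute-force check)
        rng = np.random.default_rng(3)
        ref = np.array([[5.0, 5.0], [5.1, 5.0], [8.0, 8.0], [2.0, 7.0],
                        [9.0, 2.0]])
        deformed = ref + rng.normal(0, 0.5, ref.shape)
        field = match_beads(ref, deformed, max_disp=1.5)
        i, j = field.match_indices.T
        assert len(np.unique(i)) == len(i)
        assert len(np.unique(j)) == len(j)

    def test_no_match_within_radius_raises(self):
        with pytest.raises(EmptyFieldError):
            match_beads(np.array([[0.0, 0.0]]), np.array([[10.0, 10.0]]),
                        max_disp=1.0)


class TestDeformationGradientFit:

    def test_exact_affine_field_recovered_everywhere(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 30, (400, 2))
        F = np.array([[1.1, 0.0], [0.0, 0.95]])
        field = BeadField(ref, ref @ F.T + [0.4, -0.2])
        out = fit_deformation_gradient(field, make_grid((5, 5, 25, 25), 2.0),
                                       window_radius=5.0)
        assert out.defined.all()
        assert np.abs(out.F - F).max() < 1e-10

    def test_collinear_neighbors_flagged_undefined(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0],
                        [20.0, 20.0], [21.0, 20.0], [20.0, 21.0],
                        [21.0, 21.0]])
        field = BeadField(ref, ref)
        out = fit_deformation_gradient(field, np.array([[1.0, 0.0],
                                                        [20.5, 20.5]]),
                                       window_radius=3.0, min_neighbors=3)
        assert not out.defined[0]          # 3 collinear beads
        assert out.defined[1]

    def test_radial_contraction_recovered_within_two_percent(self):
        spec = DeformationSpec("radial_contraction", {"fraction": 0.05},
                               domain=(0, 0, 50, 50))
        field = generate_bead_field(spec, n_beads=1000, seed=7)
        grid = make_grid((10, 10, 40, 40), 2.0)
        out = fit_deformation_gradient(field, grid, window_radius=5.0)
        F_true = 0.95 * np.eye(2)
        err = np.abs(out.F[out.defined] - F_true).max()
        assert err < 0.02 * 0.95

    def test_noise_bias_small_with_thirty_beads(self):
        # Monte-Carlo: 0.05-um localization noise, 5% equibiaxial stretch
        rng = np.random.default_rng(42)
        e1_true = 0.5 * (1.05**2 - 1)
        errs = []
        for _ in range(200):
            ref = rng.uniform(0, 12, (40, 2))
            deformed = ref * 1.05
            field = BeadField(ref + rng.normal(0, 0.05, ref.shape),
                              deformed + rng.normal(0, 0.05, ref.shape))
            out = fit_deformation_gradient(field, np.array([[6.0, 6.0]]),
                                           window_radius=6.0,
                                           min_neighbors=10)
            out.compute_strain()
            errs.append(out.e1[0] - e1_true)
        assert abs(np.mean(errs)) < 0.005


class TestStrainKernels:

    @pytest.mark.parametrize("F, expected", [
        (np.eye(2), np.zeros((2, 2))),
        (np.diag([1.1, 1.0]), np.array([[0.105, 0.0], [0.0, 0.0]])),
        (rotation(30), np.zeros((2, 2))),
        (np.array([[1.0, 0.2], [0.0, 1.0]]),
         np.array([[0.0, 0.1], [0.1, 0.02]])),
    ])
    def test_green_lagrange_closed_forms(self, F, expected):
        assert np.abs(green_lagrange(F) - expected).max() < 1e-12

    def test_inverted_gradient_rejected(self):
        with pytest.raises(InvertedElementError):
            green_lagrange(np.diag([-1.0, 1.0]))

    def test_principal_strain_diagonal(self):
        e1, e2, d = principal_strain(np.diag([0.1, 0.02]))
        assert e1 == pytest.approx(0.1) and e2 == pytest.approx(0.02)
        assert np.allclose(np.abs(d), [1.0, 0.0])

    def test_principal_strain_pure_shear_at_45_degrees(self):
        e1, _, d = principal_strain(np.array([[0.0, 0.1], [0.1, 0.0]]))
        assert e1 == pytest.approx(0.1)
        assert np.allclose(d, [np.sqrt(0.5), np.sqrt(0.5)])

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            principal_strain(np.array([[0.0, 0.1], [0.3, 0.0]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(-0.2, 0.2), b=st.floats(-0.2, 0.2),
           c=st.floats(-0.2, 0.2))
    def test_eigenvalue_sum_equals_trace(self, a, b, c):
        E = np.array([[a, c], [c, b]])
        e1, e2, _ = principal_strain(E)
        assert e1 + e2 == pytest.approx(a + b, abs=1e-12)
        assert e1 >= e2

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(deg=st.floats(-180, 180))
    def test_objectivity_rigid_postmotion(self, deg):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 30, (200, 2))
        F = np.array([[1.08, 0.03], [0.01, 0.96]])
        deformed = ref @ F.T
        grid = make_grid((5, 5, 25, 25), 4.0)
        E_plain = green_lagrange(
            fit_deformation_gradient(BeadField(ref, deformed), grid, 5.0).F)
        moved = deformed @ rotation(deg).T + [3.0, -1.0]
        E_moved = green_lagrange(
            fit_deformation_gradient(BeadField(ref, moved), grid, 5.0).F)
        assert np.abs(E_plain - E_moved).max() < 1e-10


class TestPipeline:

    def test_translation_only_zero_strain(self):
        # jittered lattice: bead spacing well above the displacement so
        # mutual-NN matching is unambiguous (ambiguity has its own test)
        rng = np.random.default_rng(2)
        gx, gy = np.meshgrid(np.arange(0, 20, 2.0), np.arange(0, 20, 2.0))
        ref = np.column_stack([gx.ravel(), gy.ravel()]) \
            + rng.uniform(-0.3, 0.3, (100, 2))
        _, summary = strain_pipeline(ref, ref + [0.3, 0.0], max_disp=1.0)
        assert abs(summary["max_e1"]) < 1e-10
        assert abs(summary["min_e1"]) < 1e-10

    def test_relaxation_reads_as_extension(self):
        # reference = contracted (pre-treatment) state; the relaxed state
        # after actin depolymerisation is the deformed frame, so strain
        # measured ref -> def is positive (extension)
        rng = np.random.default_rng(4)
        relaxed = rng.uniform(0, 20, (300, 2))
        contracted = 10.0 + 0.97 * (relaxed - 10.0)
        _, summary = strain_pipeline(contracted, relaxed, max_disp=1.0)
        assert summary["mean_e1"] > 0

    def test_masked_summary_subsets_grid(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(0, 20, (400, 2))
        field, summary = strain_pipeline(
            ref, ref, max_disp=1.0,
            mask=lambda pts: pts[:, 0] < 10.0)
        assert summary["n_summarised"] < summary["n_defined"]
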