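import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.decomposition import PCA as SkPCA

from algascope import features as ft
from algascope import synth

from conftest import make_obj, disk_mask, rect_mask, ellipse_mask


class TestPerimeterAndArea:
    def test_square_perimeter_chain(self):
        # the closed chain around a 10x10 square visits 36 border pixels
        # with 36 axial unit steps
        assert ft.region_perimeter(make_obj(rect_mask(10, 10))) == pytest.approx(36.0)

    def test_thin_bar_perimeter_traces_both_sides(self):
        # 1x50 bar: 49 steps out + 49 steps back
        assert ft.region_perimeter(make_obj(rect_mask(1, 50))) == pytest.approx(98.0)

    def test_disk_perimeter_close_to_circumference(self):
        per = ft.region_perimeter(make_obj(disk_mask(30)))
        assert 2 * math.pi * 30 * 0.95 <= per <= 2 * math.pi * 30 * 1.15

    def test_area_counts_pixels(self):
        assert ft.region_area(make_obj(rect_mask(10, 10))) == 100
        m = np.zeros((5, 5), bool)
        m[1, 1] = m[3, 3] = True
        assert ft.region_area(make_obj(m)) == 2

    def test_disk_area_matches_rasterization(self):
        mask = disk_mask(20)
        assert ft.region_area(make_obj(mask)) == int(mask.sum())
        assert abs(mask.sum() - math.pi * 400) / (math.pi * 400) < 0.03


class TestInclinationAngle:
    def test_eq_unit_slope_gives_45_degrees(self):
        assert ft.inclination_from_slopes(1.0, 0.0) == pytest.approx(45.0)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_slope_antisymmetry(self, m1, m2):
        t12 = ft.inclination_from_slopes(m1, m2)
        t21 = ft.inclination_from_slopes(m2, m1)
        if abs(t12) != pytest.approx(90.0, abs=1e-6):
            assert t12 == pytest.approx(-t21, abs=1e-9)

    def test_axis_aligned_ellipse_is_flat(self):
        res = ft.inclination_angle(make_obj(ellipse_mask(50, 20)))
        assert abs(res.theta) <= 1.0
        assert res.m2 == 0.0

    @pytest.mark.parametrize("angle", [30, -20, 60])
    def test_rotated_ellipse_angle_recovered(self, angle):
        # the mask builder rotates coordinates, so the chord tilts by +angle
        # in image convention (y downward)
        res = ft.inclination_angle(make_obj(ellipse_mask(50, 20, angle_deg=angle)))
        assert res.theta == pytest.approx(angle, abs=2.0)

    def test_longest_chord_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            m = np.zeros((40, 40), bool)
            # random blob: union of a few disks
            for _ in range(3):
                r0, c0, rad = rng.integers(10, 30), rng.integers(10, 30), rng.integers(3, 8)
                yy, xx = np.indices(m.shape)
                m |= (yy - r0) ** 2 + (xx - c0) ** 2 <= rad ** 2
            obj = make_obj(m)
            boundary = ft._boundary_pixels(m)
            assert len(boundary) <= 400
            pts = boundary[:, ::-1].astype(float)
            d2 = ((pts[:, None] - pts[None]) ** 2).sum(axis=2)
            best = math.sqrt(d2.max())
            # default strict search equals the exhaustive maximum exactly
            res0 = ft.inclination_angle(obj)
            got0 = math.hypot(res0.p2[0] - res0.p1[0], res0.p2[1] - res0.p1[1])
            assert got0 == pytest.approx(best, abs=1e-9)
            # the quantization-tolerant search stays within 1 px of it
            res = ft.inclination_angle(obj, tol=1.0)
            got = math.hypot(res.p2[0] - res.p1[0], res.p2[1] - res.p1[1])
            assert best - 1.0 - 1e-9 <= got <= best + 1e-9

    def test_single_pixel_mask_rejected(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(ValueError):
            ft.inclination_angle(make_obj(m))


class TestAlignment:
    def test_zero_angle_is_identity(self):
        obj = make_obj(ellipse_mask(40, 15), color=(0.3, 0.5, 0.2))
        out = ft.align_horizontal(obj, 0.0)
        assert np.array_equal(out.mask, obj.mask)

    @pytest.mark.parametrize("angle", [30, -45, 75])
    def test_aligned_object_is_horizontal(self, angle):
        obj = make_obj(ellipse_mask(50, 18, angle_deg=angle), color=(0.4, 0.4, 0.4))
        res = ft.inclination_angle(obj)
        aligned = ft.align_horizontal(obj, res.theta)
        assert abs(ft.inclination_angle(aligned, tol=1.0).theta) <= 2.0

    @pytest.mark.parametrize("angle", [15, 30, 60])
    def test_rotation_preserves_area(self, angle):
        obj = make_obj(ellipse_mask(40, 20))
        assert obj.mask.sum() >= 500
        aligned = ft.align_horizontal(obj, angle)
        assert abs(int(aligned.mask.sum()) - int(obj.mask.sum())) / obj.mask.sum() < 0.03


class TestAxesAndWidthProfile:
    def test_rectangle_axes(self):
        major, minor = ft.major_minor_axes(make_obj(rect_mask(40, 100)))
        assert major == pytest.approx(100, abs=1)
        assert minor == pytest.approx(40, abs=1)

    def test_disk_axes_symmetric(self):
        major, minor = ft.major_minor_axes(make_obj(disk_mask(30)))
        assert major == pytest.approx(60, abs=2)
        assert minor == pytest.approx(60, abs=2)

    def test_filament_axes(self):
        # stadium of length 180, width 10
        m = np.zeros((24, 196), bool)
        yy, xx = np.indices(m.shape)
        x = xx - 97.5
        y = yy - 11.5
        m |= (np.abs(x) <= 85) & (np.abs(y) <= 5)
        m |= ((np.abs(x) - 85) ** 2 + y ** 2 <= 25) & (np.abs(x) > 85)
        major, minor = ft.major_minor_axes(make_obj(m))
        assert major == pytest.approx(180, abs=5)
        assert minor == pytest.approx(10, abs=3)

    def test_rectangle_constant_width_profile(self):
        prof = ft.width_profile(make_obj(rect_mask(40, 100)))
        assert prof.n_strips == 5
        assert np.allclose(prof.strips, 0.4, atol=1e-9)
        assert prof.object_length == pytest.approx(100)

    def test_disk_profile_symmetric_peaked(self):
        prof = ft.width_profile(make_obj(disk_mask(50)))
        r = prof.strips
        assert r[2] == pytest.approx(1.0, abs=0.05)
        assert r[0] == pytest.approx(r[4], abs=0.02)
        assert r[0] < r[2] and r[4] < r[2]
        # analytic oracle: mean chord length 2*sqrt(R^2 - d^2) over each strip
        R, L = 50.0, 101.0
        for s in (0, 2, 4):
            d = np.linspace(-R + s * 2 * R / 5, -R + (s + 1) * 2 * R / 5, 200)
            expect = np.trapezoid(2 * np.sqrt(np.maximum(R ** 2 - d ** 2, 0)), d) \
                / (d[-1] - d[0]) / L
            assert r[s] == pytest.approx(expect, abs=0.05)

    def test_triangle_profile_decreases_toward_apex(self):
        m = np.zeros((62, 110), bool)
        for c in range(100):
            half = int(round(25 * (1 - c / 100)))
            m[31 - half:31 + half + 1, c + 5] = True
        prof = ft.width_profile(make_obj(m))
        assert np.all(np.diff(prof.strips) < 0)


class TestShapeIndex:
    def test_disk_is_circular(self):
        assert ft.classify_shape(make_obj(disk_mask(40))) == 0

    def test_long_bar_is_spiral(self):
        assert ft.classify_shape(make_obj(rect_mask(12, 200))) == 1

    def test_l_shaped_blob_is_irregular(self):
        m = np.zeros((100, 100), bool)
        m[10:90, 10:50] = True
        m[50:90, 10:90] = True
        assert ft.classify_shape(make_obj(m)) == -1


class TestFourierSpectrum:
    def _crop_obj(self, gray_patch):
        mask = np.ones(gray_patch.shape, bool)
        crop = np.repeat(gray_patch[:, :, None], 3, axis=2)
        return make_obj(mask).__class__(index=1, mask=mask, bbox=(0, 0, *mask.shape),
                                        color_crop=crop)

    def test_constant_crop_zero_descriptor(self):
        obj = self._crop_obj(np.full((64, 64), 0.5))
        spec = ft.fourier_spectrum(obj)
        assert spec.raw_dim == 32
        assert np.allclose(spec.descriptor, 0.0)

    def test_marginals_are_sums_of_polar_grid(self):
        rng = np.random.default_rng(2)
        obj = self._crop_obj(rng.random((64, 64)))
        spec = ft.fourier_spectrum(obj)
        p1 = spec.s_polar.sum(axis=1)
        p2 = spec.s_polar.sum(axis=0)
        assert np.allclose(spec.radial_fn, p1 / p1.sum(), atol=1e-12)
        assert np.allclose(spec.angular_fn, p2 / p2.sum(), atol=1e-12)
        assert np.all(spec.s_polar >= 0)

    def test_grating_peaks_in_expected_bins(self):
        x = np.arange(64)
        grating = 0.5 + 0.4 * np.sin(2 * np.pi * 8 * x / 64)  # 8 cycles across
        obj = self._crop_obj(np.tile(grating, (64, 1)))
        spec = ft.fourier_spectrum(obj)
        # radius 8 of 32 -> radial bin 4; wave vector along +x -> angular bin 0
        assert int(np.argmax(spec.radial_fn)) == 4
        assert int(np.argmax(spec.angular_fn)) in (0, 15)

    def test_rotation_shifts_angular_marginal(self):
        x = np.arange(64)
        patch = 0.5 + 0.3 * np.sin(2 * np.pi * 6 * x / 64)[None, :] * np.ones((64, 1))
        obj = self._crop_obj(patch)
        obj90 = self._crop_obj(np.rot90(patch))
        s1 = ft.fourier_spectrum(obj)
        s2 = ft.fourier_spectrum(obj90)
        assert np.allclose(s1.radial_fn, s2.radial_fn, atol=0.05)
        shifted = np.roll(s1.angular_fn, 8)
        assert np.allclose(s2.angular_fn, shifted, atol=0.05)


class TestPCA:
    def _descriptors(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, 32))

    def test_rank_deficient_data(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 32))
        X = rng.normal(size=(50, 2)) @ basis
        model = ft.fit_pca(X)
        assert np.all(model.eigenvalues[2:] <= 1e-10)

    def test_isotropic_eigenvalues_bounded(self):
        model = ft.fit_pca(self._descriptors(3000, seed=3))
        assert np.all(model.eigenvalues >= 0.7)
        assert np.all(model.eigenvalues <= 1.3)

    def test_orthonormal_components_descending_eigenvalues(self):
        model = ft.fit_pca(self._descriptors(60, seed=5))
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(8), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_reconstruction_variance_identity(self):
        X = self._descriptors(200, seed=7)
        model = ft.fit_pca(X)
        Xc = X - X.mean(axis=0)
        total = (Xc ** 2).sum() / (len(X) - 1)
        proj = Xc @ model.components.T
        captured = (proj ** 2).sum() / (len(X) - 1)
        cov_eigs = np.linalg.eigvalsh(Xc.T @ Xc / (len(X) - 1))
        assert captured == pytest.approx(model.eigenvalues.sum(), rel=1e-10)
        assert total == pytest.approx(cov_eigs.sum(), rel=1e-10)

    def test_matches_sklearn(self):
        X = self._descriptors(80, seed=11)
        model = ft.fit_pca(X)
        sk = SkPCA(n_components=8).fit(X)
        assert np.allclose(model.eigenvalues, sk.explained_variance_, atol=1e-8)
        cos = np.abs(np.sum(model.components * sk.components_, axis=1))
        assert np.allclose(cos, 1.0, atol=1e-8)

    def test_projection_oracles(self):
        X = self._descriptors(50, seed=13)
        model = ft.fit_pca(X)
        assert np.allclose(ft.project_pca(model, model.mean), 0.0, atol=1e-12)
        e1 = ft.project_pca(model, model.mean + model.components[0])
        assert np.allclose(e1, np.eye(8)[0], atol=1e-10)
        x = np.random.default_rng(17).normal(size=32)
        manual = np.array([(x - model.mean) @ row for row in model.components])
        assert np.allclose(ft.project_pca(model, x), manual, atol=1e-10)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ft.fit_pca(self._descriptors(8, seed=0))


@pytest.fixture(scope="module")
def pca():
    rng = np.random.default_rng(23)
    return ft.fit_pca(rng.normal(size=(40, 32)))


class TestAssembleFeatures:

    def test_vector_has_21_entries(self, pca, archetypes):
        rng = np.random.default_rng(29)
        mask, patch = synth.draw_object(archetypes["Navicula"], rng)
        obj = make_obj(mask)
        obj.color_crop = patch
        vec = ft.assemble_features(obj, pca)
        assert vec.shape == (21,)
        assert vec[1] >= vec[2] > 0        # major >= minor
        assert vec[3] >= 50                # area above the exclusion filter
        assert 0 < vec[5] <= 1             # minor/major

    def test_flat_rectangle_composition(self, pca):
        # auto-alignment puts the rectangle's diagonal (its longest chord)
        # horizontal; the width/length ratio 0.4 is invariant to that tilt
        obj = make_obj(rect_mask(40, 100), color=(0.5, 0.5, 0.5))
        vec = ft.assemble_features(obj, pca)
        assert vec[5] == pytest.approx(0.4, abs=0.01)
        assert np.allclose(vec[9:12], 0.4, atol=0.01)   # interior strips
        assert vec[8] == pytest.approx(vec[12], abs=0.01)  # symmetric ends
        # a flat-colour object has no texture: the descriptor is all zero
        assert np.allclose(vec[13:], ft.project_pca(pca, np.zeros(32)), atol=1e-9)

    @pytest.mark.parametrize("angle", [37, 62])
    def test_rotation_invariance_of_geometry(self, pca, angle):
        # well-resolved elongated object, arbitrary (lossy) rotation
        # (aspect 2.7: safely away from the elongation threshold 2.5)
        base = ellipse_mask(80, 30)
        obj = make_obj(base)
        from scipy import ndimage as ndi
        mask_r = ndi.rotate(base.astype(np.uint8), angle, reshape=True, order=0).astype(bool)
        obj_r = make_obj(mask_r)
        f, _ = ft.extract_geometry(obj)
        fr, _ = ft.extract_geometry(obj_r)
        assert f[0] == fr[0]
        rel = np.abs(fr[1:13] - f[1:13]) / np.maximum(np.abs(f[1:13]), 0.05)
        assert np.all(rel <= 0.05)

    def test_quarter_turn_invariance_of_archetypes(self, archetypes):
        rng = np.random.default_rng(31)
        for genus in ("Navicula", "Oscillatoria", "Scenedesmus"):
            mask, patch = synth.draw_object(archetypes[genus], rng, angle=0.0)
            obj = make_obj(mask)
            obj.color_crop = patch
            f, _ = ft.extract_geometry(obj)
            for k in (1, 2, 3):
                obj_r = make_obj(np.rot90(mask, k).copy())
                obj_r.color_crop = np.rot90(patch, k).copy()
                fr, _ = ft.extract_geometry(obj_r)
                assert f[0] == fr[0]
                rel = np.abs(fr[1:13] - f[1:13]) / np.maximum(np.abs(f[1:13]), 0.05)
                assert np.all(rel <= 0.05), (genus, k)

    def test_scale_covariance(self):
        small = make_obj(ellipse_mask(40, 16))
        big = make_obj(ellipse_mask(80, 32))
        f_s, _ = ft.extract_geometry(small)
        f_b, _ = ft.extract_geometry(big)
        for i in (1, 2, 4):  # major, minor, perimeter double
            assert f_b[i] == pytest.approx(2 * f_s[i], rel=0.03)
        assert f_b[3] == pytest.approx(4 * f_s[3], rel=0.05)  # area quadruples
        assert f_b[5] == pytest.approx(f_s[5], rel=0.05)
        assert np.allclose(f_b[8:13], f_s[8:13], atol=0.05)
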