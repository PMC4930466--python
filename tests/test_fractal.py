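import numpy as np
import pytest

from pancmorph import (
    BoundaryImage,
    BoxCountSeries,
    ConfigurationError,
    EmptySegmentationError,
    InputError,
    PhantomSpec,
    SilhouetteImage,
    VolumetricMask,
    box_count,
    count_occupied_boxes,
    default_box_sizes,
    estimate_fd,
    extract_boundary,
    fd_of_mask,
    generate_fractal_fixture,
    generate_organ_phantom,
    project_silhouette,
    replicate_cv,
)
from pancmorph.fractal import estimate_fd_of_boundary

from conftest import brute_force_box_count


class TestProjection:
    def test_single_voxel_projects_to_single_pixel(self):
        vox = np.zeros((5, 5, 5), dtype=bool)
        vox[2, 3, 1] = True
        sil = project_silhouette(VolumetricMask(vox, (1, 1, 1)), "anterior_posterior")
        assert sil.pixels.sum() == 1

    def test_box_projections_give_face_rectangles(self):
        # block of 20 x 30 x 40 mm along (IS, AP, LR) at 1 mm voxels
        vox = np.zeros((30, 40, 50), dtype=bool)
        vox[:20, :30, :40] = True
        mask = VolumetricMask(vox, (1, 1, 1))
        areas = {
            "inferior_superior": 30 * 40,
            "anterior_posterior": 20 * 40,
            "left_right": 20 * 30,
        }
        for axis, area in areas.items():
            assert project_silhouette(mask, axis).pixels.sum() == area

    def test_sphere_silhouette_is_disc_of_same_radius(self):
        spec = PhantomSpec(
            base_radii=(15.0, 15.0, 15.0),
            serration_amplitude=0.0,
            voxel_spacing=(1.0, 1.0, 1.0),
            grid_shape=(34, 34, 34),
        )
        mask = generate_organ_phantom(spec)
        sil = project_silhouette(mask, "inferior_superior")
        equatorial = mask.voxels[17].sum()  # grid centre lies on a voxel row
        assert sil.pixels.sum() == pytest.approx(equatorial, rel=0.02)
        assert sil.pixels.sum() == pytest.approx(np.pi * 15**2, rel=0.05)

    def test_anisotropic_stack_resampled_to_isotropic(self):
        vox = np.ones((4, 10, 10), dtype=bool)
        sil = project_silhouette(VolumetricMask(vox, (4.0, 1.0, 1.0)), "left_right")
        # remaining axes: slices (4 mm) x rows (1 mm) -> slices upsampled 4x
        assert sil.pixel_spacing == 1.0
        assert sil.pixels.shape == (16, 10)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySegmentationError):
            project_silhouette(VolumetricMask(np.zeros((3, 3, 3)), (1, 1, 1)))


class TestBoundary:
    def test_filled_square_boundary_is_perimeter_ring(self):
        px = np.zeros((14, 14), dtype=bool)
        px[2:12, 2:12] = True
        b = extract_boundary(SilhouetteImage(px, 1.0))
        assert b.pixels.sum() == 36

    def test_single_pixel_is_its_own_boundary(self):
        px = np.zeros((5, 5), dtype=bool)
        px[2, 2] = True
        assert extract_boundary(SilhouetteImage(px, 1.0)).pixels.sum() == 1

    def test_interior_hole_does_not_change_boundary(self):
        disc = np.zeros((31, 31), dtype=bool)
        rr, cc = np.mgrid[0:31, 0:31]
        disc[(rr - 15) ** 2 + (cc - 15) ** 2 <= 12**2] = True
        holey = disc.copy()
        holey[13:18, 13:18] = False
        full = extract_boundary(SilhouetteImage(disc, 1.0))
        punched = extract_boundary(SilhouetteImage(holey, 1.0))
        assert np.array_equal(full.pixels, punched.pixels)


class TestBoxCounting:
    def test_filled_block_hand_counts(self):
        img = np.zeros((8, 8), dtype=bool)
        img[:, :] = True
        for size, expected in [(1, 64), (2, 16), (4, 4), (8, 1)]:
            assert count_occupied_boxes(img, size) == expected

    def test_line_hand_counts(self):
        img = np.zeros((16, 16), dtype=bool)
        img[8, :] = True
        for size, expected in [(1, 16), (2, 8), (4, 4)]:
            assert count_occupied_boxes(img, size) == expected

    def test_single_pixel_always_one_box(self):
        img = np.zeros((32, 32), dtype=bool)
        img[11, 23] = True
        for size in (1, 2, 5, 8, 31):
            for shift in [(0, 0), (1, 3), (size - 1, size - 1)]:
                assert count_occupied_boxes(img, size, shift) == 1

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            img = rng.random((rng.integers(16, 64), rng.integers(16, 64))) > 0.8
            for size in (2, 3, 5, 7):
                assert count_occupied_boxes(img, size) == brute_force_box_count(img, size)

    def test_counts_monotone_in_box_size(self):
        rng = np.random.default_rng(7)
        img = rng.random((80, 80)) > 0.9
        series = box_count(
            BoundaryImage(img), [2, 3, 4, 6, 8, 12, 16, 20], rng.random((6, 2))
        )
        diffs = np.diff(series.counts, axis=0)
        assert (diffs <= 0).all()  # N(s) non-increasing in s
        # quartering bound: N(2s) >= N(s) / 4
        for i, s in enumerate(series.box_sizes_px):
            j = np.where(series.box_sizes_px == 2 * s)[0]
            if j.size:
                assert (series.counts[j[0]] >= series.counts[i] / 4.0).all()

    def test_too_few_sizes_rejected(self):
        img = np.zeros((64, 64), dtype=bool)
        img[3, 3] = True
        with pytest.raises(ConfigurationError):
            box_count(BoundaryImage(img), [2, 4, 8, 16], [(0.0, 0.0)])

    def test_default_ladder_requires_room(self):
        with pytest.raises(ConfigurationError):
            default_box_sizes((100, 100))
        assert list(default_box_sizes((512, 512))) == [2, 4, 8, 16, 32, 64, 128]


class TestEstimateFD:
    def test_exact_dyadic_counts_give_exact_slopes(self):
        series = BoxCountSeries(
            np.array([1, 2, 4, 8]), np.array([[64], [16], [4], [1]]), np.zeros((1, 2))
        )
        assert estimate_fd(series).fd == pytest.approx(2.0, abs=1e-12)
        series = BoxCountSeries(
            np.array([1, 2, 4]), np.array([[16], [8], [4]]), np.zeros((1, 2))
        )
        assert estimate_fd(series).fd == pytest.approx(1.0, abs=1e-12)

    def test_zero_count_rejected(self):
        series = BoxCountSeries(
            np.array([1, 2]), np.array([[4], [0]]), np.zeros((1, 2))
        )
        with pytest.raises(InputError):
            estimate_fd(series)

    def test_koch_curve_near_analytic_dimension(self):
        b = generate_fractal_fixture("koch", size=256, iterations=5)
        res = estimate_fd_of_boundary(b, n_offsets=10, rng=np.random.default_rng(1))
        assert res.fd == pytest.approx(np.log(4) / np.log(3), abs=0.05)

    def test_scale_invariance_under_upscaling(self):
        for kind, size in [("circle", 256), ("koch", 256)]:
            b = generate_fractal_fixture(kind, size=size, iterations=5)
            up = BoundaryImage(np.kron(b.pixels, np.ones((2, 2), dtype=bool)))
            fd1 = estimate_fd_of_boundary(b, 10, np.random.default_rng(0)).fd
            fd2 = estimate_fd_of_boundary(up, 10, np.random.default_rng(0)).fd
            assert abs(fd1 - fd2) < 0.05

    def test_offset_ensemble_slopes_are_stable(self):
        for kind, size in [("line", 512), ("circle", 256), ("koch", 256)]:
            b = generate_fractal_fixture(kind, size=size, iterations=5)
            res = estimate_fd_of_boundary(b, n_offsets=12, rng=np.random.default_rng(3))
            slopes = res.per_offset_slopes
            assert 100 * slopes.std(ddof=1) / slopes.mean() < 5.0


class TestReplicateCV:
    def test_hand_values(self):
        assert replicate_cv([1.0, 1.0, 1.0]) == 0.0
        assert replicate_cv([1.0, 1.1]) == pytest.approx(6.734, abs=1e-3)
        assert replicate_cv([2, 4, 4, 4, 5, 5, 7, 9]) == pytest.approx(42.762, abs=1e-3)

    def test_needs_two_values_and_nonzero_mean(self):
        with pytest.raises(InputError):
            replicate_cv([1.0])
        with pytest.raises(InputError):
            replicate_cv([-1.0, 1.0])


@pytest.fixture(scope="module")
def phantom():
    return generate_organ_phantom(PhantomSpec(serration_amplitude=0.25, seed=7))


class TestFDOfMask:

    def test_reported_fd_is_mean_of_replicates(self, phantom):
        res, _ = fd_of_mask(phantom, n_replicates=2, seed=9, replicate_seeds=[11, 22])
        singles = [
            fd_of_mask(phantom, n_replicates=1, seed=0, replicate_seeds=[s])[0].fd
            for s in (11, 22)
        ]
        assert res.fd == pytest.approx(np.mean(singles), abs=1e-12)

    def test_identical_replicate_seeds_give_zero_cv(self, phantom):
        _, prec = fd_of_mask(phantom, n_replicates=10, seed=0, replicate_seeds=[5] * 10)
        assert prec.cv_percent == 0.0
        assert prec.n_replicates == 10

    def test_single_replicate_has_no_precision_estimate(self, phantom):
        res, prec = fd_of_mask(phantom, n_replicates=1, seed=4)
        assert prec is None
        assert 0.8 <= res.fd <= 2.2

    def test_smooth_phantom_not_rougher_than_serrated(self):
        smooth = generate_organ_phantom(PhantomSpec(serration_amplitude=0.0, seed=5))
        rough = generate_organ_phantom(PhantomSpec(serration_amplitude=0.3, seed=5))
        fd_smooth, _ = fd_of_mask(smooth, n_offsets=10, n_replicates=4, seed=5)
        fd_rough, _ = fd_of_mask(rough, n_offsets=10, n_replicates=4, seed=5)
        assert fd_smooth.fd <= fd_rough.fd

    def test_deterministic_given_seed(self, phantom):
        a, _ = fd_of_mask(phantom, n_replicates=2, seed=123)
        b, _ = fd_of_mask(phantom, n_replicates=2, seed=123)
        assert a.fd == b.fd
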