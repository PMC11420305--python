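"""Geometry and color quantification of single fundus images."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fundusindex import (
    CohortConfig,
    FEATURE_NAMES,
    GeometryError,
    LandmarkSet,
    MissingLandmarkError,
    RGBSample,
    UndefinedValueError,
    extract_features,
    ovality_ratio,
    papillomacular_position,
    peripapillary_loci,
    render_image,
    sample_circle_mean,
    sample_covariates,
    sample_scene,
    tessellation_index,
    vessel_angle,
)

DISC = np.array([200.0, 200.0])
FOVEA = np.array([40.0, 200.0])  # temporal = -x


class TestVesselAngle:
    @pytest.mark.parametrize(
        "crossing, expected",
        [
            ((96.0, 200.0), 0.0),  # on the temporal horizontal ray
            ((200.0, 96.0), 90.0),  # directly above the disc center
            ((100.0, 100.0), 45.0),  # temporal offset +100, up +100
            ((100.0, 300.0), 45.0),  # temporal offset +100, down +100
        ],
    )
    def test_reference_directions(self, crossing, expected):
        assert vessel_angle(crossing, DISC, FOVEA) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            vessel_angle(DISC, DISC, FOVEA)

    def test_fovea_directly_vertical_has_no_temporal_side(self):
        with pytest.raises(GeometryError):
            vessel_angle((100.0, 100.0), DISC, (200.0, 50.0))


class TestPapillomacularPosition:
    def test_fovea_on_horizontal_is_zero(self):
        assert papillomacular_position(DISC, FOVEA) == 0.0

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_five_degrees_signed(self, sign):
        # positive when the fovea is inferior (image-down) to the horizontal
        theta = np.radians(5.0)
        fovea = DISC + 300.0 * np.array([-np.cos(theta), sign * np.sin(theta)])
        assert papillomacular_position(DISC, fovea) == pytest.approx(sign * 5.0, abs=1e-9)

    def test_coincident_error(self):
        with pytest.raises(GeometryError):
            papillomacular_position(DISC, DISC)


def _brute_force_width_ratio(points, n_directions=3600):
    """Independent slow loop: min/max width over rotated axis projections."""
    widths = []
    for k in range(n_directions):
        theta = np.pi * k / n_directions
        proj = points[:, 0] * np.cos(theta) + points[:, 1] * np.sin(theta)
        widths.append(proj.max() - proj.min())
    return min(widths) / max(widths)


class TestOvalityRatio:
    def test_circle_is_one(self):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        points = np.stack([50 * np.cos(t), 50 * np.sin(t)], axis=1)
        assert ovality_ratio(points) == pytest.approx(1.0, abs=1e-4)

    def test_axis_aligned_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        points = np.stack([50 * np.cos(t), 40 * np.sin(t)], axis=1)
        assert ovality_ratio(points) == pytest.approx(0.8, abs=1e-3)

    def test_random_convex_polygon_matches_brute_force(self, rng):
        from scipy.spatial import ConvexHull

        cloud = rng.standard_normal((400, 2)) * [30, 55] + 100
        hull = cloud[ConvexHull(cloud).vertices]
        assert ovality_ratio(hull) == pytest.approx(
            _brute_force_width_ratio(hull), abs=1e-3
        )

    @given(scale=st.floats(min_value=1e-2, max_value=1e3))
    def test_scale_invariance(self, scale):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        points = np.stack([50 * np.cos(t), 35 * np.sin(t) + 10], axis=1)
        assert ovality_ratio(points * scale) == pytest.approx(
            ovality_ratio(points), rel=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GeometryError):
            ovality_ratio(np.zeros((5, 2)))  # too few points
        line = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        with pytest.raises(GeometryError):
            ovality_ratio(line)


class TestCircleSampling:
    def test_constant_field(self):
        img = np.zeros((64, 64, 3), np.uint8)
        img[..., 0], img[..., 1], img[..., 2] = 10, 20, 30
        sample = sample_circle_mean(img, (32, 32), 20)
        assert (sample.R, sample.G, sample.B) == (10.0, 20.0, 30.0)
        assert sample.n_pixels > 0

    def test_half_plane_split(self):
        img = np.zeros((101, 101, 3), np.uint8)
        img[:, 51:] = 255  # split through the circle center at x=50.5
        sample = sample_circle_mean(img, (50.5, 50.0), 40)
        assert sample.R == pytest.approx(127.5, abs=1.0)

    def test_out_of_bounds_circle_rejected(self):
        img = np.zeros((64, 64, 3), np.uint8)
        with pytest.raises(GeometryError):
            sample_circle_mean(img, (5, 32), 20)


class TestTessellationIndex:
    @pytest.mark.parametrize(
        "rgb, expected",
        [((128, 128, 128), 1 / 3), ((120, 60, 60), 0.5)],
    )
    def test_values(self, rgb, expected):
        sample = RGBSample(*rgb, n_pixels=10)
        assert tessellation_index(sample) == pytest.approx(expected, abs=1e-12)

    def test_all_black_undefined(self):
        with pytest.raises(UndefinedValueError):
            tessellation_index(RGBSample(0, 0, 0, n_pixels=10))


class TestPeripapillaryLoci:
    def setup_method(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        self.boundary = np.stack(
            [300 + 40 * np.cos(t), 300 + 40 * np.sin(t)], axis=1
        )
        self.disc = np.array([300.0, 300.0])
        self.fovea = np.array([100.0, 300.0])

    def test_first_locus_is_temporal(self):
        centers = peripapillary_loci(self.disc, self.fovea, self.boundary)
        direction = (centers[0] - self.disc) / np.linalg.norm(centers[0] - self.disc)
        assert direction == pytest.approx([-1.0, 0.0], abs=1e-9)

    def test_angular_gaps_are_45_degrees(self):
        centers = peripapillary_loci(self.disc, self.fovea, self.boundary)
        angles = np.degrees(
            np.arctan2(*(centers - self.disc).T[::-1])
        )  # atan2(y, x)
        gaps = np.diff(np.sort(angles % 360.0))
        assert np.allclose(gaps, 45.0, atol=1e-9)

    def test_ring_radius_tangent_to_disc(self):
        centers = peripapillary_loci(self.disc, self.fovea, self.boundary)
        radii = np.linalg.norm(centers - self.disc, axis=1)
        # brute-force boundary extent: max half-width over many directions
        max_semi = max(
            (
                (self.boundary @ [np.cos(a), np.sin(a)]).max()
                - (self.boundary @ [np.cos(a), np.sin(a)]).min()
            )
            / 2
            for a in np.linspace(0, np.pi, 3600, endpoint=False)
        )
        assert np.allclose(radii, max_semi + 48.0, atol=1e-6)


@pytest.fixture(scope="module")
def rendered_scene():
    config = CohortConfig(n_subjects=4, seed=99)
    subject = sample_covariates(config)[0]
    scene = sample_scene(subject, config)
    image, landmarks = render_image(scene, config.image_size)
    return scene, image, landmarks


class TestExtractFeatures:
    def test_42_parameters_in_frozen_order(self, rendered_scene):
        _, image, landmarks = rendered_scene
        fv = extract_features(image, landmarks)
        assert len(fv) == 42
        assert fv.names == FEATURE_NAMES

    def test_idempotent_bit_identical(self, rendered_scene):
        _, image, landmarks = rendered_scene
        first = extract_features(image, landmarks)
        second = extract_features(image, landmarks)
        assert first.values.tobytes() == second.values.tobytes()

    def test_channel_fraction_conservation(self, rendered_scene):
        _, image, landmarks = rendered_scene
        fv = extract_features(image, landmarks).to_series()
        for locus in ("L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8", "F"):
            total = fv[f"{locus}_R"] + fv[f"{locus}_G"] + fv[f"{locus}_B"]
            fractions = sum(fv[f"{locus}_{c}"] / total for c in "RGB")
            assert abs(fractions - 1.0) < 1e-12

    def test_missing_landmark_is_named(self, rendered_scene):
        _, image, landmarks = rendered_scene
        payload = landmarks.to_dict()
        del payload["fovea"]
        with pytest.raises(MissingLandmarkError, match="fovea"):
            LandmarkSet.from_dict(payload)
        crossings = dict(landmarks.crossings)
        del crossings["IT_VA"]
        broken = LandmarkSet(
            landmarks.disc_center, landmarks.fovea, landmarks.disc_boundary, crossings
        )
        with pytest.raises(MissingLandmarkError, match="IT_VA"):
            extract_features(image, broken)

    def test_half_turn_rotation_consistency(self, rendered_scene):
        """A 180-degree rotation of image + landmarks preserves the angle
        magnitudes (the temporal reference follows the fovea's side) and the
        ovality ratio."""
        _, image, landmarks = rendered_scene
        h, w = image.shape[:2]
        rotated_img = image[::-1, ::-1].copy()

        def rot(p):
            p = np.atleast_2d(p)
            return np.column_stack([w - 1 - p[:, 0], h - 1 - p[:, 1]]).squeeze()

        rotated = LandmarkSet(
            disc_center=rot(landmarks.disc_center),
            fovea=rot(landmarks.fovea),
            disc_boundary=rot(landmarks.disc_boundary),
            crossings={
                # ST/IT swap sides under a half turn
                "ST_RA": rot(landmarks.crossings["IT_RA"]),
                "IT_RA": rot(landmarks.crossings["ST_RA"]),
                "ST_VA": rot(landmarks.crossings["IT_VA"]),
                "IT_VA": rot(landmarks.crossings["ST_VA"]),
            },
        )
        base = extract_features(image, landmarks).to_series()
        turned = extract_features(rotated_img, rotated).to_series()
        for st, it in (("st_ra", "it_ra"), ("st_va", "it_va")):
            assert turned[st] == pytest.approx(base[it], abs=1e-6)
            assert turned[it] == pytest.approx(base[st], abs=1e-6)
        assert turned["pmp"] == pytest.approx(-base["pmp"], abs=1e-6)
        assert turned["ovality_ratio"] == pytest.approx(base["ovality_ratio"], abs=1e-6)

    def test_quarter_turn_preserves_ovality(self, rendered_scene):
        _, _, landmarks = rendered_scene
        boundary = landmarks.disc_boundary
        quarter = np.column_stack([-boundary[:, 1], boundary[:, 0]])
        assert ovality_ratio(quarter) == pytest.approx(
            ovality_ratio(boundary), abs=1e-9
        )
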