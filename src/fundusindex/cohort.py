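"""Synthetic right-eye fundus cohort generator.

Because population fundus photograph datasets with covariates are rarely
deposited, this module generates a cohort with *known* ground truth: subject
covariates (sex, age, body height, axial length) drawn from per-sex Gaussian
distributions, plus a renderable fundus "scene" per subject whose geometric
and colorimetric parameters carry configurable standardized sex differences
and a shared latent factor that couples the fundus appearance to axial
length within each sex.

Construction of the scene parameters, on a standardized (z) scale:

    z_j = (d_j / 2) * s  +  l_j * u  +  noise_sd * sqrt(1 - l_j^2) * eps_j

where s = +1 for men and -1 for women, d_j is the configured standardized
male-minus-female difference of parameter j, u ~ N(0,1) is the per-subject
latent factor, and eps_j ~ N(0,1) i.i.d.  Axial length is

    AL = mu_sex + sigma_sex * (rho * u + sqrt(1 - rho^2) * e)

so that corr(u, AL) = rho within each sex (config field ``index_axial_rho``).
By default the latent loadings l point along the *feminizing* direction
-d/|d|, scaled by ``latent_strength``, so a negative rho couples a more
masculine fundus to a longer eye, the direction reported for adult cohorts.

The optimal (Bayes) linear discriminant for sex on the z scale has
AUC = Phi(sqrt(d' Sigma^-1 d) / sqrt(2)) with Sigma = diag(noise variances)
+ l l'; by default the effect pattern is scaled once so this oracle AUC is
0.815, the separability implied by the reference cohort's index summary
(0.35 +/- 0.23 vs 0.64 +/- 0.23).

Rendering produces an 8-bit RGB image plus the exact landmark annotations:
a bright disc ellipse (major axis vertical, minor/major = ovality ratio),
four straight vessel rays crossing the 208-px measurement circle at the
configured angles, and flat-painted sampling disks so that circle-sampled
channel means equal the scene's color truth up to 8-bit quantization.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, GeometryError
from .features import (
    FEATURE_NAMES,
    FOVEAL_CIRCLE_DIAMETER,
    MEASUREMENT_CIRCLE_DIAMETER,
    PERIPAPILLARY_CIRCLE_DIAMETER,
    PERIPAPILLARY_LOCI,
    FeatureVector,
    LandmarkSet,
    peripapillary_loci,
)

SEXES = ("male", "female")

# Fixed rendering geometry (pixels). The disc sits nasally with the fovea
# temporal to it; sizes chosen so a ~30-degree field at 768 px gives a
# realistic disc diameter (~160 px) and the 8 tangent sampling circles do
# not overlap (ring radius 128 -> adjacent center gap 98 px > 96 px).
DISC_SEMI_MAJOR = 80.0
FOVEA_DISC_DISTANCE = 300.0
DISC_CENTER_FRACTION = (0.60, 0.50)
N_BOUNDARY_POINTS = 64

#: Scene parameters: name -> (baseline, per-unit-z scale). Ovality uses a
#: squashing map instead (see _ovality_from_z) to stay inside (0, 1].
_ANGLE_PARAMS = {
    "st_ra": (66.0, 7.0),
    "it_ra": (64.0, 7.0),
    "st_va": (70.0, 6.0),
    "it_va": (68.0, 6.0),
}
_PMP_PARAMS = (6.0, 3.0)
_PERI_COLOR_PARAMS = {"R": (175.0, 12.0), "G": (88.0, 10.0), "B": (62.0, 8.0)}
_FOVEA_COLOR_PARAMS = {"R": (150.0, 12.0), "G": (66.0, 9.0), "B": (46.0, 7.0)}
_OVALITY_A, _OVALITY_B = 2.0, 0.3

SCENE_PARAM_NAMES: tuple[str, ...] = (
    "st_ra",
    "it_ra",
    "st_va",
    "it_va",
    "pmp",
    "ovality",
) + tuple(
    f"{locus}_{channel}"
    for locus in PERIPAPILLARY_LOCI + ("F",)
    for channel in ("R", "G", "B")
)

#: Direction of the default sex effects (male minus female, standardized):
#: men have rounder discs, steeper (further-from-fovea) temporal vessels and
#: stronger peripapillary tessellation (more red); women higher green/blue.
DEFAULT_EFFECT_PATTERN: dict[str, float] = {
    "st_ra": 0.40,
    "it_ra": 0.30,
    "st_va": 0.25,
    "it_va": 0.20,
    "ovality": 0.50,
    "F_G": -0.25,
    **{f"{locus}_R": 0.15 for locus in PERIPAPILLARY_LOCI},
    **{f"{locus}_G": -0.35 for locus in PERIPAPILLARY_LOCI},
    **{f"{locus}_B": -0.25 for locus in PERIPAPILLARY_LOCI},
}


def _ovality_from_z(z):
    """Map a standardized score to an ovality ratio in (0, 1)."""
    return 1.0 - np.exp(-(_OVALITY_A + _OVALITY_B * np.asarray(z)))


def ovality_group_mean(z_mean: float, z_sd: float = 1.0) -> float:
    """Closed-form E[ovality] when z ~ N(z_mean, z_sd^2) (lognormal moment)."""
    return 1.0 - np.exp(-_OVALITY_A - _OVALITY_B * z_mean + (_OVALITY_B * z_sd) ** 2 / 2.0)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Per-sex covariate means/SDs default to the reference adult population
    cohort (men/women): height 163.7+/-6.3 / 151.1+/-5.8 cm, axial length
    23.71+/-0.83 / 23.28+/-0.88 mm, age 52.8+/-9.4 / 54.0+/-10.8 years.
    """

    n_subjects: int = 1653
    sex_ratio: float = 838.0 / 1653.0  # fraction male
    seed: int = 20050501
    height_params: dict = field(
        default_factory=lambda: {"male": (163.7, 6.3), "female": (151.1, 5.8)}
    )
    axial_params: dict = field(
        default_factory=lambda: {"male": (23.71, 0.83), "female": (23.28, 0.88)}
    )
    age_params: dict = field(
        default_factory=lambda: {"male": (52.8, 9.4), "female": (54.0, 10.8)}
    )
    #: per-parameter standardized male-minus-female differences; None ->
    #: DEFAULT_EFFECT_PATTERN scaled so the oracle AUC equals oracle_auc.
    feature_effect_sizes: dict | None = None
    oracle_auc: float = 0.815
    #: latent-factor loadings per parameter; None -> -latent_strength * d/|d|.
    latent_loadings: dict | None = None
    latent_strength: float = 0.6
    #: within-sex correlation between the latent factor and axial length.
    index_axial_rho: float = -0.13
    noise_sd: float = 1.0
    image_size: int = 768
    trunc_sd: float = 4.0

    # ---- derived vectors -------------------------------------------------

    def _as_vector(self, mapping: dict, what: str) -> np.ndarray:
        unknown = set(mapping) - set(SCENE_PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown {what} entries: {sorted(unknown)}")
        return np.array([float(mapping.get(name, 0.0)) for name in SCENE_PARAM_NAMES])

    def effect_vector(self) -> np.ndarray:
        """Standardized male-minus-female differences, aligned with SCENE_PARAM_NAMES."""
        if self.feature_effect_sizes is not None:
            return self._as_vector(self.feature_effect_sizes, "feature_effect_sizes")
        pattern = self._as_vector(DEFAULT_EFFECT_PATTERN, "feature_effect_sizes")
        return calibrate_effect_sizes(
            pattern, self.oracle_auc, self.loading_vector_for(pattern), self.noise_sd
        )

    def loading_vector_for(self, effects: np.ndarray) -> np.ndarray:
        if self.latent_loadings is not None:
            loadings = self._as_vector(self.latent_loadings, "latent_loadings")
        else:
            norm_d = np.linalg.norm(effects)
            loadings = (
                -self.latent_strength * effects / norm_d
                if norm_d > 0
                else np.zeros_like(effects)
            )
        if np.any(np.abs(loadings) >= 1.0):
            raise ConfigurationError("latent loadings must have magnitude < 1")
        return loadings

    def loading_vector(self) -> np.ndarray:
        return self.loading_vector_for(self.effect_vector())

    # ---- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be at least 2")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ConfigurationError("sex_ratio must lie strictly between 0 and 1")
        for name, params in (
            ("height_params", self.height_params),
            ("axial_params", self.axial_params),
            ("age_params", self.age_params),
        ):
            for sex in SEXES:
                if sex not in params:
                    raise ConfigurationError(f"{name} missing entry for {sex!r}")
                mean, sd = params[sex]
                if not np.isfinite(mean) or not np.isfinite(sd) or sd <= 0:
                    raise ConfigurationError(f"{name}[{sex!r}] needs finite mean and SD > 0")
        if not -1.0 < self.index_axial_rho < 1.0:
            raise ConfigurationError("index_axial_rho must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.5 <= self.oracle_auc < 1.0:
            raise ConfigurationError("oracle_auc must lie in [0.5, 1)")
        self.effect_vector()  # raises on unknown names
        self._check_geometry()

    def _check_geometry(self) -> None:
        """Worst-case check that all sampling circles fit in the image."""
        s = self.image_size
        cx, cy = DISC_CENTER_FRACTION[0] * s, DISC_CENTER_FRACTION[1] * s
        ring_outer = DISC_SEMI_MAJOR + PERIPAPILLARY_CIRCLE_DIAMETER
        pmp_max = np.radians(
            abs(_PMP_PARAMS[0]) + 5.0 * _PMP_PARAMS[1]
        )  # generous PMP envelope
        fovea_x = cx - FOVEA_DISC_DISTANCE * np.cos(pmp_max)
        fovea_dy = FOVEA_DISC_DISTANCE * np.sin(pmp_max)
        margin = FOVEAL_CIRCLE_DIAMETER / 2.0 + 2.0
        checks = [
            cx - ring_outer >= 0,
            cx + ring_outer <= s - 1,
            cy - ring_outer >= 0,
            cy + ring_outer <= s - 1,
            fovea_x - margin >= 0,
            cy + fovea_dy + margin <= s - 1,
            cy - fovea_dy - margin >= 0,
        ]
        if not all(checks):
            raise GeometryError(
                f"image_size={s} px cannot contain the disc sampling ring "
                f"(outer radius {ring_outer:.0f} px) and foveal circle"
            )


def oracle_auc_for(effects: np.ndarray, loadings: np.ndarray, noise_sd: float = 1.0) -> float:
    """Bayes AUC of the optimal linear sex discriminant on the z scale.

    Sigma = diag(noise_sd^2 (1 - l^2)) + l l'; AUC = Phi(sqrt(d'S^-1 d)/sqrt 2),
    evaluated with the Sherman-Morrison identity.
    """
    d = np.asarray(effects, dtype=float)
    l = np.asarray(loadings, dtype=float)
    if not d.any():
        return 0.5
    diag = noise_sd**2 * (1.0 - l**2)
    if np.any(diag <= 0):
        raise ConfigurationError("degenerate noise variance in oracle AUC")
    dinv_d = d / diag
    dinv_l = l / diag
    quad = d @ dinv_d - (l @ dinv_d) ** 2 / (1.0 + l @ dinv_l)
    return float(norm.cdf(np.sqrt(quad) / np.sqrt(2.0)))


def calibrate_effect_sizes(
    pattern: np.ndarray,
    target_auc: float,
    loadings: np.ndarray,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Scale an effect-direction pattern so the oracle AUC hits target_auc.

    Scaling the pattern leaves the (normalized) loading direction unchanged,
    so the Mahalanobis separation is linear in the scale factor.
    """
    pattern = np.asarray(pattern, dtype=float)
    if target_auc == 0.5 or not pattern.any():
        return np.zeros_like(pattern)
    current = oracle_auc_for(pattern, loadings, noise_sd)
    m_current = np.sqrt(2.0) * norm.ppf(current)
    m_target = np.sqrt(2.0) * norm.ppf(target_auc)
    return pattern * (m_target / m_current)


def oracle_auc(config: CohortConfig) -> float:
    """Oracle (Bayes) sex-discrimination AUC implied by a configuration."""
    effects = config.effect_vector()
    return oracle_auc_for(effects, config.loading_vector_for(effects), config.noise_sd)


@dataclass
class SubjectRecord:
    """One participant (right eye only)."""

    subject_id: str
    sex: str
    age: float
    height: float
    axial_length: float
    eye: str = "right"
    #: hidden simulation ground truth (latent factor), not written to the
    #: covariate CSV; kept for validation of the generator's contracts.
    latent: float = 0.0


@dataclass
class FundusScene:
    """Ground-truth renderable description of one right-eye fundus."""

    disc_center: np.ndarray
    disc_axes: tuple[float, float]  # (major, minor) semi-axes, px
    disc_tilt: float  # degrees from horizontal of the major axis
    fovea: np.ndarray
    vessel_truth: dict[str, float]  # ST_RA/IT_RA/ST_VA/IT_VA, degrees
    color_truth: dict[str, tuple[float, float, float]]  # locus -> (R, G, B)
    pmp: float = 0.0

    def __post_init__(self):
        self.disc_center = np.asarray(self.disc_center, dtype=float)
        self.fovea = np.asarray(self.fovea, dtype=float)
        major, minor = self.disc_axes
        if minor > major:
            raise GeometryError("disc minor semi-axis exceeds major")
        if np.array_equal(self.disc_center, self.fovea):
            raise GeometryError("fovea coincides with disc center")
        for vessel, angle in self.vessel_truth.items():
            if not 0.0 <= angle <= 90.0:
                raise GeometryError(f"vessel angle {vessel}={angle} outside [0, 90]")

    @property
    def ovality(self) -> float:
        return self.disc_axes[1] / self.disc_axes[0]

    def truth_features(self) -> FeatureVector:
        """The noise-free 42-parameter vector implied by this scene."""
        values = [self.vessel_truth[v] for v in ("ST_RA", "IT_RA", "ST_VA", "IT_VA")]
        values += [self.pmp, self.ovality]
        for locus in PERIPAPILLARY_LOCI + ("F",):
            r, g, b = self.color_truth[locus]
            values += [r, g, b, r / (r + g + b)]
        return FeatureVector(np.array(values))


def _truncated_normal(rng, mean, sd, trunc, size):
    """Gaussian draws re-sampled beyond +/- trunc SD."""
    draws = rng.standard_normal(size)
    bad = np.abs(draws) > trunc
    while bad.any():
        draws[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(draws) > trunc
    return mean + sd * draws


def sample_covariates(config: CohortConfig) -> list[SubjectRecord]:
    """Draw the subject table: sex, age, height, axial length, latent factor.

    Sex counts are deterministic (round(n * sex_ratio) men); the within-sex
    distributions are Gaussians truncated at +/- trunc_sd SD.  Axial length
    shares the latent factor u at correlation index_axial_rho.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_subjects
    n_male = int(round(n * config.sex_ratio))
    n_male = min(max(n_male, 1), n - 1)
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)

    rho = config.index_axial_rho
    records = []
    latent = rng.standard_normal(n)
    for i in range(n):
        sex = str(sexes[i])
        age = float(_truncated_normal(rng, *config.age_params[sex], config.trunc_sd, 1)[0])
        height = float(
            _truncated_normal(rng, *config.height_params[sex], config.trunc_sd, 1)[0]
        )
        mu, sd = config.axial_params[sex]
        eps = float(rng.standard_normal())
        # re-draw the residual (keeping u) if the combined z-score is extreme
        while abs(rho * latent[i] + np.sqrt(1 - rho**2) * eps) > config.trunc_sd:
            eps = float(rng.standard_normal())
        axial = mu + sd * (rho * latent[i] + np.sqrt(1 - rho**2) * eps)
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                sex=sex,
                age=round(age, 1),
                height=float(height),
                axial_length=float(axial),
                latent=float(latent[i]),
            )
        )
    return records


def covariates_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Covariate table with the external CSV schema."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "height_cm": [r.height for r in records],
            "axial_length_mm": [r.axial_length for r in records],
            "eye": [r.eye for r in records],
        }
    )


def _subject_rng(config: CohortConfig, subject: SubjectRecord):
    index = int(subject.subject_id.lstrip("S"))
    return np.random.default_rng([config.seed, 2, index])


def sample_scene(
    subject: SubjectRecord, config: CohortConfig, rng=None
) -> FundusScene:
    """Draw one subject's fundus scene from the configured per-sex distributions."""
    effects = config.effect_vector()
    loadings = config.loading_vector_for(effects)
    if rng is None:
        rng = _subject_rng(config, subject)
    s = 1.0 if subject.sex == "male" else -1.0
    eps = rng.standard_normal(len(SCENE_PARAM_NAMES))
    z = (
        0.5 * effects * s
        + loadings * subject.latent
        + config.noise_sd * np.sqrt(1.0 - loadings**2) * eps
    )
    params = dict(zip(SCENE_PARAM_NAMES, z))

    vessel_truth = {
        name.upper(): float(np.clip(center + scale * params[name], 1.0, 89.0))
        for name, (center, scale) in _ANGLE_PARAMS.items()
    }
    pmp = float(np.clip(_PMP_PARAMS[0] + _PMP_PARAMS[1] * params["pmp"], -30.0, 30.0))
    ovality = float(np.clip(_ovality_from_z(params["ovality"]), 1e-3, 1.0 - 1e-9))

    color_truth = {}
    for locus in PERIPAPILLARY_LOCI:
        color_truth[locus] = tuple(
            float(np.clip(center + scale * params[f"{locus}_{ch}"], 5.0, 250.0))
            for ch, (center, scale) in _PERI_COLOR_PARAMS.items()
        )
    color_truth["F"] = tuple(
        float(np.clip(center + scale * params[f"F_{ch}"], 5.0, 250.0))
        for ch, (center, scale) in _FOVEA_COLOR_PARAMS.items()
    )

    size = config.image_size
    cx, cy = DISC_CENTER_FRACTION[0] * size, DISC_CENTER_FRACTION[1] * size
    pmp_rad = np.radians(pmp)
    fovea = np.array(
        [
            cx - FOVEA_DISC_DISTANCE * np.cos(pmp_rad),
            cy + FOVEA_DISC_DISTANCE * np.sin(pmp_rad),  # +y is inferior
        ]
    )
    return FundusScene(
        disc_center=np.array([cx, cy]),
        disc_axes=(DISC_SEMI_MAJOR, DISC_SEMI_MAJOR * ovality),
        disc_tilt=90.0,
        fovea=fovea,
        vessel_truth=vessel_truth,
        color_truth=color_truth,
        pmp=pmp,
    )


# ---------------------------------------------------------------------------
# rendering


_BACKGROUND = np.array([168, 84, 56], dtype=np.uint8)
_MACULA_SHADE = np.array([150, 70, 46], dtype=np.uint8)
_DISC_COLOR = np.array([235, 180, 120], dtype=np.uint8)
_VESSEL_COLORS = {"RA": np.array([175, 45, 40]), "VA": np.array([120, 25, 30])}


def _paint_disk(img, center, radius, color):
    h, w = img.shape[:2]
    cx, cy = float(center[0]), float(center[1])
    x0, x1 = max(int(cx - radius) - 1, 0), min(int(cx + radius) + 2, w)
    y0, y1 = max(int(cy - radius) - 1, 0), min(int(cy + radius) + 2, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius * radius
    img[y0:y1, x0:x1][mask] = color


def render_image(scene: FundusScene, image_size: int = 768):
    """Rasterize a scene; returns (uint8 RGB array, LandmarkSet).

    Sampling regions (the 8 peripapillary disks and the foveal disk) are
    painted flat *after* the vasculature, so their circle-sampled means equal
    the scene color truth up to quantization; the measurement geometry lives
    in the emitted landmarks, not in image content.
    """
    size = int(image_size)
    cx, cy = scene.disc_center
    major, minor = scene.disc_axes
    ring_outer = major + PERIPAPILLARY_CIRCLE_DIAMETER
    fovea_margin = FOVEAL_CIRCLE_DIAMETER / 2.0 + 2.0
    extents = [
        cx - ring_outer,
        cy - ring_outer,
        scene.fovea[0] - fovea_margin,
        scene.fovea[1] - fovea_margin,
    ]
    upper = [
        cx + ring_outer,
        cy + ring_outer,
        scene.fovea[0] + fovea_margin,
        scene.fovea[1] + fovea_margin,
    ]
    if min(extents) < 0 or max(upper) > size - 1:
        raise GeometryError(
            f"scene does not fit in a {size}x{size} image "
            "(sampling circle exceeds image bounds)"
        )

    img = np.empty((size, size, 3), dtype=np.uint8)
    img[:] = _BACKGROUND
    _paint_disk(img, scene.fovea, 55.0, _MACULA_SHADE)

    # optic disc: filled ellipse, major axis vertical
    x0, x1 = int(cx - major) - 1, int(cx + major) + 2
    y0, y1 = int(cy - major) - 1, int(cy + major) + 2
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = ((xs - cx) / minor) ** 2 + ((ys - cy) / major) ** 2 <= 1.0
    img[y0:y1, x0:x1][inside] = _DISC_COLOR

    # temporal unit vector (toward the fovea's side) and vessel rays
    tx = np.sign(scene.fovea[0] - cx)
    for vessel, angle in scene.vessel_truth.items():
        theta = np.radians(angle)
        vertical = -1.0 if vessel.startswith("ST") else 1.0  # up for ST
        direction = np.array([tx * np.cos(theta), vertical * np.sin(theta)])
        radii = np.arange(minor * 0.4, ring_outer + 40.0, 0.7)
        points = scene.disc_center + radii[:, None] * direction
        color = _VESSEL_COLORS[vessel[-2:]]
        for px, py in points:
            _paint_disk(img, (px, py), 1.6, color)

    # landmark boundary polygon of the disc ellipse
    t = np.linspace(0.0, 2.0 * np.pi, N_BOUNDARY_POINTS, endpoint=False)
    boundary = np.stack([cx + minor * np.cos(t), cy + major * np.sin(t)], axis=1)

    # flat-painted sampling disks (placed by the same rule extraction uses)
    centers = peripapillary_loci(scene.disc_center, scene.fovea, boundary)
    paint_radius = PERIPAPILLARY_CIRCLE_DIAMETER / 2.0 + 1.5
    for locus, center in zip(PERIPAPILLARY_LOCI, centers):
        color = np.round(scene.color_truth[locus]).astype(np.uint8)
        _paint_disk(img, center, paint_radius, color)
    fovea_color = np.round(scene.color_truth["F"]).astype(np.uint8)
    _paint_disk(img, scene.fovea, FOVEAL_CIRCLE_DIAMETER / 2.0 + 1.5, fovea_color)

    # crossing landmarks on the measurement circle, exact
    radius = MEASUREMENT_CIRCLE_DIAMETER / 2.0
    crossings = {}
    for vessel, angle in scene.vessel_truth.items():
        theta = np.radians(angle)
        vertical = -1.0 if vessel.startswith("ST") else 1.0
        crossings[vessel] = scene.disc_center + radius * np.array(
            [tx * np.cos(theta), vertical * np.sin(theta)]
        )

    landmarks = LandmarkSet(
        disc_center=scene.disc_center.copy(),
        fovea=scene.fovea.copy(),
        disc_boundary=boundary,
        crossings=crossings,
    )
    landmarks.validate(image_shape=img.shape)
    return img, landmarks


def simulate_cohort(config: CohortConfig):
    """Covariates plus noise-free scene-truth features for every subject.

    Returns (records, covariates DataFrame, features DataFrame).  Rendering
    and re-extraction add only sub-quantization error on top of these truth
    features; statistical stages may therefore run on either.
    """
    records = sample_covariates(config)
    features = {}
    for record in records:
        scene = sample_scene(record, config)
        features[record.subject_id] = scene.truth_features()
    frame = pd.DataFrame(
        {sid: fv.values for sid, fv in features.items()}, index=list(FEATURE_NAMES)
    ).T
    frame.index.name = "subject_id"
    return records, covariates_frame(records), frame


def null_config(**overrides) -> CohortConfig:
    """A configuration with no sex effects on any fundus parameter."""
    cfg = CohortConfig(feature_effect_sizes={}, **overrides)
    return cfg


def config_from_dict(payload: dict) -> CohortConfig:
    """Build a CohortConfig from a plain mapping (YAML/JSON), strictly."""
    payload = copy.deepcopy(payload)
    valid = set(CohortConfig.__dataclass_fields__)
    unknown = set(payload) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("height_params", "axial_params", "age_params"):
        if key in payload:
            payload[key] = {
                sex: tuple(map(float, value)) for sex, value in payload[key].items()
            }
    cfg = CohortConfig(**payload)
    cfg.validate()
    return cfg
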