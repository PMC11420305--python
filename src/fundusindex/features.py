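"""Quantification of color fundus photograph (CFP) parameters.

A single right-eye fundus photograph, together with a manually annotated
landmark set (optic-disc boundary, disc center, fovea, and the points where
the four major temporal vessels cross a measurement circle around the disc),
is reduced to 42 ordered scalar parameters:

* four vessel angles (supratemporal/infratemporal artery and vein, ST-RA,
  IT-RA, ST-VA, IT-VA) measured against the temporal horizontal line,
* the papillomacular position (PMP), the signed angle between the horizontal
  and the disc-center-to-fovea line,
* the optic-disc ovality ratio (minimum disc diameter / maximum),
* mean red, green, blue intensity and the tessellation fundus index
  TFI = R/(R+G+B) in eight peripapillary sampling circles (L1..L8, L1
  temporal) and one foveal circle (F): 9 loci x 4 values.

Pixel conventions: 0-based integer pixel centers, origin top-left, y grows
downward.  "Temporal" is the horizontal direction from the disc center
toward the fovea's side, so no left/right image orientation is assumed.
The "208-pixel" measurement circle and "96-/32-pixel" sampling circles are
interpreted as circle *diameters* in pixels (configurable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, MissingLandmarkError, UndefinedValueError

# Circle sizes are diameters in pixels.
MEASUREMENT_CIRCLE_DIAMETER = 208.0
PERIPAPILLARY_CIRCLE_DIAMETER = 96.0
FOVEAL_CIRCLE_DIAMETER = 32.0

VESSEL_IDS = ("ST_RA", "IT_RA", "ST_VA", "IT_VA")
PERIPAPILLARY_LOCI = ("L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8")
LOCI = PERIPAPILLARY_LOCI + ("F",)

#: Frozen column order of the 42-parameter feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    "st_ra",
    "it_ra",
    "st_va",
    "it_va",
    "pmp",
    "ovality_ratio",
) + tuple(f"{locus}_{channel}" for locus in LOCI for channel in ("R", "G", "B", "TFI"))

assert len(FEATURE_NAMES) == 42


@dataclass
class RGBSample:
    """Mean channel intensities over one sampling circle."""

    R: float
    G: float
    B: float
    n_pixels: int


@dataclass
class LandmarkSet:
    """Annotated geometry of one fundus image.

    crossings maps a vessel id (ST_RA, IT_RA, ST_VA, IT_VA) to the pixel
    point where that vessel crosses the measurement circle around the disc.
    """

    disc_center: np.ndarray
    fovea: np.ndarray
    disc_boundary: np.ndarray
    crossings: dict[str, np.ndarray]

    def __post_init__(self):
        self.disc_center = np.asarray(self.disc_center, dtype=float)
        self.fovea = np.asarray(self.fovea, dtype=float)
        self.disc_boundary = np.asarray(self.disc_boundary, dtype=float)
        self.crossings = {k: np.asarray(v, dtype=float) for k, v in self.crossings.items()}

    def validate(self, image_shape=None,
                 measurement_diameter: float = MEASUREMENT_CIRCLE_DIAMETER) -> None:
        """Check completeness and geometric consistency; raise on violation."""
        if self.disc_boundary.ndim != 2 or self.disc_boundary.shape[0] < 8:
            raise GeometryError("disc_boundary needs at least 8 points")
        for vessel in VESSEL_IDS:
            if vessel not in self.crossings:
                raise MissingLandmarkError(vessel)
        radius = measurement_diameter / 2.0
        for vessel, point in self.crossings.items():
            r = float(np.hypot(*(point - self.disc_center)))
            if abs(r - radius) > 1.0:
                raise GeometryError(
                    f"{vessel} crossing at radius {r:.2f} px, expected "
                    f"{radius:.1f} +/- 1 px from disc center"
                )
            if vessel.startswith("ST") and point[1] >= self.disc_center[1]:
                raise GeometryError(f"{vessel} crossing must lie above the disc center")
            if vessel.startswith("IT") and point[1] <= self.disc_center[1]:
                raise GeometryError(f"{vessel} crossing must lie below the disc center")
        if image_shape is not None:
            h, w = image_shape[:2]
            points = np.vstack(
                [self.disc_boundary, self.disc_center, self.fovea]
                + [self.crossings[v] for v in VESSEL_IDS]
            )
            if (points < -0.5).any() or (points[:, 0] > w - 0.5).any() or (
                points[:, 1] > h - 0.5
            ).any():
                raise GeometryError("landmark outside image bounds")

    def to_dict(self) -> dict:
        return {
            "disc_center": list(self.disc_center),
            "fovea": list(self.fovea),
            "disc_boundary": [list(p) for p in self.disc_boundary],
            "crossings": {k: list(v) for k, v in self.crossings.items()},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "LandmarkSet":
        for key in ("disc_center", "fovea", "disc_boundary", "crossings"):
            if key not in payload:
                raise MissingLandmarkError(key)
        return cls(
            disc_center=payload["disc_center"],
            fovea=payload["fovea"],
            disc_boundary=payload["disc_boundary"],
            crossings=payload["crossings"],
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FeatureVector:
    """The 42 ordered fundus parameters of one eye."""

    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} feature values, got {self.values.shape}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _temporal_unit(disc_center, fovea) -> np.ndarray:
    """Horizontal unit vector from the disc center toward the fovea's side."""
    dx = float(fovea[0]) - float(disc_center[0])
    if dx == 0.0:
        raise GeometryError(
            "fovea lies directly above/below the disc center; temporal side undefined"
        )
    return np.array([np.sign(dx), 0.0])


def vessel_angle(crossing, disc_center, fovea) -> float:
    """Unsigned angle (degrees, [0, 180)) between the disc-center->crossing ray
    and the temporal horizontal line."""
    crossing = np.asarray(crossing, dtype=float)
    disc_center = np.asarray(disc_center, dtype=float)
    v = crossing - disc_center
    if not np.any(v):
        raise GeometryError("crossing point coincides with disc center")
    u = _temporal_unit(disc_center, fovea)
    cross = abs(u[0] * v[1] - u[1] * v[0])
    dot = float(u @ v)
    angle = np.degrees(np.arctan2(cross, dot))
    return float(angle % 180.0)


def papillomacular_position(disc_center, fovea) -> float:
    """Signed angle (degrees) between the horizontal and the disc-to-fovea line.

    Positive when the fovea is inferior to (below, image-down) the disc-center
    horizontal; magnitude at most 90.
    """
    disc_center = np.asarray(disc_center, dtype=float)
    fovea = np.asarray(fovea, dtype=float)
    v = fovea - disc_center
    if not np.any(v):
        raise GeometryError("fovea coincides with disc center")
    along = abs(v[0])  # distance along the temporal horizontal, side-agnostic
    down = v[1]
    return float(np.degrees(np.arctan2(down, along)))


def _directional_widths(points: np.ndarray, n_directions: int) -> np.ndarray:
    """Width of a point set (max - min projection) along n_directions in [0, pi)."""
    theta = np.linspace(0.0, np.pi, n_directions, endpoint=False)
    directions = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    proj = points @ directions.T
    return proj.max(axis=0) - proj.min(axis=0)


def ovality_ratio(disc_boundary, n_directions: int = 3600) -> float:
    """Minimum disc diameter divided by maximum (directional widths)."""
    points = np.asarray(disc_boundary, dtype=float)
    if points.ndim != 2 or points.shape[0] < 8:
        raise GeometryError("ovality ratio needs at least 8 boundary points")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0.0 or s[1] <= 1e-9 * s[0]:
        raise GeometryError("boundary points are collinear")
    widths = _directional_widths(points, n_directions)
    return float(widths.min() / widths.max())


def sample_circle_mean(image, center, circle_diameter: float) -> RGBSample:
    """Mean R, G, B over pixels whose centers lie inside the given disk."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise GeometryError("expected an RGB image of shape (H, W, 3)")
    h, w = img.shape[:2]
    cx, cy = float(center[0]), float(center[1])
    r = circle_diameter / 2.0
    if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
        raise GeometryError(
            f"sampling circle (center=({cx:.1f},{cy:.1f}), d={circle_diameter}) "
            "extends outside the image"
        )
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    patch = img[y0 : y1 + 1, x0 : x1 + 1].astype(float)
    n = int(mask.sum())
    means = patch[mask].mean(axis=0)
    return RGBSample(R=float(means[0]), G=float(means[1]), B=float(means[2]), n_pixels=n)


def tessellation_index(sample: RGBSample) -> float:
    """TFI = R/(R+G+B) of a sampling circle's mean intensities."""
    total = sample.R + sample.G + sample.B
    if total <= 0:
        raise UndefinedValueError("TFI undefined: R+G+B is zero")
    return float(sample.R / total)


def peripapillary_loci(
    disc_center,
    fovea,
    disc_boundary,
    circle_diameter: float = PERIPAPILLARY_CIRCLE_DIAMETER,
    n_directions: int = 3600,
) -> np.ndarray:
    """Centers of the 8 peripapillary sampling circles.

    The circles sit on a ring concentric with the disc, tangent to the disc
    margin (ring radius = max disc semi-diameter + sampling-circle radius).
    L1 lies on the disc-center-to-fovea line; subsequent loci advance in
    45-degree steps counterclockwise as seen on the (right-eye) image.
    """
    disc_center = np.asarray(disc_center, dtype=float)
    fovea = np.asarray(fovea, dtype=float)
    boundary = np.asarray(disc_boundary, dtype=float)
    v = fovea - disc_center
    if not np.any(v):
        raise GeometryError("fovea coincides with disc center")
    max_semi = _directional_widths(boundary, n_directions).max() / 2.0
    ring_radius = max_semi + circle_diameter / 2.0
    a0 = np.arctan2(v[1], v[0])
    # y grows downward, so decreasing the mathematical angle advances
    # counterclockwise as seen on the displayed image.
    angles = a0 - np.arange(8) * (np.pi / 4.0)
    centers = disc_center + ring_radius * np.stack(
        [np.cos(angles), np.sin(angles)], axis=1
    )
    return centers


def extract_features(
    image,
    landmarks: LandmarkSet,
    peripapillary_diameter: float = PERIPAPILLARY_CIRCLE_DIAMETER,
    foveal_diameter: float = FOVEAL_CIRCLE_DIAMETER,
) -> FeatureVector:
    """Compute the 42 fundus parameters from an image and its landmarks.

    Deterministic: repeated runs on the same inputs are bit-identical.
    Raises MissingLandmarkError naming the first absent landmark.
    """
    for name in ("disc_center", "fovea", "disc_boundary", "crossings"):
        value = getattr(landmarks, name, None)
        if value is None or (hasattr(value, "__len__") and len(value) == 0):
            raise MissingLandmarkError(name)
    for vessel in VESSEL_IDS:
        if vessel not in landmarks.crossings:
            raise MissingLandmarkError(vessel)

    values = [
        vessel_angle(landmarks.crossings[v], landmarks.disc_center, landmarks.fovea)
        for v in VESSEL_IDS
    ]
    values.append(papillomacular_position(landmarks.disc_center, landmarks.fovea))
    values.append(ovality_ratio(landmarks.disc_boundary))

    centers = peripapillary_loci(
        landmarks.disc_center,
        landmarks.fovea,
        landmarks.disc_boundary,
        circle_diameter=peripapillary_diameter,
    )
    for center in centers:
        sample = sample_circle_mean(image, center, peripapillary_diameter)
        values += [sample.R, sample.G, sample.B, tessellation_index(sample)]
    sample = sample_circle_mean(image, landmarks.fovea, foveal_diameter)
    values += [sample.R, sample.G, sample.B, tessellation_index(sample)]

    return FeatureVector(np.array(values))


def features_to_frame(rows: dict[str, FeatureVector]) -> pd.DataFrame:
    """Assemble per-subject feature vectors into a table (frozen column order)."""
    frame = pd.DataFrame(
        {sid: fv.values for sid, fv in rows.items()}, index=list(FEATURE_NAMES)
    ).T
    frame.index.name = "subject_id"
    return frame
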