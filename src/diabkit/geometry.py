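"""Single-shot photo geometry: phone-to-food distance and projected area.

The measurement scenario is a phone leaning on a table at tilt ``alpha``
(read from the gyroscope), photographing food placed on the table in front
of it.  Working in the vertical plane through the phone, the phone--table
contact point is the origin O, x runs along the table toward the food and
y is vertical.  The camera sits at the top of the phone at

    A = (p cos(alpha), p sin(alpha)),

where ``p`` is the bottom-of-phone-to-camera length.  ``beta`` is the
phone-model constant angle between the phone body and the field-of-view
boundary ray that meets the table closest to the phone; that ray crosses
the table at B with

    l_OB = p sin(beta) / sin(alpha + beta).

A food whose image sits at fractional height ``k = a / b`` (a = pixels
from the bottom edge of the photo, b = total image length) is seen along a
ray that the pinhole model maps to a table point C; ``l_OC`` is the
shooting distance used as a regression feature for weight estimation.

Two distance modes exist.  The default mode is the standard pinhole
intersection (image plane perpendicular to the phone body, the bottom
image edge anchored to the boundary ray through B); it is validated
against an independent numerical ray-cast.  The literal mode reproduces a
published closed form that is dimensionally inconsistent in its
denominator, and is kept only so the disagreement can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhoneSpec",
    "ShotGeometry",
    "GeometrySolution",
    "SingularGeometryError",
    "ParallelRayError",
    "EmptyMaskError",
    "camera_position",
    "base_intersection",
    "image_point",
    "shooting_distance",
    "distance_from_image",
    "max_valid_k",
    "projected_area",
    "solve_shot",
]


class SingularGeometryError(ValueError):
    """alpha + beta hits pi (or the FOV construction is otherwise singular)."""


class ParallelRayError(ValueError):
    """The viewing ray never meets the table plane."""


class EmptyMaskError(ValueError):
    """A segmentation mask with no set pixels."""


@dataclass(frozen=True)
class PhoneSpec:
    """Phone-model constants.

    Parameters
    ----------
    p : float
        Distance from the bottom of the phone to the camera, metres.
    beta : float
        Camera field-offset angle (phone body to near FOV boundary ray),
        radians, in (0, pi/2).
    """

    p: float
    beta: float

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValueError(f"phone length p must be positive, got {self.p}")
        if not 0 < self.beta < math.pi / 2:
            raise ValueError(f"beta must lie in (0, pi/2), got {self.beta}")


@dataclass(frozen=True)
class ShotGeometry:
    """One photograph's pose and in-image food position.

    ``alpha`` is the tilt from the table in radians; ``a`` and ``b`` are the
    food-to-bottom distance and total image length in pixels, so
    ``k = a / b`` is the fractional image height of the food.
    """

    alpha: float
    a: float
    b: float
    image_size: tuple[int, int] | None = None
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= math.pi / 2:
            raise ValueError(f"alpha must lie in (0, pi/2], got {self.alpha}")
        if not 0 <= self.a <= self.b:
            raise ValueError(f"need 0 <= a <= b, got a={self.a}, b={self.b}")

    @property
    def k(self) -> float:
        return self.a / self.b

    @property
    def degenerate(self) -> bool:
        """True when the phone stands exactly vertical."""
        return self.alpha == math.pi / 2


@dataclass(frozen=True)
class GeometrySolution:
    """Derived geometry for one shot (metres / square metres)."""

    A: tuple[float, float]
    l_OB: float
    D: tuple[float, float]
    l_OC: float
    S: float | None = None
    degenerate: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)


def camera_position(spec: PhoneSpec, alpha: float) -> tuple[float, float]:
    """Camera coordinate A = (p cos(alpha), p sin(alpha))."""
    return (spec.p * math.cos(alpha), spec.p * math.sin(alpha))


def base_intersection(spec: PhoneSpec, alpha: float) -> float:
    """Distance l_OB where the near FOV boundary ray meets the table.

    l_OB = p sin(beta) / sin(alpha + beta); singular when alpha + beta = pi.
    """
    s = math.sin(alpha + spec.beta)
    if abs(s) < 1e-12:
        raise SingularGeometryError(
            f"alpha + beta = {alpha + spec.beta:.6f} rad makes the boundary "
            "ray parallel to the table"
        )
    return spec.p * math.sin(spec.beta) / s


def image_point(spec: PhoneSpec, shot: ShotGeometry) -> tuple[float, float]:
    """Literal published mapping from image fraction k to the point D.

    D = (2 p k sin(alpha) cos(beta) / sin(alpha+beta)) * (cos(alpha), sin(alpha)),
    exactly as printed.  Note this places D on the phone axis; it is kept
    for the literal audit mode only.
    """
    alpha = shot.alpha
    s = math.sin(alpha + spec.beta)
    if abs(s) < 1e-12:
        raise SingularGeometryError("sin(alpha + beta) vanishes")
    m = 2.0 * spec.p * shot.k * math.sin(alpha) * math.cos(spec.beta) / s
    return (m * math.cos(alpha), m * math.sin(alpha))


def shooting_distance(A: tuple[float, float], D: tuple[float, float]) -> float:
    """Intersect the line through A and D with the table plane y = 0.

    Returns the x-coordinate of the intersection:
    l_OC = x_A - y_A (x_D - x_A) / (y_D - y_A).
    """
    (xa, ya), (xd, yd) = A, D
    dy = yd - ya
    if abs(dy) < 1e-15:
        raise ParallelRayError(
            f"line through A={A} and D={D} is parallel to the table"
        )
    return xa - ya * (xd - xa) / dy


def _literal_distance(spec: PhoneSpec, alpha: float, k: float) -> float:
    """Published Eq-form shooting distance, evaluated exactly as printed:
    l_OC = y_D (x_D - x_A) / (y_D - x_A) + x_A.  Audit mode only."""
    xa, ya = camera_position(spec, alpha)
    xd, yd = image_point(spec, ShotGeometry(alpha=alpha, a=k, b=1.0))
    den = yd - xa
    if abs(den) < 1e-15:
        raise ParallelRayError("literal-mode denominator y_D - x_A vanishes")
    return yd * (xd - xa) / den + xa


def max_valid_k(spec: PhoneSpec, alpha: float) -> float:
    """Largest image fraction whose viewing ray still meets the table.

    The ray direction is n + (2k-1) cot(beta) u with n the optical axis and
    u the phone body; it points below the horizon iff
    (2k-1) cot(beta) sin(alpha) < cos(alpha).
    """
    limit = 0.5 * (1.0 + math.tan(spec.beta) / math.tan(alpha)) if alpha < math.pi / 2 else 0.5
    return min(1.0, limit)


def distance_from_image(
    spec: PhoneSpec, alpha: float, k: float, mode: str = "default"
) -> float:
    """Shooting distance l_OC for a food at image fraction k.

    ``mode="default"`` uses the pinhole closed form: camera at A, optical
    axis perpendicular to the phone body, image plane at unit focal length
    with vertical half-extent cot(beta) so the bottom edge ray passes
    through B.  ``mode="literal"`` evaluates the published formula as
    printed (see module docstring).
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"image fraction k must lie in [0, 1], got {k}")
    if mode == "literal":
        return _literal_distance(spec, alpha, k)
    if mode != "default":
        raise ValueError(f"unknown mode {mode!r}")
    xa, ya = camera_position(spec, alpha)
    ca, sa = math.cos(alpha), math.sin(alpha)
    # ray direction = optical axis + image-plane offset along the phone body
    s = (2.0 * k - 1.0) / math.tan(spec.beta)
    dx, dy = sa + s * ca, -ca + s * sa
    if dy >= -1e-15:
        raise ParallelRayError(
            f"viewing ray at k={k} does not descend to the table "
            f"(valid k < {max_valid_k(spec, alpha):.4f} at this tilt)"
        )
    t = -ya / dy
    return xa + t * dx


def projected_area(
    mask: np.ndarray, pixel_pitch: float
) -> tuple[float, float, float]:
    """Projected area S and image position (a, b) from a binary food mask.

    The mask is row-major with row 0 at the *top* of the photo (image
    convention); ``a`` is the distance in pixels from the mask centroid to
    the bottom edge and ``b`` the image length in pixels.

    Returns
    -------
    (S, a, b) : S = set-pixel count * pitch^2 in m^2.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if pixel_pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    on = mask != 0
    count = int(on.sum())
    if count == 0:
        raise EmptyMaskError("mask has no set pixels")
    rows = np.nonzero(on)[0]
    b = float(mask.shape[0])
    # centroid row measured from the bottom edge; pixel centres at row + 0.5
    a = b - (float(rows.mean()) + 0.5)
    return count * pixel_pitch**2, a, b


def solve_shot(
    spec: PhoneSpec,
    shot: ShotGeometry,
    mask: np.ndarray | None = None,
    mode: str = "default",
) -> GeometrySolution:
    """Full geometric solution for one shot."""
    A = camera_position(spec, shot.alpha)
    l_ob = base_intersection(spec, shot.alpha)
    D = image_point(spec, shot)
    l_oc = distance_from_image(spec, shot.alpha, shot.k, mode=mode)
    S = None
    notes: list[str] = []
    if mask is not None:
        if shot.pixel_pitch is None:
            raise ValueError("pixel_pitch required to convert a mask to area")
        S, _, _ = projected_area(mask, shot.pixel_pitch)
    if shot.degenerate:
        notes.append("vertical phone (alpha = pi/2)")
    return GeometrySolution(
        A=A, l_OB=l_ob, D=D, l_OC=l_oc, S=S,
        degenerate=shot.degenerate, notes=tuple(notes),
    )
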