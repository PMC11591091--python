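"""Synthetic tabletop scene generation with known geometric ground truth.

Foods are modelled as flat disks lying
on the table, photographed by the same leaning-phone pinhole camera that
:mod:`diabkit.geometry` solves analytically.  Because every scene is
generated with known food position, footprint area and mass, the module
doubles as the independent oracle for the closed-form geometry (the ray
caster here intersects rays numerically and shares no formula with
``geometry.distance_from_image``) and as the training-data source for the
food-weight regression.

Masses follow a per-type density law

    mass [g] = density_coefficient [g/m^2] * footprint area [m^2] * shape factor,

with multiplicative log-normal observation noise on the recorded weight
(sigma defaults to 5 %), emulating kitchen-scale labels on real photos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import ParallelRayError, PhoneSpec

__all__ = [
    "SyntheticFood",
    "SceneRecord",
    "PlacementError",
    "default_food_catalog",
    "raycast_distance",
    "render_scene",
    "make_cuisine_dataset",
    "DEFAULT_WEIGHT_NOISE_SD",
    "DEFAULT_ALPHA_RANGE",
]

DEFAULT_WEIGHT_NOISE_SD = 0.05
#: shooting-tilt range sampled for synthetic photo sessions, radians
DEFAULT_ALPHA_RANGE = (np.deg2rad(30.0), np.deg2rad(80.0))
#: radius jitter half-width (relative) applied per sample around the type base
RADIUS_JITTER = 0.2


class PlacementError(ValueError):
    """Food placed (partly) outside the camera field of view."""


@dataclass(frozen=True)
class SyntheticFood:
    """One food type: a disk footprint with a type-specific density law."""

    type_id: int
    footprint_radius: float  # m
    height: float  # m
    density_coefficient: float  # g per m^2 of footprint
    shape_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.footprint_radius, self.height,
               self.density_coefficient, self.shape_factor) <= 0:
            raise ValueError("food dimensions and density must be positive")

    @property
    def footprint_area(self) -> float:
        return float(np.pi * self.footprint_radius**2)

    @property
    def mean_mass(self) -> float:
        """Noise-free mass of the nominal footprint, grams."""
        return self.density_coefficient * self.footprint_area * self.shape_factor


@dataclass(frozen=True)
class SceneRecord:
    """One rendered scene with its ground truth."""

    food: SyntheticFood
    phone: PhoneSpec
    alpha: float
    l_OC: float          # true distance O -> food centre, m
    k: float             # true image fraction of the food centre
    mask: np.ndarray     # H x W uint8, nonzero = food
    S: float             # true footprint area, m^2
    weight: float        # noisy recorded weight, g
    true_weight: float   # noise-free mass, g
    pixel_pitch: float   # ground metres per pixel at the food centre
    seed: int


def default_food_catalog(n_types: int = 19, seed: int = 7) -> list[SyntheticFood]:
    """Deterministic catalogue of ``n_types`` disk foods.

    Radii 3-12 cm, heights 1-6 cm, densities 5-20 kg/m^2 — the range of a
    plated portion (e.g. r = 8 cm at 10 kg/m^2 is a ~200 g serving).
    """
    if n_types < 2:
        raise ValueError("need at least two food types")
    rng = np.random.default_rng(seed)
    foods = []
    for i in range(n_types):
        foods.append(
            SyntheticFood(
                type_id=i,
                footprint_radius=float(rng.uniform(0.03, 0.12)),
                height=float(rng.uniform(0.01, 0.06)),
                density_coefficient=float(rng.uniform(5_000.0, 20_000.0)),
                shape_factor=float(rng.uniform(0.6, 1.4)),
            )
        )
    return foods


# ---------------------------------------------------------------------------
# camera frame helpers (rotation-matrix construction; no closed-form reuse)
# ---------------------------------------------------------------------------

def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _camera_frame(spec: PhoneSpec, alpha: float):
    """Camera origin A, optical axis n, in-plane up u, and the image-plane
    vertical half-extent at unit focal length, built from rotations."""
    phone_dir = np.array([np.cos(alpha), np.sin(alpha)])
    A = spec.p * phone_dir
    down = -phone_dir
    axis = _rot2(np.pi / 2) @ down          # perpendicular to the phone, toward the scene
    up = -down
    half_extent = float(np.tan(np.pi / 2 - spec.beta))
    return A, axis, up, half_extent


def raycast_distance(spec: PhoneSpec, alpha: float, k: float) -> float:
    """Numerical table intersection of the viewing ray at image fraction k.

    Builds the ray through the image-plane point geometrically and finds
    the root of its height above the table with a bracketing solver;
    deliberately avoids the closed form in :mod:`diabkit.geometry`.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"image fraction k must lie in [0, 1], got {k}")
    A, axis, up, half_extent = _camera_frame(spec, alpha)
    target = A + axis + (2.0 * k - 1.0) * half_extent * up
    d = target - A
    if d[1] >= -1e-15:
        raise ParallelRayError(
            f"viewing ray at k={k} does not descend to the table"
        )
    height = lambda t: float(A[1] + t * d[1])
    t_hi = 2.0 * A[1] / -d[1] + 1.0
    t_star = brentq(height, 0.0, t_hi, xtol=1e-15, rtol=1e-15)
    return float(A[0] + t_star * d[0])


# ---------------------------------------------------------------------------
# 3-D rendering of the disk footprint
# ---------------------------------------------------------------------------

def _frame3(spec: PhoneSpec, alpha: float):
    A2, axis2, up2, half_extent = _camera_frame(spec, alpha)
    A = np.array([A2[0], A2[1], 0.0])
    axis = np.array([axis2[0], axis2[1], 0.0])
    up = np.array([up2[0], up2[1], 0.0])
    lat = np.array([0.0, 0.0, 1.0])
    return A, axis, up, lat, half_extent


def _project_ground_point(spec, alpha, point):
    """Ground point -> (v, h) fractional image coordinates (v=0 bottom)."""
    A, axis, up, lat, half = _frame3(spec, alpha)
    rel = np.asarray(point, dtype=float) - A
    depth = rel @ axis
    if depth <= 0:
        raise PlacementError("point behind the camera image plane")
    ov = (rel @ up) / depth
    oh = (rel @ lat) / depth
    v = (ov / half + 1.0) / 2.0
    h = (oh / half + 1.0) / 2.0
    return v, h


def render_scene(
    food: SyntheticFood,
    spec: PhoneSpec,
    alpha: float,
    placement: float,
    seed: int,
    resolution: tuple[int, int] = (120, 120),
    noise_sd: float = DEFAULT_WEIGHT_NOISE_SD,
) -> SceneRecord:
    """Render the binary footprint mask of one food placed ``placement``
    metres from the phone-contact origin, straight ahead of the camera.

    The mask is deterministic given the geometry; only the recorded weight
    depends on ``seed`` (log-normal noise, ``noise_sd`` defaulting to 5 %).
    """
    H, W = resolution
    r = food.footprint_radius
    centre = np.array([placement, 0.0, 0.0])
    # field-of-view check on the footprint's extreme points
    for probe in (
        centre,
        centre + [r, 0, 0], centre + [-r, 0, 0],
        centre + [0, 0, r], centre + [0, 0, -r],
    ):
        v, h = _project_ground_point(spec, alpha, probe)
        if not (0.0 <= v <= 1.0 and 0.0 <= h <= 1.0):
            raise PlacementError(
                f"food extent projects outside the image (v={v:.3f}, h={h:.3f})"
            )

    A, axis, up, lat, half = _frame3(spec, alpha)
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    v = 1.0 - (rows + 0.5) / H          # row 0 is the top of the photo
    h = (cols + 0.5) / W
    ov = (2.0 * v - 1.0) * half
    oh = (2.0 * h - 1.0) * half * (W / H)
    # ray directions through every pixel
    d = (axis[None, None, :]
         + ov[..., None] * up[None, None, :]
         + oh[..., None] * lat[None, None, :])
    dy = d[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dy < 0, -A[1] / dy, np.nan)
    gx = A[0] + t * d[..., 0]
    gz = A[2] + t * d[..., 2]
    inside = ((gx - centre[0]) ** 2 + (gz - centre[2]) ** 2) <= r**2
    mask = np.where(np.isfinite(t) & inside, 1, 0).astype(np.uint8)
    if mask.sum() == 0:
        raise PlacementError(
            "food footprint projects to no pixels at this resolution"
        )

    k_true, _ = _project_ground_point(spec, alpha, centre)
    # effective pitch: sqrt of the mean ground area one mask pixel covers,
    # from the projection Jacobian (perspective scale varies across the mask)
    dgx_r, dgx_c = np.gradient(gx)
    dgz_r, dgz_c = np.gradient(gz)
    cell = np.abs(dgx_r * dgz_c - dgz_r * dgx_c)
    pitch = float(np.sqrt(np.nanmean(np.where(mask > 0, cell, np.nan))))
    rng = np.random.default_rng(seed)
    true_mass = food.mean_mass
    weight = float(true_mass * np.exp(rng.normal(0.0, noise_sd)))
    return SceneRecord(
        food=food, phone=spec, alpha=alpha, l_OC=float(placement),
        k=float(k_true), mask=mask, S=float(np.pi * r**2),
        weight=weight, true_weight=float(true_mass),
        pixel_pitch=pitch, seed=seed,
    )


# ---------------------------------------------------------------------------
# cuisine dataset for the weight regression
# ---------------------------------------------------------------------------

def make_cuisine_dataset(
    n: int,
    n_types: int = 19,
    seed: int = 0,
    phone: PhoneSpec | None = None,
    noise_sd: float = DEFAULT_WEIGHT_NOISE_SD,
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
    catalog: list[SyntheticFood] | None = None,
) -> pd.DataFrame:
    """Synthetic photo-session table: columns type_id, alpha, l_OC, S, weight.

    Rows are stratified over the ``n_types`` food types (counts differing by
    at most one), shot tilts are uniform over ``alpha_range``, per-sample
    footprint radii jitter ±20 % around the type base radius, and weights
    carry multiplicative log-normal noise.  Fully reproducible from ``seed``.
    """
    if phone is None:
        phone = PhoneSpec(p=0.15, beta=np.deg2rad(25.0))
    foods = catalog if catalog is not None else default_food_catalog(n_types)
    if len(foods) != n_types:
        raise ValueError("catalog size must match n_types")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, n_types)
    counts = [base + (1 if i < extra else 0) for i in range(n_types)]
    rows = []
    for food, c in zip(foods, counts):
        for _ in range(c):
            alpha = rng.uniform(*alpha_range)
            # keep the viewing ray comfortably inside the valid range
            k_hi = _k_ceiling(phone, alpha)
            k = rng.uniform(0.05, 0.9) * k_hi
            l_oc = raycast_distance(phone, alpha, k)
            r = food.footprint_radius * (1.0 + rng.uniform(-RADIUS_JITTER, RADIUS_JITTER))
            S = np.pi * r**2
            true_mass = food.density_coefficient * S * food.shape_factor
            weight = true_mass * np.exp(rng.normal(0.0, noise_sd))
            rows.append((food.type_id, alpha, l_oc, S, weight, true_mass))
    df = pd.DataFrame(
        rows, columns=["type_id", "alpha", "l_OC", "S", "weight", "true_weight"]
    )
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def _k_ceiling(phone: PhoneSpec, alpha: float) -> float:
    """Numerically locate (by bisection on the ray caster's validity) the
    largest usable image fraction at this tilt."""
    lo, hi = 0.0, 1.0
    try:
        raycast_distance(phone, alpha, 1.0)
        return 1.0
    except ParallelRayError:
        pass
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        try:
            raycast_distance(phone, alpha, mid)
            lo = mid
        except ParallelRayError:
            hi = mid
    return lo


def expected_mean_weight(
    n_types: int = 19,
    noise_sd: float = DEFAULT_WEIGHT_NOISE_SD,
    catalog: list[SyntheticFood] | None = None,
) -> float:
    """Closed-form expectation of the cuisine-table weight column.

    E[weight] = mean_type( c_t * shape_t * pi * r_t^2 * E[(1+J)^2] ) * e^{s^2/2}
    with J ~ U(-0.2, 0.2), so E[(1+J)^2] = 1 + 0.2^2/3.
    """
    foods = catalog if catalog is not None else default_food_catalog(n_types)
    jitter_factor = 1.0 + RADIUS_JITTER**2 / 3.0
    per_type = [
        f.density_coefficient * f.shape_factor * np.pi * f.footprint_radius**2 * jitter_factor
        for f in foods
    ]
    return float(np.mean(per_type) * np.exp(noise_sd**2 / 2.0))
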