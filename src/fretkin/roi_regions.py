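"""Named-region definitions and mean-efficiency trace extraction.

The organizer scheme places nine circular ROIs of 20 um diameter on a
wing-pouch image: three along the anterior-posterior (AP) compartment
boundary, three along the dorsal-ventral (DV) boundary (the central
circle at the boundary intersection is shared by both), and four
"non-organizer" circles in the quadrants away from either boundary.
Composite regions are averaged ROI-wise:

* APB / DVB - mean of their three circle means,
* ORG       - mean of the five distinct organizer circle means,
* NO        - mean of the four non-organizer circle means.

Compartment analysis instead pools pixels over freehand dorsal/ventral
polygons, optionally split into anterior/posterior halves by the AP
boundary line (DA, DP, VA, VP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "RoiScheme", "RegionTrace", "make_roi_scheme", "circle_mask",
    "extract_trace", "organizer_traces", "compartment_traces",
    "load_landmarks",
]

ORGANIZER_ROLES = ("APB1", "APB2", "APB3", "DVB1", "DVB2", "DVB3")
NON_ORGANIZER_ROLES = ("NO1", "NO2", "NO3", "NO4")


@dataclass
class RegionTrace:
    """Mean FRET efficiency of one named region over time for one disc."""

    region: str
    disc_id: str
    times_min: np.ndarray
    mean_eta: np.ndarray
    #: valid pixels contributing per frame (ROI-count for composite regions)
    n_valid: np.ndarray

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.mean_eta = np.asarray(self.mean_eta, dtype=float)
        self.n_valid = np.asarray(self.n_valid)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        finite = self.mean_eta[np.isfinite(self.mean_eta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("mean efficiency must lie in [0, 1] where defined")


@dataclass(frozen=True)
class RoiScheme:
    """Nine-circle organizer scheme plus compartment landmarks.

    ``circles`` maps role names (APB1..3, DVB1..3, NO1..4) to (row, col)
    pixel centers; APB2 and DVB2 share the central center by construction.
    """

    circles: dict[str, tuple[float, float]]
    diameter_um: float
    pixel_size_um: float
    image_shape: tuple[int, int]
    dorsal_polygon: np.ndarray | None = None
    ventral_polygon: np.ndarray | None = None
    #: AP boundary line: (point, direction) in (row, col) pixel coords;
    #: anterior is the side to the left of the direction vector.
    ap_line: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        missing = [r for r in ORGANIZER_ROLES + NON_ORGANIZER_ROLES
                   if r not in self.circles]
        if missing:
            raise ValueError(f"scheme is missing circles: {missing}")
        distinct = {tuple(np.round(c, 6)) for name, c in self.circles.items()
                    if name in ORGANIZER_ROLES}
        if len(distinct) != 5:
            raise ValueError(
                "expected exactly 5 distinct organizer circle centers "
                f"(APB and DVB share the central one), got {len(distinct)}"
            )

    @property
    def radius_px(self) -> float:
        return 0.5 * self.diameter_um / self.pixel_size_um

    def mask(self, role: str) -> np.ndarray:
        return circle_mask(self.image_shape, self.circles[role], self.radius_px)

    def composite(self, region: str) -> list[np.ndarray]:
        """Constituent circle masks of a composite region name."""
        members = {
            "APB": ("APB1", "APB2", "APB3"),
            "DVB": ("DVB1", "DVB2", "DVB3"),
            "ORG": ("APB1", "APB2", "APB3", "DVB1", "DVB3"),
            "NO": NON_ORGANIZER_ROLES,
        }
        if region in members:
            return [self.mask(r) for r in members[region]]
        if region in self.circles:
            return [self.mask(region)]
        raise KeyError(f"unknown region {region!r}")


def circle_mask(shape: tuple[int, int], center, radius_px: float) -> np.ndarray:
    """Boolean disc: pixels whose center lies within the radius (inclusive)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def make_roi_scheme(
    intersection_point,
    ap_direction,
    dv_direction,
    pixel_size_um: float,
    image_shape: tuple[int, int],
    diameter_um: float = 20.0,
    spacing_um: float | None = None,
    dorsal_polygon=None,
    ventral_polygon=None,
) -> RoiScheme:
    """Place the nine-ROI scheme from boundary landmarks.

    The central circle sits at the AP/DV boundary intersection; two more
    are placed along each boundary direction at +-spacing (default
    1.5 x diameter, which keeps neighbouring circles disjoint); the four
    non-organizer circles sit at the quadrant midpoints of the pouch
    bounding box (here: halfway between the intersection and each image
    corner).

    Raises
    ------
    ValueError
        Parallel boundary directions, non-positive spacing, or any circle
        extending outside the image (the error names the offenders).
    """
    center = np.asarray(intersection_point, dtype=float)
    ap_dir = np.asarray(ap_direction, dtype=float)
    dv_dir = np.asarray(dv_direction, dtype=float)
    for name, d in (("ap_direction", ap_dir), ("dv_direction", dv_dir)):
        if np.linalg.norm(d) == 0:
            raise ValueError(f"{name} must be non-zero")
    ap_u = ap_dir / np.linalg.norm(ap_dir)
    dv_u = dv_dir / np.linalg.norm(dv_dir)
    if abs(ap_u[0] * dv_u[1] - ap_u[1] * dv_u[0]) < 1e-9:
        raise ValueError("ap_direction and dv_direction must not be parallel")
    if spacing_um is None:
        spacing_um = 1.5 * diameter_um
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive (identical overlapping "
                         "circles are not allowed)")

    step = spacing_um / pixel_size_um
    circles: dict[str, tuple[float, float]] = {
        "APB1": tuple(center - step * ap_u),
        "APB2": tuple(center),
        "APB3": tuple(center + step * ap_u),
        "DVB1": tuple(center - step * dv_u),
        "DVB2": tuple(center),
        "DVB3": tuple(center + step * dv_u),
    }
    corners = np.array([[0, 0], [0, image_shape[1] - 1],
                        [image_shape[0] - 1, 0],
                        [image_shape[0] - 1, image_shape[1] - 1]], dtype=float)
    for i, corner in enumerate(corners, start=1):
        circles[f"NO{i}"] = tuple(0.5 * (center + corner))

    radius_px = 0.5 * diameter_um / pixel_size_um
    out_of_bounds = [
        name for name, (r, c) in circles.items()
        if r - radius_px < -0.5 or c - radius_px < -0.5
        or r + radius_px > image_shape[0] - 0.5
        or c + radius_px > image_shape[1] - 0.5
    ]
    if out_of_bounds:
        raise ValueError(f"circles out of image bounds: {sorted(out_of_bounds)}")

    ap_line = (center, ap_u)
    return RoiScheme(
        circles=circles, diameter_um=diameter_um, pixel_size_um=pixel_size_um,
        image_shape=tuple(image_shape),
        dorsal_polygon=None if dorsal_polygon is None else np.asarray(dorsal_polygon, float),
        ventral_polygon=None if ventral_polygon is None else np.asarray(ventral_polygon, float),
        ap_line=ap_line,
    )


def _masked_means(eta: np.ndarray, mask: np.ndarray):
    """Per-frame mean of finite eta over a boolean mask; NaN when empty."""
    sub = eta[:, mask]
    valid = np.isfinite(sub)
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, np.nansum(np.where(valid, sub, 0.0), axis=1)
                         / np.maximum(n, 1), np.nan)
    return means, n


def extract_trace(eta_stack, region, *, label: str, disc_id: str = "disc0") -> RegionTrace:
    """Mean-efficiency time trace over a region of an efficiency stack.

    ``region`` is either a single boolean mask (pixel-pooled mean) or a
    list of masks forming a composite region, in which case each frame's
    value is the unweighted mean of the constituent ROI means.  Frames in
    which a constituent has no valid pixel are missing (NaN).
    """
    masks = region if isinstance(region, (list, tuple)) else [region]
    if not masks or any(not m.any() for m in masks):
        raise ValueError(f"empty region {label!r}")
    if not any(np.isfinite(eta_stack.eta[:, m]).any() for m in masks):
        raise ValueError(f"region {label!r} contains no valid pixel in any frame")

    per_roi = [_masked_means(eta_stack.eta, m) for m in masks]
    means = np.vstack([m for m, _ in per_roi])
    counts = np.vstack([n for _, n in per_roi])
    if len(masks) == 1:
        trace, n = means[0], counts[0]
    else:
        # composite: unweighted ROI-mean of means, defined only when every
        # constituent ROI has valid pixels that frame
        trace = means.mean(axis=0)
        n = np.where(np.isfinite(trace), counts.sum(axis=0), 0)
    return RegionTrace(region=label, disc_id=disc_id,
                       times_min=eta_stack.times_min, mean_eta=trace, n_valid=n)


def organizer_traces(eta_stack, scheme: RoiScheme, disc_id: str = "disc0",
                     regions=("APB", "DVB", "ORG", "NO")) -> dict[str, RegionTrace]:
    """Composite organizer-scheme traces (APB, DVB, ORG, NO) for one disc."""
    return {
        region: extract_trace(eta_stack, scheme.composite(region),
                              label=region, disc_id=disc_id)
        for region in regions
    }


def _polygon_mask(shape, polygon, name):
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[0] < 3:
        raise ValueError(f"{name} polygon needs >= 3 vertices")
    mask = polygon2mask(shape, polygon)
    if not mask.any():
        raise ValueError(f"{name} polygon rasterises to an empty mask")
    return mask


def compartment_traces(eta_stack, scheme: RoiScheme,
                       disc_id: str = "disc0") -> dict[str, RegionTrace]:
    """Pixel-pooled traces for D, V and the DA/DP/VA/VP sub-compartments.

    Sub-compartments are the intersection of each compartment polygon
    with a half-plane of the AP boundary line: anterior is the side to
    the left of the line's direction vector; pixels exactly on the line
    count as posterior.
    """
    if scheme.dorsal_polygon is None or scheme.ventral_polygon is None:
        raise ValueError("scheme has no dorsal/ventral polygons")
    if scheme.ap_line is None:
        raise ValueError("scheme has no AP boundary line")
    shape = scheme.image_shape
    d_mask = _polygon_mask(shape, scheme.dorsal_polygon, "dorsal")
    v_mask = _polygon_mask(shape, scheme.ventral_polygon, "ventral")

    point, direction = scheme.ap_line
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    cross = direction[0] * (cc - point[1]) - direction[1] * (rr - point[0])
    anterior = cross < 0

    regions = {
        "D": d_mask, "V": v_mask,
        "DA": d_mask & anterior, "DP": d_mask & ~anterior,
        "VA": v_mask & anterior, "VP": v_mask & ~anterior,
    }
    return {
        name: extract_trace(eta_stack, mask, label=name, disc_id=disc_id)
        for name, mask in regions.items()
    }


def load_landmarks(path) -> dict:
    """Read a landmark sidecar JSON (intersection, directions, polygons)."""
    with open(path) as fh:
        data = json.load(fh)
    required = {"intersection", "ap_dir", "dv_dir"}
    missing = required - data.keys()
    if missing:
        raise ValueError(f"landmark file {path} missing keys: {sorted(missing)}")
    return data
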