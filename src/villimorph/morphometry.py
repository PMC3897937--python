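"""Villous morphometry: thresholding, contours, landmarks and normalization.

Implements the measurement scheme used for quantifying environmental
enteropathy on H&E-stained jejunal sections:

* an orientation-adequacy screen (both crypts and villi must appear in
  longitudinal section, villus axes near-perpendicular to the muscularis);
* automatic global thresholding (Otsu) to separate tissue from lumen;
* villous contour extraction above the inter-villous plateau, giving
  villous cross-sectional area (VA) and villous perimeter excluding the
  basal attachment chord (VP);
* per-100-μm muscularis mucosae normalization of VP and VA;
* landmark-based villous height (VH), crypt depth (CD) and maximal
  villous width perpendicular to the VH axis (VW).

All geometry is carried in μm; images carry an explicit μm-per-pixel scale
(pixel ``(row, col)`` has its centre at ``((col+0.5)*s, (row+0.5)*s)`` μm,
y increasing downward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.filters import threshold_otsu

__all__ = [
    "MorphometryRecord",
    "LandmarkSet",
    "VillousContour",
    "OrientationError",
    "assess_orientation",
    "auto_threshold",
    "extract_villous_contours",
    "measure_villus",
    "normalize_per_muscularis",
    "measure_landmarks",
    "landmarks_from_annotation",
    "summarize_biopsy",
    "polyline_length",
]

# villus axes further than this from the muscularis normal fail the
# orientation screen ("longitudinal section" operationalized)
DEFAULT_TILT_TOLERANCE_DEG = 30.0
# connected components narrower than this are treated as debris, not villi
MIN_VILLUS_WIDTH_UM = 5.0


class OrientationError(ValueError):
    """Raised when orientation adequacy cannot be assessed at all."""


@dataclass
class MorphometryRecord:
    """Per-biopsy morphometric summary.

    VH/CD/VW in μm; VP_per100 in μm per 100 μm muscularis mucosae
    (epithelial surface-area proxy); VA_per100 in μm² per 100 μm
    muscularis mucosae (villous compartment volume proxy). ``adequate``
    is False for biopsies failing the orientation screen; their
    measurements are NaN and they are excluded from analysis downstream.
    Note VH >= VW is *not* required: blunted villi in enteropathy can be
    wider than tall.
    """

    VH: float
    CD: float
    VW: float
    VP_per100: float
    VA_per100: float
    muscularis_length_um: float
    adequate: bool = True

    def __post_init__(self) -> None:
        for name in ("VH", "CD", "VW", "VP_per100", "VA_per100"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.muscularis_length_um is not None and not math.isnan(
            self.muscularis_length_um
        ):
            if self.muscularis_length_um < 0:
                raise ValueError("muscularis_length_um must be >= 0")

    def to_dict(self) -> dict:
        return {
            "VH": self.VH,
            "CD": self.CD,
            "VW": self.VW,
            "VP_per100": self.VP_per100,
            "VA_per100": self.VA_per100,
            "muscularis_length_um": self.muscularis_length_um,
            "adequate": bool(self.adequate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MorphometryRecord":
        return cls(
            VH=float(d["VH"]),
            CD=float(d["CD"]),
            VW=float(d["VW"]),
            VP_per100=float(d["VP_per100"]),
            VA_per100=float(d["VA_per100"]),
            muscularis_length_um=float(d["muscularis_length_um"]),
            adequate=bool(d["adequate"]),
        )


@dataclass
class LandmarkSet:
    """Hand-drawn (or annotation-derived) measurement polylines, in μm.

    ``vh_polylines``: one open polyline per villus, tip to base along the
    villus axis; ``cd_polylines``: one per crypt, mouth to base;
    ``vw_segment``: the maximal-width chord perpendicular to the VH axis;
    ``muscularis_polyline``: the muscularis mucosae trace used as the
    normalizing denominator.
    """

    vh_polylines: list = field(default_factory=list)
    cd_polylines: list = field(default_factory=list)
    vw_segment: np.ndarray | None = None
    muscularis_polyline: np.ndarray | None = None


@dataclass
class VillousContour:
    """A closed villous outline plus its basal attachment chord (μm)."""

    polygon: np.ndarray  # (N, 2) x, y vertices, closed implicitly
    base_segment: np.ndarray  # (2, 2) chord endpoints

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.base_segment = np.asarray(self.base_segment, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (N, 2) array")


class ThresholdResult(NamedTuple):
    threshold: float
    mask: np.ndarray  # True where tissue


def polyline_length(points: Sequence) -> float:
    """Arc length of an open polyline given as an (N, 2) point array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


# ---------------------------------------------------------------------------
# orientation screen
# ---------------------------------------------------------------------------

def _axis_tilt_deg(vec: np.ndarray) -> float:
    """Angle (deg) between a villus-axis vector and the vertical normal."""
    dx, dy = float(vec[0]), float(vec[1])
    norm = math.hypot(dx, dy)
    if norm == 0:
        return 90.0
    return math.degrees(math.acos(min(1.0, abs(dy) / norm)))


def _villus_axis(polygon: np.ndarray, base_segment: np.ndarray) -> np.ndarray:
    """Axis vector from the base-chord midpoint to the farthest vertex."""
    poly = np.asarray(polygon, dtype=float)
    base_mid = np.asarray(base_segment, dtype=float).mean(axis=0)
    d = np.hypot(*(poly - base_mid).T)
    tip = poly[int(np.argmax(d))]
    return tip - base_mid


def assess_orientation(
    annotation,
    tilt_tolerance_deg: float = DEFAULT_TILT_TOLERANCE_DEG,
) -> bool:
    """Screen a biopsy for adequacy of orientation.

    Adequate iff at least one villus *and* at least one crypt are present
    in longitudinal section and every candidate villus axis lies within
    ``tilt_tolerance_deg`` of the muscularis normal.  Accepts either a
    ground-truth annotation (villus polygons + crypt polylines) or a
    :class:`LandmarkSet`.  A missing annotation raises
    :class:`OrientationError` — never a silent pass.
    """
    if annotation is None:
        raise OrientationError("no annotation provided; orientation unassessable")

    if hasattr(annotation, "villus_polygons"):
        villi = list(annotation.villus_polygons)
        crypts = list(annotation.crypt_polylines)
        if not villi or not crypts:
            return False
        bases = list(annotation.villus_base_segments)
        for poly, base in zip(villi, bases):
            if _axis_tilt_deg(_villus_axis(poly, base)) > tilt_tolerance_deg:
                return False
        return True

    if hasattr(annotation, "vh_polylines"):
        villi = list(annotation.vh_polylines)
        crypts = list(annotation.cd_polylines)
        if not villi or not crypts:
            return False
        for pl in villi:
            pts = np.asarray(pl, dtype=float)
            if _axis_tilt_deg(pts[-1] - pts[0]) > tilt_tolerance_deg:
                return False
        return True

    raise OrientationError(
        f"cannot assess orientation from object of type {type(annotation).__name__}"
    )


# ---------------------------------------------------------------------------
# threshold segmentation
# ---------------------------------------------------------------------------

def auto_threshold(image, tissue_is_dark: bool = True) -> ThresholdResult:
    """Global Otsu threshold separating tissue from lumen.

    Returns the threshold maximizing between-class intensity variance and
    the tissue mask.  Tissue is taken as the darker class; pass
    ``tissue_is_dark=False`` for inverted-polarity images.  RGB input is
    converted to grayscale by luminance first.
    """
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:  # RGB -> luminance
        pixels = (
            0.2125 * pixels[..., 0]
            + 0.7154 * pixels[..., 1]
            + 0.0721 * pixels[..., 2]
        )
    if pixels.size == 0:
        raise ValueError("empty image")
    if np.ptp(pixels) == 0:
        raise ValueError("no threshold separable: image intensity is constant")
    work = pixels if tissue_is_dark else pixels.max() - pixels
    thr = float(threshold_otsu(np.asarray(work, dtype=float)))
    mask = np.asarray(work, dtype=float) < thr
    return ThresholdResult(threshold=thr, mask=mask)


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def _plateau_row(mask: np.ndarray, col_range: tuple[int, int] | None) -> int:
    """Row index of the inter-villous plateau surface.

    Uses the per-column elevation of the topmost tissue pixel; the plateau
    is the modal elevation (villus tops vary with the villus profile, the
    plateau between villi is flat), refined by the median of nearby tops.
    """
    cols = np.arange(mask.shape[1])
    if col_range is not None:
        cols = cols[(cols >= col_range[0]) & (cols <= col_range[1])]
    sub = mask[:, cols]
    has_tissue = sub.any(axis=0)
    if not has_tissue.any():
        raise ValueError("mask contains no tissue in the muscularis extent")
    tops = np.argmax(sub[:, has_tissue], axis=0)
    counts = np.bincount(tops)
    mode = int(np.argmax(counts))
    near = tops[np.abs(tops - mode) <= 2]
    return int(np.median(near))


def extract_villous_contours(
    mask: np.ndarray,
    muscularis_polyline=None,
    um_per_pixel: float = 1.0,
    min_villus_width_um: float = MIN_VILLUS_WIDTH_UM,
) -> list[VillousContour]:
    """Extract one sub-pixel contour per villous protrusion.

    Villi are the connected tissue components strictly above the
    inter-villous plateau level; cutting at the plateau separates villi
    whose tips approach each other and defines each base chord.  Contours
    are computed by marching squares on a Gaussian-smoothed (sigma = 1 px)
    copy of the binary mask at the 0.5 level — pixel-boundary staircase
    perimeters are biased high, sub-pixel level sets are not.  Returned
    contours are in μm, ordered left to right; a flat mucosa yields an
    empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    min_px = max(1, int(round(min_villus_width_um / um_per_pixel)))
    clean = skmorph.remove_small_objects(mask, max_size=min_px * min_px)
    clean = skmorph.remove_small_holes(clean, max_size=min_px * min_px)
    if not clean.any():
        return []

    col_range = None
    if muscularis_polyline is not None:
        pl = np.asarray(muscularis_polyline, dtype=float)
        c_lo = int(math.floor(pl[:, 0].min() / um_per_pixel - 0.5))
        c_hi = int(math.ceil(pl[:, 0].max() / um_per_pixel - 0.5))
        col_range = (max(0, c_lo), min(clean.shape[1] - 1, c_hi))

    cut_row = _plateau_row(clean, col_range)
    if cut_row <= 0:
        return []
    above = clean.copy()
    above[cut_row:, :] = False
    labels = skmeasure.label(above, connectivity=1)

    contours: list[VillousContour] = []
    for region in skmeasure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        if (c1 - c0) < min_px or region.area < min_px * min_px:
            continue
        pad = 4
        local = np.zeros((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad), dtype=float)
        local[pad : pad + (r1 - r0), pad : pad + (c1 - c0)] = (
            labels[r0:r1, c0:c1] == region.label
        )
        smooth = gaussian_filter(local, sigma=1.0)
        found = skmeasure.find_contours(smooth, level=0.5)
        if not found:
            continue
        contour = max(found, key=len)  # (row, col) vertices
        rows = contour[:, 0] + (r0 - pad)
        cols_ = contour[:, 1] + (c0 - pad)
        xy_um = np.column_stack(
            [(cols_ + 0.5) * um_per_pixel, (rows + 0.5) * um_per_pixel]
        )
        # base chord: contour points lying along the plateau cut
        base_rows = rows >= (cut_row - 1.5)
        if base_rows.sum() >= 2:
            bx = xy_um[base_rows, 0]
            by = float(np.mean(xy_um[base_rows, 1]))
            base = np.array([[bx.min(), by], [bx.max(), by]])
        else:  # degenerate: use the lowest edge of the contour
            lowest = xy_um[np.argsort(xy_um[:, 1])[-2:]]
            base = lowest[np.argsort(lowest[:, 0])]
        contours.append(VillousContour(polygon=xy_um, base_segment=base))

    contours.sort(key=lambda c: float(c.polygon[:, 0].mean()))
    return contours


def measure_villus(
    contour: VillousContour, um_per_pixel: float = 1.0
) -> tuple[float, float]:
    """Area (μm²) and base-excluded perimeter (μm) of a villous contour.

    Area is the shoelace polygon area; perimeter is the closed boundary
    length minus the basal chord length.  ``um_per_pixel`` rescales
    contours still expressed in pixel units (contours from
    :func:`extract_villous_contours` are already in μm; leave it at 1).
    """
    pts = np.asarray(contour.polygon, dtype=float) * um_per_pixel
    if len(pts) < 3:
        raise ValueError(f"degenerate polygon with {len(pts)} vertices")
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    base = np.asarray(contour.base_segment, dtype=float) * um_per_pixel
    base_len = float(np.hypot(*(base[1] - base[0])))
    perimeter = max(0.0, float(poly.exterior.length) - base_len)
    return float(poly.area), perimeter


def normalize_per_muscularis(total: float, muscularis_length_um: float) -> float:
    """Express a summed quantity per 100 μm of muscularis mucosae."""
    if muscularis_length_um <= 0:
        raise ValueError(
            f"muscularis length must be > 0 μm, got {muscularis_length_um}"
        )
    return total / muscularis_length_um * 100.0


# ---------------------------------------------------------------------------
# landmark measurements
# ---------------------------------------------------------------------------

def measure_landmarks(
    landmarks: LandmarkSet,
    um_per_pixel: float = 1.0,
    cd_rule: str = "mean",
    vh_rule: str = "max",
) -> tuple[float, float, float, float]:
    """(VH, CD, VW, muscularis length) in μm from drawn polylines.

    VH is by default the *maximal* villous height over the villi in the
    section and CD the mean over measured crypts (both rules switchable:
    ``"max"`` / ``"mean"``).  Each value is a polyline arc length (or
    segment length for VW) times the scale.
    """
    if not landmarks.vh_polylines:
        raise ValueError("missing landmark field: vh_polylines")
    if not landmarks.cd_polylines:
        raise ValueError("missing landmark field: cd_polylines")
    if landmarks.vw_segment is None:
        raise ValueError("missing landmark field: vw_segment")
    if landmarks.muscularis_polyline is None:
        raise ValueError("missing landmark field: muscularis_polyline")
    agg = {"max": max, "mean": lambda v: sum(v) / len(v)}
    if cd_rule not in agg or vh_rule not in agg:
        raise ValueError("cd_rule / vh_rule must be 'mean' or 'max'")
    vh_lengths = [polyline_length(pl) * um_per_pixel for pl in landmarks.vh_polylines]
    cd_lengths = [polyline_length(pl) * um_per_pixel for pl in landmarks.cd_polylines]
    vh = float(agg[vh_rule](vh_lengths))
    cd = float(agg[cd_rule](cd_lengths))
    vw = polyline_length(landmarks.vw_segment) * um_per_pixel
    musc = polyline_length(landmarks.muscularis_polyline) * um_per_pixel
    return vh, cd, vw, musc


def landmarks_from_annotation(annotation) -> LandmarkSet:
    """Derive measurement polylines from a ground-truth annotation.

    Stands in for the human tracing step: the VH polyline runs from each
    villus base-chord midpoint to the farthest outline vertex (the tip);
    CD polylines are the crypt axes as annotated; VW is the maximal chord
    of the tallest villus perpendicular to its axis.
    """
    villi = list(annotation.villus_polygons)
    bases = list(annotation.villus_base_segments)
    if not villi:
        raise ValueError("annotation contains no villus polygons")
    vh_polylines = []
    axes = []
    for poly, base in zip(villi, bases):
        base_mid = np.asarray(base, dtype=float).mean(axis=0)
        axis = _villus_axis(np.asarray(poly, dtype=float), base)
        vh_polylines.append(np.array([base_mid + axis, base_mid]))
        axes.append(axis)
    # VW: width of the tallest villus perpendicular to its own axis
    tallest = int(np.argmax([polyline_length(pl) for pl in vh_polylines]))
    poly = np.asarray(villi[tallest], dtype=float)
    axis = axes[tallest]
    axis = axis / np.hypot(*axis)
    perp = np.array([-axis[1], axis[0]])
    proj = poly @ perp
    centre = poly.mean(axis=0)
    lo, hi = proj.min(), proj.max()
    vw_segment = np.array([centre + (lo - centre @ perp) * perp,
                           centre + (hi - centre @ perp) * perp])
    return LandmarkSet(
        vh_polylines=vh_polylines,
        cd_polylines=[np.asarray(pl, dtype=float) for pl in annotation.crypt_polylines],
        vw_segment=vw_segment,
        muscularis_polyline=np.asarray(annotation.muscularis_polyline, dtype=float),
    )


# ---------------------------------------------------------------------------
# per-biopsy summary
# ---------------------------------------------------------------------------

def summarize_biopsy(
    image,
    annotation,
    tilt_tolerance_deg: float = DEFAULT_TILT_TOLERANCE_DEG,
    cd_rule: str = "mean",
    tissue_is_dark: bool = True,
) -> MorphometryRecord:
    """Full semi-automated measurement of one biopsy image.

    Pipeline: orientation screen -> Otsu threshold -> villous contours ->
    per-villus area/perimeter summed over the section -> per-100-μm
    muscularis normalization; VH/CD/VW come from the landmark path.
    Biopsies failing the orientation screen return a record flagged
    ``adequate=False`` with NaN measurements (excluded downstream).
    """
    musc_len = polyline_length(annotation.muscularis_polyline)
    if not assess_orientation(annotation, tilt_tolerance_deg):
        nan = float("nan")
        return MorphometryRecord(
            VH=nan, CD=nan, VW=nan, VP_per100=nan, VA_per100=nan,
            muscularis_length_um=musc_len, adequate=False,
        )

    landmarks = landmarks_from_annotation(annotation)
    vh, cd, vw, _ = measure_landmarks(landmarks, um_per_pixel=1.0, cd_rule=cd_rule)

    _, mask = auto_threshold(image, tissue_is_dark=tissue_is_dark)
    upp = float(getattr(image, "um_per_pixel", 1.0))
    contours = extract_villous_contours(
        mask, annotation.muscularis_polyline, um_per_pixel=upp
    )
    total_area = 0.0
    total_perim = 0.0
    for c in contours:
        a, p = measure_villus(c)
        total_area += a
        total_perim += p
    return MorphometryRecord(
        VH=vh,
        CD=cd,
        VW=vw,
        VP_per100=normalize_per_muscularis(total_perim, musc_len),
        VA_per100=normalize_per_muscularis(total_area, musc_len),
        muscularis_length_um=musc_len,
        adequate=True,
    )
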