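"""Synthetic jejunal-mucosa section generator with exact ground truth.

Renders H&E-like (intensity-only) cross sections: finger-like villi on a
flat inter-villous plateau, a lamina-propria band containing crypt axes,
and a horizontal muscularis mucosae baseline near the bottom edge.  Every
image ships with an analytically computed ground-truth annotation so the
morphometry engine can be validated without any real slide.

Geometry lives in μm with an explicit μm-per-pixel scale; image
coordinates are row-major with the origin top-left and y increasing
downward.  Villus profiles come in two families with closed-form
perimeter/area oracles:

* ``"rect"``      — a w × h rectangle: VP = 2h + w, VA = w·h
* ``"capped"``    — rectangle with a semicircular tip (total height h,
  straight side h - w/2): VP = 2(h - w/2) + πw/2, VA = w(h - w/2) + πw²/8

(VP excludes the basal attachment chord throughout.)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .morphometry import MorphometryRecord

__all__ = [
    "MucosaSpec",
    "CalibratedImage",
    "GroundTruthAnnotation",
    "generate_mucosa_image",
    "render_batch",
    "load_image",
    "load_annotation",
]

TISSUE_INTENSITY = 60.0
LUMEN_INTENSITY = 200.0
ARC_SEGMENTS = 64  # semicircular-cap discretization; length error < 0.05%
MIN_VILLUS_GAP_UM = 10.0
LAMINA_MARGIN_UM = 30.0  # band depth below the plateau beyond the crypts
TILT_INADEQUATE_DEG = 45.0  # applied when orientation_adequate is False


@dataclass(frozen=True)
class MucosaSpec:
    """Parameters of one synthetic mucosa section.

    Lengths in μm: ``villus_height_um`` is the full base-to-tip height
    (cap included for the capped profile), ``villus_width_um`` the villus
    width, ``crypt_depth_um`` the crypt mouth-to-base depth, and
    ``muscularis_length_um`` the horizontal extent of the muscularis
    baseline.  ``noise_sd`` is additive Gaussian intensity noise (8-bit
    units).  With ``orientation_adequate=False`` villi are rendered
    sheared 45° off the muscularis normal and the ground truth is flagged
    inadequate.
    """

    n_villi: int
    villus_height_um: float
    villus_width_um: float
    crypt_depth_um: float
    muscularis_length_um: float
    um_per_pixel: float = 1.0
    noise_sd: float = 0.0
    orientation_adequate: bool = True
    seed: int = 0
    profile: str = "capped"

    def __post_init__(self) -> None:
        for name in (
            "villus_height_um",
            "villus_width_um",
            "crypt_depth_um",
            "muscularis_length_um",
            "um_per_pixel",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_villi < 1:
            raise ValueError(f"n_villi must be >= 1, got {self.n_villi}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.profile not in ("rect", "capped"):
            raise ValueError(f"unknown villus profile {self.profile!r}")
        if self.profile == "capped" and (
            self.villus_height_um <= self.villus_width_um / 2
        ):
            raise ValueError(
                "capped profile needs villus_height_um > villus_width_um / 2"
            )
        spacing = self.muscularis_length_um / self.n_villi
        if self.villus_width_um + MIN_VILLUS_GAP_UM > spacing:
            raise ValueError(
                f"geometry cannot fit the canvas: {self.n_villi} villi of width "
                f"{self.villus_width_um} μm (+{MIN_VILLUS_GAP_UM} μm gap) do not "
                f"fit a {self.muscularis_length_um} μm muscularis baseline"
            )


@dataclass
class CalibratedImage:
    """An 8-bit grayscale image plus its μm-per-pixel calibration."""

    pixels: np.ndarray
    um_per_pixel: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        img = PILImage.fromarray(self.pixels.astype(np.uint8))
        if path.suffix.lower() in (".tif", ".tiff"):
            img.save(path, format="TIFF")
        else:
            img.save(path, format="PNG")


@dataclass
class GroundTruthAnnotation:
    """Exact geometry of a rendered section, in μm, plus its true record."""

    villus_polygons: list
    villus_base_segments: list
    crypt_polylines: list
    muscularis_polyline: np.ndarray
    true_record: MorphometryRecord
    um_per_pixel: float = 1.0
    band_polygon: np.ndarray | None = None  # lamina-propria band outline

    def total_tissue_area_um2(self) -> float:
        """Continuous-geometry area of all rendered tissue polygons."""
        area = sum(Polygon(p).area for p in self.villus_polygons)
        if self.band_polygon is not None:
            area += Polygon(self.band_polygon).area
        return float(area)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "um_per_pixel": self.um_per_pixel,
            "villus_polygons": [np.asarray(p).tolist() for p in self.villus_polygons],
            "villus_base_segments": [
                np.asarray(s).tolist() for s in self.villus_base_segments
            ],
            "crypt_polylines": [np.asarray(p).tolist() for p in self.crypt_polylines],
            "muscularis_polyline": np.asarray(self.muscularis_polyline).tolist(),
            "band_polygon": (
                np.asarray(self.band_polygon).tolist()
                if self.band_polygon is not None
                else None
            ),
            "true_record": self.true_record.to_dict(),
            "orientation_adequate": bool(self.true_record.adequate),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthAnnotation":
        d = json.loads(Path(path).read_text())
        band = d.get("band_polygon")
        return cls(
            villus_polygons=[np.asarray(p, dtype=float) for p in d["villus_polygons"]],
            villus_base_segments=[
                np.asarray(s, dtype=float) for s in d["villus_base_segments"]
            ],
            crypt_polylines=[
                np.asarray(p, dtype=float) for p in d["crypt_polylines"]
            ],
            muscularis_polyline=np.asarray(d["muscularis_polyline"], dtype=float),
            true_record=MorphometryRecord.from_dict(d["true_record"]),
            um_per_pixel=float(d["um_per_pixel"]),
            band_polygon=None if band is None else np.asarray(band, dtype=float),
        )


# ---------------------------------------------------------------------------
# closed-form per-villus truths
# ---------------------------------------------------------------------------

def _villus_truth(profile: str, h: float, w: float) -> tuple[float, float]:
    """(perimeter excluding base, area) of one upright villus, closed form."""
    if profile == "rect":
        return 2 * h + w, h * w
    hs = h - w / 2
    return 2 * hs + math.pi * w / 2, w * hs + math.pi * w * w / 8


def _villus_polygon(
    profile: str, cx: float, y_base: float, h: float, w: float
) -> np.ndarray:
    """Vertices (x, y in μm, y down) of an upright villus, base last-first."""
    half = w / 2
    if profile == "rect":
        return np.array(
            [
                [cx - half, y_base],
                [cx - half, y_base - h],
                [cx + half, y_base - h],
                [cx + half, y_base],
            ]
        )
    hs = h - half
    y_c = y_base - hs  # cap centre
    thetas = np.linspace(math.pi, 0.0, ARC_SEGMENTS + 1)
    arc = np.column_stack([cx + half * np.cos(thetas), y_c - half * np.sin(thetas)])
    return np.vstack([[cx - half, y_base], arc, [cx + half, y_base]])


def _shear(points: np.ndarray, y_base: float, slope: float) -> np.ndarray:
    """Shear about the base line: x += slope * (y_base - y)."""
    pts = np.asarray(points, dtype=float).copy()
    pts[:, 0] += slope * (y_base - pts[:, 1])
    return pts


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_mucosa_image(
    spec: MucosaSpec,
) -> tuple[CalibratedImage, GroundTruthAnnotation]:
    """Render one synthetic section and its exact ground truth.

    Deterministic for a fixed spec (the seed drives only the intensity
    noise).  In the noise-free limit the image is exactly two-valued
    (tissue dark, lumen bright), separable by a global threshold.  The
    true record holds the closed-form VH/CD/VW/VP/VA of the rendered
    geometry, normalized per 100 μm muscularis.
    """
    n = spec.n_villi
    h, w = spec.villus_height_um, spec.villus_width_um
    ml, cd = spec.muscularis_length_um, spec.crypt_depth_um
    upp = spec.um_per_pixel

    tilt_slope = (
        0.0
        if spec.orientation_adequate
        else math.tan(math.radians(TILT_INADEQUATE_DEG))
    )
    margin_x = 20.0 + h * tilt_slope
    margin_top, margin_bottom = 30.0, 15.0
    band_depth = cd + LAMINA_MARGIN_UM
    width_um = ml + 2 * margin_x
    height_um = margin_top + h + band_depth + margin_bottom
    y_plateau = margin_top + h
    y_musc = y_plateau + band_depth

    spacing = ml / n
    centres = margin_x + (np.arange(n) + 0.5) * spacing
    mid_x = margin_x + ml / 2

    villus_polygons, base_segments, vps, vas = [], [], [], []
    for cx in centres:
        poly = _villus_polygon(spec.profile, cx, y_plateau, h, w)
        base = np.array([[cx - w / 2, y_plateau], [cx + w / 2, y_plateau]])
        if tilt_slope:
            # shear toward the canvas centre; area is preserved, the
            # perimeter is re-measured on the sheared outline
            s = tilt_slope if cx <= mid_x else -tilt_slope
            poly = _shear(poly, y_plateau, s)
            shp = Polygon(poly)
            vp = shp.exterior.length - w
            va = shp.area
        else:
            vp, va = _villus_truth(spec.profile, h, w)
        villus_polygons.append(poly)
        base_segments.append(base)
        vps.append(vp)
        vas.append(va)

    # crypt axes: vertical polylines between/flanking the villi
    crypt_x = margin_x + np.arange(n + 1) * spacing
    crypt_polylines = [
        np.array([[x, y_plateau], [x, y_plateau + cd]]) for x in crypt_x
    ]
    muscularis_polyline = np.array([[margin_x, y_musc], [margin_x + ml, y_musc]])
    band_polygon = np.array(
        [
            [margin_x, y_plateau],
            [margin_x + ml, y_plateau],
            [margin_x + ml, y_musc],
            [margin_x, y_musc],
        ]
    )

    record = MorphometryRecord(
        VH=h,
        CD=cd,
        VW=w,
        VP_per100=sum(vps) / ml * 100.0,
        VA_per100=sum(vas) / ml * 100.0,
        muscularis_length_um=ml,
        adequate=spec.orientation_adequate,
    )

    # rasterize: pixel (r, c) centre at ((c+0.5)·upp, (r+0.5)·upp) μm
    shape = (int(round(height_um / upp)), int(round(width_um / upp)))
    canvas = np.full(shape, LUMEN_INTENSITY, dtype=float)
    for poly in [band_polygon, *villus_polygons]:
        rr, cc = draw_polygon(
            poly[:, 1] / upp - 0.5, poly[:, 0] / upp - 0.5, shape=shape
        )
        canvas[rr, cc] = TISSUE_INTENSITY
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    image = CalibratedImage(pixels=pixels, um_per_pixel=upp)
    annotation = GroundTruthAnnotation(
        villus_polygons=villus_polygons,
        villus_base_segments=base_segments,
        crypt_polylines=crypt_polylines,
        muscularis_polyline=muscularis_polyline,
        true_record=record,
        um_per_pixel=upp,
        band_polygon=band_polygon,
    )
    return image, annotation


# ---------------------------------------------------------------------------
# batch rendering and I/O
# ---------------------------------------------------------------------------

def render_batch(
    specs: list[MucosaSpec], out_dir: str | Path, image_format: str = "png"
) -> pd.DataFrame:
    """Render a list of specs to ``out_dir``; returns the manifest table.

    Writes one image and one JSON annotation sidecar per spec plus a
    ``manifest.csv``.  All specs are validated before anything is written,
    so an invalid spec produces an error naming its index and no partial
    output.
    """
    out_dir = Path(out_dir)
    for i, spec in enumerate(specs):
        if not isinstance(spec, MucosaSpec):
            raise TypeError(f"spec at index {i} is not a MucosaSpec: {spec!r}")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        image, annotation = generate_mucosa_image(spec)
        img_path = out_dir / f"mucosa_{i:03d}.{image_format}"
        try:
            image.save(img_path)
            annotation.to_json(img_path.with_suffix(".json"))
        except OSError as exc:
            raise OSError(f"failed writing {img_path}: {exc}") from exc
        t = annotation.true_record
        rows.append(
            {
                "image_path": img_path.name,
                "seed": spec.seed,
                "VH": t.VH,
                "CD": t.CD,
                "VW": t.VW,
                "VP_per100": t.VP_per100,
                "VA_per100": t.VA_per100,
                "adequate": t.adequate,
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "image_path", "seed", "VH", "CD", "VW",
            "VP_per100", "VA_per100", "adequate",
        ],
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_image(path: str | Path, um_per_pixel: float | None = None) -> CalibratedImage:
    """Load a PNG/TIFF image; the scale comes from the JSON sidecar unless given."""
    path = Path(path)
    pixels = np.asarray(PILImage.open(path).convert("L"))
    if um_per_pixel is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(
                f"no um_per_pixel given and no sidecar found at {sidecar}"
            )
        um_per_pixel = float(json.loads(sidecar.read_text())["um_per_pixel"])
    return CalibratedImage(pixels=pixels, um_per_pixel=um_per_pixel)


def load_annotation(path: str | Path) -> GroundTruthAnnotation:
    """Load a JSON annotation sidecar."""
    return GroundTruthAnnotation.from_json(path)
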