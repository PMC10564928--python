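"""Regions of interest: Frangi vessel segmentation + ONH polygon masks.

Two ROIs drive the pulsation analysis: RV, the dominant large retinal
vasculature segmented on the average-projection image by a Hessian-based
Frangi vesselness filter with thresholding, and ONH_T, the optic nerve
head tissue — the interior of an observer-drawn polygon minus a dilated
copy of the vessel mask (the dilation margin keeps vessel-edge pixels out
of the tissue signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.morphology import dilation, disk, remove_small_objects

__all__ = [
    "FrangiParams",
    "OnhPolygon",
    "RoiSet",
    "frangi_vesselness",
    "segment_vessels",
    "rasterize_polygon",
    "build_rois",
]


@dataclass(frozen=True)
class FrangiParams:
    """Tunable vesselness settings.

    ``scales`` are Gaussian sigmas in pixels and should span the radii of
    the vessels of interest; ``beta`` weights the blobness ratio, ``c`` the
    structureness (second-order energy, on the image's intensity scale);
    ``threshold`` cuts the vesselness map into a binary mask.  Polarity is
    dark-on-bright by default: blood absorbs at 570 nm, so vessels are
    dark ridges on bright tissue.
    """

    scales: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0, 8.0)
    beta: float = 0.5
    c: float = 15.0
    threshold: float = 0.10
    polarity: str = "dark-on-bright"
    min_area: int = 60

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(self.scales))
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be nonempty and positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.polarity not in ("dark-on-bright", "bright-on-dark"):
            raise ValueError("polarity must be dark-on-bright | bright-on-dark")


def frangi_vesselness(image: np.ndarray, params: FrangiParams) -> np.ndarray:
    """Multiscale Frangi vesselness map in [0, 1].

    Per scale sigma, the gamma-normalized Hessian (sigma^2-scaled Gaussian
    second derivatives) yields eigenvalues |l1| <= |l2|; the tubularity
    response is ``exp(-R_B^2/2 beta^2) * (1 - exp(-S^2/2 c^2))`` with
    ``R_B = l1/l2`` and ``S = sqrt(l1^2 + l2^2)``, gated to zero where the
    sign of l2 contradicts the chosen ridge polarity.  The output is the
    per-pixel maximum over scales.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    out = np.zeros_like(image)
    for s in params.scales:
        H = hessian_matrix(
            image, sigma=s, order="rc", use_gaussian_derivatives=True
        )
        l_hi, l_lo = hessian_matrix_eigvals(H)  # sorted by value, descending
        # re-sort by absolute value: l1 small, l2 large
        swap = np.abs(l_hi) > np.abs(l_lo)
        l1 = np.where(swap, l_lo, l_hi) * s**2
        l2 = np.where(swap, l_hi, l_lo) * s**2
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
        s2 = l1**2 + l2**2
        v = np.exp(-rb2 / (2.0 * params.beta**2)) * (
            1.0 - np.exp(-s2 / (2.0 * params.c**2))
        )
        # dark ridge: intensity minimum across the vessel => l2 > 0
        if params.polarity == "dark-on-bright":
            v[l2 <= 0] = 0.0
        else:
            v[l2 >= 0] = 0.0
        # Gaussian-derivative support leaks past the image edge; kill the
        # border band where the Hessian is untrustworthy
        b = max(2, int(np.ceil(2.0 * s)))
        v[:b] = v[-b:] = 0.0
        v[:, :b] = v[:, -b:] = 0.0
        np.maximum(out, v, out=out)
    return out


def segment_vessels(
    vesselness: np.ndarray,
    params: FrangiParams,
    min_area: int | None = None,
) -> np.ndarray:
    """Threshold a vesselness map and drop small components.

    ``min_area`` (default from params) removes connected components below
    that pixel count, keeping only the dominant large vasculature.
    """
    if vesselness.min() < 0 or vesselness.max() > 1:
        raise ValueError("vesselness map must lie in [0, 1]")
    min_area = params.min_area if min_area is None else min_area
    mask = vesselness >= params.threshold
    if min_area > 1:
        mask = remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        raise ValueError(
            "vessel segmentation is empty; lower the vesselness threshold "
            f"(currently {params.threshold})"
        )
    return mask


@dataclass(frozen=True)
class OnhPolygon:
    """Observer-supplied ONH boundary: ordered (y, x) vertices, 0-based."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        poly = shapely.Polygon([(x, y) for y, x in self.vertices])
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting")

    @classmethod
    def from_json(cls, path) -> "OnhPolygon":
        import json

        data = json.loads(open(path).read())
        return cls(vertices=tuple(tuple(v) for v in data["vertices"]))


def rasterize_polygon(
    poly: OnhPolygon, shape: tuple[int, int]
) -> np.ndarray:
    """Polygon interior on the pixel grid, boundary pixels included.

    A pixel belongs to the mask when its center lies inside or on the
    polygon boundary (even-odd interior; vertex order is irrelevant).
    """
    verts = np.asarray(poly.vertices, dtype=float)
    if (
        (verts[:, 0] < 0).any()
        or (verts[:, 1] < 0).any()
        or (verts[:, 0] > shape[0] - 1).any()
        or (verts[:, 1] > shape[1] - 1).any()
    ):
        raise ValueError("polygon vertices outside image bounds")
    geom = shapely.Polygon([(x, y) for y, x in poly.vertices])
    y0 = int(np.floor(verts[:, 0].min()))
    y1 = int(np.ceil(verts[:, 0].max())) + 1
    x0 = int(np.floor(verts[:, 1].min()))
    x1 = int(np.ceil(verts[:, 1].max())) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = shapely.intersects_xy(geom, xx.ravel(), yy.ravel()).reshape(yy.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


@dataclass
class RoiSet:
    """The two pulsation ROIs plus their parents.

    Invariants checked on construction: rv_mask within the vessel mask,
    onht_mask within the polygon mask, and the two ROIs disjoint.
    """

    vessel_mask: np.ndarray
    onh_mask: np.ndarray
    rv_mask: np.ndarray
    onht_mask: np.ndarray
    margin: int = 2
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.rv_mask & ~self.vessel_mask).sum() == 0:
            raise ValueError("rv_mask must be a subset of vessel_mask")
        if not (self.onht_mask & ~self.onh_mask).sum() == 0:
            raise ValueError("onht_mask must be a subset of onh_mask")
        if (self.rv_mask & self.onht_mask).any():
            raise ValueError("rv_mask and onht_mask must be disjoint")


def build_rois(
    onh_mask: np.ndarray,
    vessel_mask: np.ndarray,
    margin: int = 2,
    clip_rv_to_polygon: bool = False,
) -> RoiSet:
    """Combine the polygon interior and the vessel segmentation into ROIs.

    RV is the full segmented dominant vasculature in the field (optionally
    clipped to the polygon); ONH_T is the polygon interior minus the
    vessel mask dilated by ``margin`` pixels, which keeps partial-volume
    vessel-edge pixels out of the tissue waveform.
    """
    if onh_mask.shape != vessel_mask.shape:
        raise ValueError("masks must share a shape")
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty; cannot build RV ROI")
    rv = vessel_mask & onh_mask if clip_rv_to_polygon else vessel_mask.copy()
    grown = (
        dilation(vessel_mask, footprint=disk(margin))
        if margin > 0
        else vessel_mask
    )
    onht = onh_mask & ~grown
    if not rv.any():
        raise ValueError("RV ROI is empty")
    if not onht.any():
        raise ValueError("ONH_T ROI is empty (polygon fully covered by vessels?)")
    return RoiSet(
        vessel_mask=vessel_mask,
        onh_mask=onh_mask,
        rv_mask=rv,
        onht_mask=onht,
        margin=margin,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap between two binary masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
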