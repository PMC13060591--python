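"""Fluorescence quantification of nerve cross-sections.

Channels follow the staining panel: NF (neurofilament, axons), MBP (myelin
basic protein), CD31 (endothelium), DAPI (nuclei), GFP (lineage reporter).
The metrics mirror standard having/not-having overlap analysis:

* maximum-intensity projection of z-stacks;
* per-channel thresholding (manual, negative-control mean + k*SD, or Otsu);
* percent myelinated/unmyelinated axons by NF-component overlap with MBP;
* axon density (axons/mm^2) per fascicle ROI, centroid-in-polygon counting;
* capillary density from DAPI-confirmed CD31 components;
* marker coassociation percentages (e.g. GFP+CD31 double positives).

Objects are 8-connected components with a minimum size filter (default
4 px) to suppress speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ConfigurationError, InputError

__all__ = [
    "ImageBundle",
    "ThresholdSpec",
    "QuantResult",
    "MyelinationResult",
    "CoassociationResult",
    "max_project",
    "binarize",
    "myelination_fraction",
    "axon_density",
    "capillary_density",
    "coassociation",
    "quantify_bundle",
]

#: default connected-component filtering
MIN_OBJECT_PX = 4
CONNECTIVITY = 2  # 8-connected


@dataclass
class ImageBundle:
    """Named channel images sharing one shape, with pixel size and ROIs.

    ``rois`` maps a name (e.g. ``'fascicle'``) to an (N, 2) array of
    polygon vertices in (x=col, y=row) pixel coordinates.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm / pixel
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be > 0")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise InputError(f"channel shapes differ: {shapes}")


@dataclass
class ThresholdSpec:
    """How to binarize a channel.

    ``manual`` uses ``value`` directly.  ``automatic`` uses the
    negative-control ``reference`` image (mean + k*SD) when given, else
    Otsu's threshold on the image itself.
    """

    mode: str = "automatic"
    value: float | None = None
    reference: np.ndarray | None = None
    k: float = 3.0

    def __post_init__(self):
        if self.mode not in ("manual", "automatic"):
            raise ConfigurationError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "manual" and self.value is None:
            raise ConfigurationError("manual thresholding requires a value")


@dataclass
class MyelinationResult:
    n_axons: int
    n_myelinated: int
    n_unmyelinated: int
    pct_myelinated: float | None
    pct_unmyelinated: float | None
    flagged_empty: bool = False


@dataclass
class CoassociationResult:
    pct: float | None
    n_double_positive: int
    n_denominator: int
    denominator: str
    flagged_empty: bool = False


@dataclass
class QuantResult:
    """Aggregate quantification for one image/ROI."""

    pct_myelinated: float | None = None
    pct_unmyelinated: float | None = None
    axon_count: int = 0
    axons_per_mm2: float = 0.0
    capillaries_per_mm2: float = 0.0
    coassociation_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "pct_myelinated": self.pct_myelinated,
            "pct_unmyelinated": self.pct_unmyelinated,
            "axon_count": self.axon_count,
            "axons_per_mm2": self.axons_per_mm2,
            "capillaries_per_mm2": self.capillaries_per_mm2,
            "coassociation_pct": self.coassociation_pct,
        }


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection across z (axis 0); a single 2-D plane
    is returned unchanged."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise InputError("stack must be a non-empty 2-D or 3-D array")
    return arr.max(axis=0)


def binarize(img: np.ndarray, spec: ThresholdSpec | None = None) -> np.ndarray:
    """Threshold an image to a boolean mask (``img >= threshold``)."""
    if spec is None:
        spec = ThresholdSpec()
    img = np.asarray(img, dtype=float)
    if spec.mode == "manual":
        thr = float(spec.value)
    elif spec.reference is not None:
        ref = np.asarray(spec.reference, dtype=float)
        thr = float(ref.mean() + spec.k * ref.std())
    else:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool)
        # Otsu, floored at the image's own noise level (mean + k*SD) so a
        # signal-free channel does not get its background split into
        # spurious foreground
        thr = max(float(threshold_otsu(img)), float(img.mean() + spec.k * img.std()))
    return img >= thr


def _components(mask: np.ndarray, min_size: int = MIN_OBJECT_PX):
    """Labelled 8-connected components at least ``min_size`` px, as a list
    of regionprops."""
    lab = cc_label(np.asarray(mask, dtype=bool), connectivity=CONNECTIVITY)
    return [p for p in regionprops(lab) if p.area >= min_size]


def _overlap_px(prop, other: np.ndarray) -> int:
    r0, c0, r1, c1 = prop.bbox
    return int(np.count_nonzero(prop.image & other[r0:r1, c0:c1]))


def _roi_polygon(roi: np.ndarray) -> Polygon:
    pts = np.asarray(roi, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InputError("ROI must be an (N>=3, 2) vertex array")
    poly = Polygon(pts)
    if not poly.is_valid or poly.area <= 0:
        raise InputError("degenerate ROI polygon")
    return poly


def _roi_area_mm2(poly: Polygon, pixel_size: float) -> float:
    return poly.area * pixel_size**2 * 1e-6


def myelination_fraction(
    nf_mask: np.ndarray,
    mbp_mask: np.ndarray,
    min_overlap_px: int = 1,
    min_size: int = MIN_OBJECT_PX,
    overlap_fraction: float | None = None,
) -> MyelinationResult:
    """Classify NF axon components as myelinated (having) or unmyelinated
    (not having) by their overlap with the MBP mask.

    An axon is myelinated when its overlap with MBP reaches
    ``min_overlap_px`` pixels, or — if ``overlap_fraction`` is given —
    that fraction of the axon's own area.  The two percentages partition
    the axon count, so they sum to 100 whenever any axon is present.
    """
    nf_mask = np.asarray(nf_mask, dtype=bool)
    mbp_mask = np.asarray(mbp_mask, dtype=bool)
    if nf_mask.shape != mbp_mask.shape:
        raise InputError("NF and MBP masks must share a shape")
    comps = _components(nf_mask, min_size)
    n_axons = len(comps)
    if n_axons == 0:
        return MyelinationResult(0, 0, 0, None, None, flagged_empty=True)
    n_myel = 0
    for p in comps:
        ov = _overlap_px(p, mbp_mask)
        need = (
            max(1, int(np.ceil(overlap_fraction * p.area)))
            if overlap_fraction is not None
            else min_overlap_px
        )
        if ov >= need:
            n_myel += 1
    n_unmyel = n_axons - n_myel
    return MyelinationResult(
        n_axons=n_axons,
        n_myelinated=n_myel,
        n_unmyelinated=n_unmyel,
        pct_myelinated=100.0 * n_myel / n_axons,
        pct_unmyelinated=100.0 * n_unmyel / n_axons,
    )


def axon_density(
    nf_mask: np.ndarray,
    roi: np.ndarray,
    pixel_size: float,
    min_size: int = MIN_OBJECT_PX,
) -> float:
    """Axons per mm² within a fascicle ROI (centroid-in-polygon counting)."""
    if pixel_size <= 0:
        raise InputError("pixel_size must be > 0")
    poly = _roi_polygon(roi)
    comps = _components(np.asarray(nf_mask, dtype=bool), min_size)
    k = sum(1 for p in comps if poly.covers(Point(p.centroid[1], p.centroid[0])))
    return k / _roi_area_mm2(poly, pixel_size)


def capillary_density(
    cd31_mask: np.ndarray,
    dapi_mask: np.ndarray,
    roi: np.ndarray,
    pixel_size: float,
    min_overlap_px: int = 1,
    min_size: int = MIN_OBJECT_PX,
) -> float:
    """Capillaries per mm²: CD31 components kept only when they overlap
    DAPI (nucleus confirmation) and their centroid lies in the ROI."""
    cd31_mask = np.asarray(cd31_mask, dtype=bool)
    dapi_mask = np.asarray(dapi_mask, dtype=bool)
    if cd31_mask.shape != dapi_mask.shape:
        raise InputError("CD31 and DAPI masks must share a shape")
    if pixel_size <= 0:
        raise InputError("pixel_size must be > 0")
    poly = _roi_polygon(roi)
    k = 0
    for p in _components(cd31_mask, min_size):
        if _overlap_px(p, dapi_mask) < min_overlap_px:
            continue
        if poly.covers(Point(p.centroid[1], p.centroid[0])):
            k += 1
    return k / _roi_area_mm2(poly, pixel_size)


def coassociation(
    marker_a: np.ndarray,
    marker_b: np.ndarray,
    dapi: np.ndarray | None = None,
    denominator: str = "A",
    min_overlap_px: int = 1,
    min_size: int = MIN_OBJECT_PX,
) -> CoassociationResult:
    """Percentage of double-positive components (A overlapping B, optionally
    DAPI-confirmed) relative to the chosen denominator population.

    ``denominator``: ``'A'`` (components of marker A, the default — e.g.
    lineage-reporter cells), ``'B'``, or ``'union'`` (components of the
    merged mask).  DAPI confirmation, when requested, applies to numerator
    and denominator alike.
    """
    a = np.asarray(marker_a, dtype=bool)
    b = np.asarray(marker_b, dtype=bool)
    if a.shape != b.shape:
        raise InputError("marker masks must share a shape")
    if denominator not in ("A", "B", "union"):
        raise ConfigurationError(f"unknown denominator {denominator!r}")

    def confirmed(props):
        if dapi is None:
            return props
        d = np.asarray(dapi, dtype=bool)
        return [p for p in props if _overlap_px(p, d) >= min_overlap_px]

    a_comps = confirmed(_components(a, min_size))
    n_double = sum(1 for p in a_comps if _overlap_px(p, b) >= min_overlap_px)
    if denominator == "A":
        n_den = len(a_comps)
    elif denominator == "B":
        n_den = len(confirmed(_components(b, min_size)))
    else:
        n_den = len(confirmed(_components(a | b, min_size)))
    if n_den == 0:
        return CoassociationResult(None, n_double, 0, denominator, flagged_empty=True)
    return CoassociationResult(
        pct=100.0 * n_double / n_den,
        n_double_positive=n_double,
        n_denominator=n_den,
        denominator=denominator,
    )


def quantify_bundle(
    bundle: ImageBundle,
    roi_name: str = "fascicle",
    threshold: ThresholdSpec | None = None,
    coassociation_pair: tuple[str, str] = ("GFP", "CD31"),
) -> QuantResult:
    """Run the full quantification panel on one image bundle.

    Projects each available channel, binarizes it, and computes whichever
    metrics the channel set supports (myelination needs NF+MBP, densities
    need an ROI, capillaries need CD31+DAPI, coassociation needs both pair
    markers).
    """
    masks = {
        name: binarize(max_project(img), threshold)
        for name, img in bundle.channels.items()
    }
    out = QuantResult()
    if "NF" in masks and "MBP" in masks:
        myel = myelination_fraction(masks["NF"], masks["MBP"])
        out.pct_myelinated = myel.pct_myelinated
        out.pct_unmyelinated = myel.pct_unmyelinated
        out.axon_count = myel.n_axons
    roi = bundle.rois.get(roi_name)
    if roi is not None:
        if "NF" in masks:
            out.axons_per_mm2 = axon_density(masks["NF"], roi, bundle.pixel_size)
        if "CD31" in masks and "DAPI" in masks:
            out.capillaries_per_mm2 = capillary_density(
                masks["CD31"], masks["DAPI"], roi, bundle.pixel_size
            )
    ka, kb = coassociation_pair
    if ka in masks and kb in masks:
        co = coassociation(masks[ka], masks[kb], masks.get("DAPI"))
        out.coassociation_pct = co.pct
    return out
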