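"""Binary post-processing primitives.

Thresholding of membership planes, 8-connected component labeling, the
20%-of-mean small-component filter, hole filling (4-connected background
holes) and cosmetic Canny edge extraction with disk dilation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import dilation, disk

from .ns_core import MembershipMap, NeutrosophicMaps

__all__ = [
    "ThresholdStrategy",
    "BinaryMask",
    "LabelMap",
    "otsu_threshold",
    "binarize",
    "invert",
    "label_components",
    "remove_small",
    "fill_holes",
    "extract_edges",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)        # fiber components: 8-connected
_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # holes: 4-connected


@dataclass(frozen=True)
class ThresholdStrategy:
    """How to turn a [0,1] plane into a mask.

    kind:
        ``"otsu_strict"``  - between-class-variance (Otsu) threshold times
        ``strictness``, capped at ``cap``.  Default for boundary and
        single-channel (nuclei) planes.
        ``"multiotsu_upper"`` - upper split of a 3-class Otsu, capped at
        ``cap``.  Default for color/black membership maps, whose value
        distribution is inherently tri-level (in-class fibers, unstained
        fibers, other-stained fibers): the strict threshold must sit above
        the middle, unstained plateau, which a 2-class split driven by
        class masses can fall below.
        ``"fixed"``        - use ``value`` directly.
    """

    kind: str = "otsu_strict"
    value: float | None = None
    strictness: float = 1.2
    cap: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in ("otsu_strict", "multiotsu_upper", "fixed"):
            raise ValueError(f"unknown threshold strategy {self.kind!r}")
        if self.kind == "fixed" and self.value is None:
            raise ValueError("fixed strategy needs a value")


@dataclass
class BinaryMask:
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class LabelMap:
    """Integer component labels, 0 = background, 1..n_components foreground."""

    labels: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def areas(self) -> np.ndarray:
        """Pixel counts of components 1..n (index 0 of the result unused)."""
        return np.bincount(self.labels.ravel(),
                           minlength=self.n_components + 1)


def otsu_threshold(plane: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance maximizing threshold of a [0,1] plane."""
    return float(threshold_otsu(np.asarray(plane, dtype=float), nbins=nbins))


def _resolve_threshold(plane: np.ndarray, strategy: ThresholdStrategy) -> float:
    if strategy.kind == "fixed":
        return float(strategy.value)
    if strategy.kind == "otsu_strict":
        return min(strategy.strictness * otsu_threshold(plane), strategy.cap)
    # multiotsu_upper; fall back to otsu_strict when the histogram cannot
    # support three classes (e.g. a two-valued plane)
    try:
        upper = float(threshold_multiotsu(np.asarray(plane, float),
                                          classes=3)[-1])
    except ValueError:
        return min(strategy.strictness * otsu_threshold(plane), strategy.cap)
    return min(upper, strategy.cap)


def binarize(plane, strategy: ThresholdStrategy | None = None) -> BinaryMask:
    """Threshold a membership/True plane: mask = plane >= threshold.

    ``plane`` may be a raw array, a :class:`MembershipMap` (its M plane) or
    :class:`NeutrosophicMaps` (its T plane).  A constant plane under an
    automatic strategy yields an all-false mask with a warning.
    """
    if isinstance(plane, MembershipMap):
        arr = plane.M
    elif isinstance(plane, NeutrosophicMaps):
        arr = plane.T
    else:
        arr = np.asarray(plane, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot binarize an empty plane")
    strategy = strategy or ThresholdStrategy()
    if strategy.kind != "fixed" and arr.min() == arr.max():
        warnings.warn("constant plane under automatic threshold; "
                      "returning empty mask", stacklevel=2)
        return BinaryMask(np.zeros(arr.shape, dtype=bool),
                          {"strategy": strategy.kind, "threshold_used": None})
    thr = _resolve_threshold(arr, strategy)
    return BinaryMask(arr >= thr,
                      {"strategy": strategy.kind, "threshold_used": thr})


def invert(mask: BinaryMask) -> BinaryMask:
    prov = dict(mask.provenance)
    prov["inverted"] = not prov.get("inverted", False)
    return BinaryMask(~mask.mask, prov)


def label_components(mask: BinaryMask | np.ndarray) -> LabelMap:
    """8-connected foreground components, labeled 1..n (background 0)."""
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    labels, n = ndimage.label(arr, structure=_STRUCT8)
    return LabelMap(labels, int(n))


def remove_small(labelmap: LabelMap, min_area_fraction: float = 0.20) -> LabelMap:
    """Drop components smaller than ``min_area_fraction`` x mean area.

    The mean is taken over all components *before* any removal; survivors
    are relabeled consecutively.  A map with no components is returned
    unchanged.
    """
    if not 0 < min_area_fraction < 1:
        raise ValueError("min_area_fraction must lie in (0, 1)")
    n = labelmap.n_components
    if n == 0:
        return LabelMap(labelmap.labels.copy(), 0)
    areas = labelmap.areas()[1:]
    cutoff = min_area_fraction * areas.mean()
    keep = areas >= cutoff
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return LabelMap(remap[labelmap.labels], int(keep.sum()))


def fill_holes(labelmap: LabelMap) -> LabelMap:
    """Assign enclosed background regions to their surrounding component.

    A hole is a 4-connected background region with no path to the image
    border; it receives the label bordering the majority of its dilated
    rim (exact ties go to the lower label).  Foreground never shrinks.
    """
    fg = labelmap.foreground
    filled = ndimage.binary_fill_holes(fg, structure=_STRUCT4)
    holes = filled & ~fg
    out = labelmap.labels.copy()
    if not holes.any():
        return LabelMap(out, labelmap.n_components)
    hole_lab, n_holes = ndimage.label(holes, structure=_STRUCT4)
    slices = ndimage.find_objects(hole_lab)
    h, w = out.shape
    for i, sl in enumerate(slices, start=1):
        rs = slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, h))
        cs = slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, w))
        sub_hole = hole_lab[rs, cs] == i
        rim = ndimage.binary_dilation(sub_hole, structure=_STRUCT8) & ~sub_hole
        neighbours = out[rs, cs][rim]
        neighbours = neighbours[neighbours > 0]
        if neighbours.size == 0:          # pragma: no cover - cannot happen
            continue
        counts = np.bincount(neighbours)
        host = int(counts.argmax())       # argmax takes the lower on ties
        sub = out[rs, cs]
        sub[sub_hole] = host
        out[rs, cs] = sub
    return LabelMap(out, labelmap.n_components)


def extract_edges(labelmap: LabelMap, dilate_radius: int = 2) -> BinaryMask:
    """Canny edges of the component mask, dilated with a disk element.

    The result is used for overlay rendering only; all areas are measured
    on the filled label maps, so the dilation radius is cosmetic.
    """
    if dilate_radius < 0:
        raise ValueError("dilate_radius must be >= 0")
    fg = labelmap.foreground
    edges = canny(fg.astype(float), sigma=1.0)
    if dilate_radius > 0:
        edges = dilation(edges, disk(dilate_radius))
    return BinaryMask(edges, {"dilate_radius": dilate_radius})
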