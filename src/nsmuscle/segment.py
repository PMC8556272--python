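"""Segmentation pipelines.

Two workflows share the same post-processing chain (binarize, label,
20%-rule, hole filling, measure):

* boundary mode: the bright laminin lattice is put into the True set,
  True/False are swapped so fibers become foreground, and every fiber of
  any type is recovered at once;
* per-color mode: each stained class (blue MyHC I, green IIa, red IIb) and
  the unstained "black" (IIx) class is segmented from its membership map
  M = T * (1 - I).

Black-mode masks alone would claim everything dark, including the space
outside the section, so the black class is intersected with the fiber
interior found by the boundary pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

from . import ns_core
from .config import Config
from .morphology import BinaryMask, LabelMap, binarize, fill_holes, invert, \
    label_components, remove_small
from .ns_core import MultiChannelImage

__all__ = [
    "CLASS_TAGS",
    "SegmentationResult",
    "measure_components",
    "segment_all",
    "segment_color",
    "segment_whole_section",
]

#: class tags and the 1-based color channel each one reads
CLASS_TAGS = {"I_blue": 3, "IIa_green": 2, "IIb_red": 1, "IIx_black": None}

_TABLE_COLUMNS = ["fiber_id", "area_px", "area_um2",
                  "centroid_r", "centroid_c"]


@dataclass
class SegmentationResult:
    """Labeled components plus a per-component morphometry table."""

    labelmap: LabelMap
    table: pd.DataFrame            # fiber_id, area_px, area_um2, centroid_r/c
    class_tag: str                 # all | I_blue | IIa_green | IIx_black | IIb_red
    summary: dict = field(default_factory=dict)
    membership: np.ndarray | None = None   # M plane used (color modes)
    calibrated: bool = False

    @property
    def n_components(self) -> int:
        return self.labelmap.n_components


def measure_components(labelmap: LabelMap, um_per_px: float = 0.0) -> pd.DataFrame:
    """Per-component area and centroid (row/column, 0-based)."""
    if labelmap.n_components == 0:
        return pd.DataFrame(columns=_TABLE_COLUMNS).astype(
            {"fiber_id": int, "area_px": int})
    props = regionprops_table(labelmap.labels,
                              properties=("label", "area", "centroid"))
    df = pd.DataFrame({
        "fiber_id": props["label"].astype(int),
        "area_px": props["area"].astype(int),
        "centroid_r": props["centroid-0"],
        "centroid_c": props["centroid-1"],
    })
    df["area_um2"] = df["area_px"] * (um_per_px ** 2) if um_per_px > 0 else np.nan
    return df[_TABLE_COLUMNS].sort_values("fiber_id").reset_index(drop=True)


def _summarize(table: pd.DataFrame) -> dict:
    n = len(table)
    return {
        "n_components": n,
        "sum_area_px": int(table["area_px"].sum()) if n else 0,
        "mean_area_px": float(table["area_px"].mean()) if n else 0.0,
    }


def _drop_border(labelmap: LabelMap) -> LabelMap:
    lab = labelmap.labels
    border = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    border = border[border > 0]
    if border.size == 0:
        return labelmap
    keep_mask = np.ones(labelmap.n_components + 1, dtype=bool)
    keep_mask[border] = False
    keep_mask[0] = False
    remap = np.zeros(labelmap.n_components + 1, dtype=np.int32)
    remap[keep_mask] = np.arange(1, int(keep_mask.sum()) + 1, dtype=np.int32)
    return LabelMap(remap[lab], int(keep_mask.sum()))


def _postprocess(mask: BinaryMask, cfg: Config) -> LabelMap:
    lm = label_components(mask)
    if cfg.exclude_border:
        # drop border-touching components (e.g. the space beyond a sparse
        # section) before they can inflate the mean of the area filter
        lm = _drop_border(lm)
    if lm.n_components:
        lm = remove_small(lm, cfg.min_area_fraction)
        lm = fill_holes(lm)
    return lm


def _finish(lm: LabelMap, class_tag: str, cfg: Config,
            membership: np.ndarray | None = None) -> SegmentationResult:
    if lm.n_components == 0:
        warnings.warn(f"no components survive for class {class_tag!r}",
                      stacklevel=3)
    table = measure_components(lm, cfg.um_per_px)
    return SegmentationResult(lm, table, class_tag, _summarize(table),
                              membership=membership,
                              calibrated=cfg.um_per_px > 0)


def _as_normalized(img: MultiChannelImage) -> MultiChannelImage:
    return img if img.normalized else ns_core.normalize_channels(img)


def segment_all(img: MultiChannelImage, cfg: Config | None = None) -> SegmentationResult:
    """Segment every fiber from the laminin boundary lattice.

    Pipeline: normalize -> boundary T/I/F -> binarize T -> invert (cells
    into the True set) -> label -> 20% small-object rule -> fill holes ->
    measure.
    """
    cfg = cfg or Config()
    img = _as_normalized(img)
    maps = ns_core.boundary_maps(img, k=1, w=cfg.window_w)
    boundary = binarize(maps.T, cfg.strategy_for("boundary"))
    if not boundary.mask.any():
        # no laminin lattice at all: an inverted empty mask would claim the
        # whole frame as one fake cell
        warnings.warn("no boundary signal detected; empty segmentation",
                      stacklevel=2)
        return _finish(LabelMap(np.zeros(img.shape, np.int32), 0), "all", cfg)
    cells = invert(boundary)
    lm = _postprocess(cells, cfg)
    return _finish(lm, "all", cfg)


def segment_color(img: MultiChannelImage, cell_class: str,
                  cfg: Config | None = None,
                  interior: np.ndarray | None = None) -> SegmentationResult:
    """Segment one fiber class from its membership map.

    ``cell_class`` is one of ``I_blue``, ``IIa_green``, ``IIb_red``,
    ``IIx_black``.  For the black class the thresholded mask is
    intersected with ``interior`` (foreground of :func:`segment_all`,
    computed on the fly when not supplied): IIx fibers are unstained but
    still laminin-bounded.
    """
    cfg = cfg or Config()
    if cell_class not in CLASS_TAGS:
        raise ValueError(f"unknown cell class {cell_class!r}; "
                         f"expected one of {sorted(CLASS_TAGS)}")
    img = _as_normalized(img)
    k = CLASS_TAGS[cell_class]
    if k is None:
        maps = ns_core.black_maps(img, w=cfg.window_w)
    else:
        maps = ns_core.color_maps(img, k=k, w=cfg.window_w)
    m = ns_core.membership(maps)
    mask = binarize(m, cfg.strategy_for(maps.mode))
    # absolute stain-positivity gate on the raw tau scale: min-max
    # normalization stretches whatever is present to T = 1, so without an
    # absolute anchor a class absent from the image would still segment
    # its best-scoring pixels
    gate = cfg.black_positivity_tau if k is None else cfg.color_positivity_tau
    mask = BinaryMask(mask.mask & (maps.tau > gate),
                      {**mask.provenance, "positivity_tau": gate})
    if k is None:
        if interior is None:
            interior = segment_all(img, cfg).labelmap.foreground
        if interior.shape != mask.mask.shape:
            raise ValueError("interior mask shape mismatch")
        mask = BinaryMask(mask.mask & interior,
                          {**mask.provenance, "interior_restricted": True})
    lm = _postprocess(mask, cfg)
    return _finish(lm, cell_class, cfg, membership=m.M)


def segment_whole_section(img: MultiChannelImage,
                          cfg: Config | None = None) -> dict[str, SegmentationResult]:
    """Run the boundary pipeline plus all four fiber classes.

    Returns a mapping with keys ``all``, ``I_blue``, ``IIa_green``,
    ``IIx_black``, ``IIb_red``.  Downstream type assignment
    (:func:`nsmuscle.quantify.assign_types`) guarantees each
    laminin-delimited fiber lands in exactly one class.
    """
    cfg = cfg or Config()
    img = _as_normalized(img)
    results: dict[str, SegmentationResult] = {"all": segment_all(img, cfg)}
    interior = results["all"].labelmap.foreground
    for tag in ("I_blue", "IIa_green", "IIx_black", "IIb_red"):
        results[tag] = segment_color(img, tag, cfg, interior=interior)
    return results
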