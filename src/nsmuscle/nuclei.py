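"""Myonucleus and satellite-cell detection.

DAPI nuclei and Pax7+ blobs are segmented with the single-channel
neutrosophic pipeline (the indeterminacy plane normalizes away local
intensity variation that otherwise over-segments dim nuclei).  A detected
nucleus is a *myonucleus* of a fiber when its centroid lies inside that
fiber's mask AND strictly more than 50% of its area does; a *satellite
cell* is a Pax7+ blob mutually overlapping a DAPI nucleus by at least 50%
and sitting within a few pixels of the fiber boundary (sub-laminar
position).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy.ndimage import distance_transform_edt, find_objects

from . import ns_core
from .config import Config
from .morphology import LabelMap, binarize, fill_holes, label_components, \
    remove_small
from .segment import measure_components

__all__ = [
    "NucleusRecord",
    "NucleiResult",
    "detect_nuclei",
    "classify_myonuclei",
    "detect_satellite_cells",
    "myonuclei_per_fiber",
]


@dataclass
class NucleusRecord:
    nucleus_id: int
    centroid_rc: tuple[float, float]
    area_px: int
    overlap_fraction: float = 0.0
    host_fiber_id: int | None = None
    kind: str = "unclassified"     # myonucleus | satellite | excluded


@dataclass
class NucleiResult:
    """Detections plus the labelmap they were measured on."""

    labelmap: LabelMap
    records: list[NucleusRecord] = field(default_factory=list)


def detect_nuclei(channel: np.ndarray, cfg: Config | None = None) -> NucleiResult:
    """Segment blobs in a single fluorescence channel (DAPI or Pax7).

    Pipeline: min-max normalize -> single-channel T/I/F -> M = T(1-I) ->
    strict binarize -> label -> small-object removal -> hole fill ->
    measure.  A blank (constant) channel yields zero detections.
    """
    cfg = cfg or Config()
    plane = np.asarray(channel, dtype=float)
    if plane.ndim != 2:
        raise ValueError("detect_nuclei expects a single 2-D channel")
    if plane.min() == plane.max():
        return NucleiResult(LabelMap(np.zeros(plane.shape, np.int32), 0), [])
    norm = ns_core.minmax_scale(plane, what="nucleus channel")
    maps = ns_core.single_channel_maps(norm, w=cfg.nucleus_window_w)
    m = ns_core.membership(maps)
    mask = binarize(m, cfg.strategy_for("single"))
    lm = label_components(mask)
    if lm.n_components:
        lm = remove_small(lm, cfg.min_area_fraction)
        lm = fill_holes(lm)
    table = measure_components(lm)
    records = [NucleusRecord(int(r.fiber_id),
                             (float(r.centroid_r), float(r.centroid_c)),
                             int(r.area_px))
               for r in table.itertuples()]
    return NucleiResult(lm, records)


def _overlap_with_fibers(nucleus_mask: np.ndarray, fiber_labels: np.ndarray
                         ) -> tuple[int | None, float]:
    """(host fiber, overlap fraction) for one nucleus pixel mask.

    Host is the fiber maximizing the overlap; exact ties go to the lower
    fiber id (bincount argmax returns the first maximum).
    """
    under = fiber_labels[nucleus_mask]
    area = under.size
    counts = np.bincount(under)
    if counts.size <= 1 or counts[1:].max() == 0:
        return None, 0.0
    host = int(counts[1:].argmax()) + 1
    return host, counts[host] / area


def classify_myonuclei(detections: NucleiResult, fibers: LabelMap
                       ) -> list[NucleusRecord]:
    """Apply the myonucleus inclusion rule against a fiber label map.

    kind = "myonucleus" iff the centroid pixel lies inside the
    maximum-overlap fiber AND strictly more than half the nucleus area is
    inside that same fiber; otherwise "excluded".  Returns new records.
    """
    lab = detections.labelmap.labels
    if lab.shape != fibers.labels.shape:
        raise ValueError("nuclei / fiber geometry mismatch")
    slices = find_objects(lab)
    out = []
    h, w = lab.shape
    for rec in detections.records:
        sl = slices[rec.nucleus_id - 1]
        nmask = lab[sl] == rec.nucleus_id
        host, frac = _overlap_with_fibers(nmask, fibers.labels[sl])
        cr = min(max(int(round(rec.centroid_rc[0])), 0), h - 1)
        cc = min(max(int(round(rec.centroid_rc[1])), 0), w - 1)
        inside = host is not None and fibers.labels[cr, cc] == host
        kind = "myonucleus" if (inside and frac > 0.5) else "excluded"
        out.append(NucleusRecord(rec.nucleus_id, rec.centroid_rc, rec.area_px,
                                 overlap_fraction=float(frac),
                                 host_fiber_id=host, kind=kind))
    return out


def detect_satellite_cells(pax7_channel: np.ndarray,
                           dapi: NucleiResult,
                           classified: list[NucleusRecord],
                           fibers: LabelMap,
                           cfg: Config | None = None) -> list[NucleusRecord]:
    """Upgrade DAPI nuclei matched by a sub-laminar Pax7 blob to satellites.

    A Pax7 blob marks a satellite cell when (a) it mutually overlaps one
    DAPI nucleus by >= 50% of both areas and (b) its centroid lies within
    ``cfg.sublaminar_px`` of the fiber boundary (distance measured to the
    nearest non-fiber pixel; blobs outside any fiber are at distance 0).
    Returns the full updated record list, so
    myonuclei + satellites + excluded still partition all detections.
    """
    cfg = cfg or Config()
    if pax7_channel is None:
        raise ValueError("pax7 channel is required")
    pax = detect_nuclei(np.asarray(pax7_channel, float), cfg)
    if pax.labelmap.labels.shape != fibers.labels.shape:
        raise ValueError("pax7 / fiber geometry mismatch")
    dist_to_boundary = distance_transform_edt(fibers.foreground)
    dlab = dapi.labelmap.labels
    darea = dapi.labelmap.areas()
    out = {r.nucleus_id: r for r in classified}
    h, w = dlab.shape
    pslices = find_objects(pax.labelmap.labels)
    for blob in pax.records:
        sl = pslices[blob.nucleus_id - 1]
        bmask = pax.labelmap.labels[sl] == blob.nucleus_id
        under = dlab[sl][bmask]
        counts = np.bincount(under)
        if counts.size <= 1 or counts[1:].max() == 0:
            continue
        nid = int(counts[1:].argmax()) + 1
        shared = counts[nid]
        if shared < 0.5 * blob.area_px or shared < 0.5 * darea[nid]:
            continue
        cr = min(max(int(round(blob.centroid_rc[0])), 0), h - 1)
        cc = min(max(int(round(blob.centroid_rc[1])), 0), w - 1)
        if dist_to_boundary[cr, cc] > cfg.sublaminar_px:
            continue
        prev = out[nid]
        out[nid] = NucleusRecord(prev.nucleus_id, prev.centroid_rc,
                                 prev.area_px, prev.overlap_fraction,
                                 prev.host_fiber_id, kind="satellite")
    return [out[r.nucleus_id] for r in classified]


def myonuclei_per_fiber(records: list[NucleusRecord],
                        fiber_table: pd.DataFrame) -> pd.DataFrame:
    """Count myonuclei per host fiber; fibers with none report 0."""
    counts: dict[int, int] = {}
    for r in records:
        if r.kind == "myonucleus" and r.host_fiber_id is not None:
            counts[r.host_fiber_id] = counts.get(r.host_fiber_id, 0) + 1
    df = fiber_table[["fiber_id"]].copy()
    df["n_myonuclei"] = df["fiber_id"].map(counts).fillna(0).astype(int)
    return df
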