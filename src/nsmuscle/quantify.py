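"""Fiber-type assignment, CSA statistics and subset-vs-whole comparisons.

Each laminin-delimited fiber receives the stained class (MyHC I, IIa or
IIb) whose mask covers the largest fraction of its pixels; fibers not
majority-covered by any stained class are the unstained IIx type.  Section
reports aggregate counts, mean cross-sectional area (CSA) and type
proportions, and ``subset_vs_whole`` quantifies the sampling bias of
estimating CSA from a handful of image tiles instead of the whole section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import SegmentationResult

__all__ = [
    "FIBER_TYPES",
    "FiberRecord",
    "SectionReport",
    "assign_types",
    "records_frame",
    "section_report",
    "subset_vs_whole",
]

FIBER_TYPES = ("I", "IIa", "IIx", "IIb")

#: stained classes in tie-break priority order, with their result tags
_STAINED = (("I", "I_blue"), ("IIa", "IIa_green"), ("IIb", "IIb_red"))


@dataclass
class FiberRecord:
    fiber_id: int
    area_px: int
    area_um2: float
    centroid_rc: tuple[float, float]
    type: str
    type_coverage: float
    n_myonuclei: int = 0

    @property
    def csa(self) -> float:
        """Cross-sectional area in um^2 when calibrated, else px^2."""
        return self.area_um2 if np.isfinite(self.area_um2) else float(self.area_px)


@dataclass
class SectionReport:
    overall: dict
    per_type: pd.DataFrame        # index: type; count, mean_csa, proportion
    histogram: dict               # bin_edges, counts, bin_width
    area_unit: str                # "um2" or "px2"


def assign_types(fibers: SegmentationResult,
                 color_results: dict[str, SegmentationResult]) -> list[FiberRecord]:
    """Assign exactly one MyHC type to every fiber.

    Rule: the stained class covering the largest fraction of the fiber's
    pixels wins; below 0.5 majority coverage the fiber is the unstained
    IIx type.  Exact coverage ties break on higher mean membership M
    inside the fiber, then on the fixed priority I > IIa > IIb.
    """
    labels = fibers.labelmap.labels
    n = fibers.labelmap.n_components
    areas = np.bincount(labels.ravel(), minlength=n + 1).astype(float)

    cover = np.zeros((n + 1, len(_STAINED)))
    mean_m = np.zeros((n + 1, len(_STAINED)))
    for j, (_, tag) in enumerate(_STAINED):
        res = color_results[tag]
        if res.labelmap.labels.shape != labels.shape:
            raise ValueError(f"geometry mismatch for class {tag!r}")
        class_fg = res.labelmap.foreground
        cover[:, j] = np.bincount(labels[class_fg], minlength=n + 1)
        if res.membership is not None:
            sums = np.bincount(labels.ravel(), weights=res.membership.ravel(),
                               minlength=n + 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_m[:, j] = np.where(areas > 0, sums / areas, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cover = np.where(areas[:, None] > 0, cover / areas[:, None], 0.0)

    records = []
    for fid, row in fibers.table.iterrows():
        i = int(row["fiber_id"])
        cov = cover[i]
        best = cov.max()
        if best < 0.5:
            ftype, tcov = "IIx", float(best)
        else:
            winners = np.flatnonzero(cov == best)
            if winners.size > 1:
                mm = mean_m[i, winners]
                winners = winners[mm == mm.max()]
            ftype, tcov = _STAINED[winners[0]][0], float(best)
        records.append(FiberRecord(
            fiber_id=i,
            area_px=int(row["area_px"]),
            area_um2=float(row["area_um2"]),
            centroid_rc=(float(row["centroid_r"]), float(row["centroid_c"])),
            type=ftype,
            type_coverage=tcov,
        ))
    return records


def records_frame(records: list[FiberRecord]) -> pd.DataFrame:
    """Flatten FiberRecords into the canonical per-fiber table."""
    return pd.DataFrame([{
        "fiber_id": r.fiber_id,
        "type": r.type,
        "area_px": r.area_px,
        "area_um2": r.area_um2,
        "centroid_r": r.centroid_rc[0],
        "centroid_c": r.centroid_rc[1],
        "type_coverage": r.type_coverage,
        "n_myonuclei": r.n_myonuclei,
    } for r in records], columns=["fiber_id", "type", "area_px", "area_um2",
                                  "centroid_r", "centroid_c",
                                  "type_coverage", "n_myonuclei"])


def section_report(records: list[FiberRecord],
                   bin_width: float = 250.0) -> SectionReport:
    """Counts, mean CSA (overall and per type), proportions, histogram.

    The default histogram bin width of 250 is in um^2 for calibrated
    images and px^2 otherwise.
    """
    n = len(records)
    calibrated = n > 0 and all(np.isfinite(r.area_um2) for r in records)
    csas = np.array([r.csa for r in records], dtype=float)
    per_type_rows = {}
    for t in FIBER_TYPES:
        sel = csas[[r.type == t for r in records]]
        per_type_rows[t] = {
            "count": int(sel.size),
            "mean_csa": float(sel.mean()) if sel.size else np.nan,
            "proportion": sel.size / n if n else 0.0,
        }
    per_type = pd.DataFrame.from_dict(per_type_rows, orient="index")
    if n:
        hi = max(csas.max(), bin_width)
        edges = np.arange(0.0, hi + bin_width, bin_width)
        counts, edges = np.histogram(csas, bins=edges)
    else:
        edges, counts = np.array([0.0, bin_width]), np.array([0])
    return SectionReport(
        overall={"count": n, "mean_csa": float(csas.mean()) if n else np.nan},
        per_type=per_type,
        histogram={"bin_edges": edges, "counts": counts,
                   "bin_width": bin_width},
        area_unit="um2" if calibrated else "px2",
    )


def _tile_index(records, image_size, tile_grid) -> np.ndarray:
    rows, cols = tile_grid
    h, w = image_size
    idx = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        tr = min(int(r.centroid_rc[0] * rows / h), rows - 1)
        tc = min(int(r.centroid_rc[1] * cols / w), cols - 1)
        idx[i] = tr * cols + tc
    return idx


def subset_vs_whole(records: list[FiberRecord],
                    image_size: tuple[int, int],
                    tile_grid: tuple[int, int] = (3, 4),
                    n_tiles_sampled: int = 12,
                    seed: int = 0) -> pd.DataFrame:
    """Compare per-type counts and mean CSA from sampled tiles vs the whole.

    The section is partitioned into a ``tile_grid`` of equal tiles;
    ``n_tiles_sampled`` tiles are drawn without replacement and statistics
    are recomputed from the fibers whose centroids fall inside them.
    Sampling all tiles reproduces the whole-section values exactly.
    """
    rows, cols = tile_grid
    total = rows * cols
    if n_tiles_sampled > total:
        raise ValueError(f"cannot sample {n_tiles_sampled} of {total} tiles")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(total, size=n_tiles_sampled, replace=False).tolist())
    tiles = _tile_index(records, image_size, tile_grid)
    subset = [r for r, t in zip(records, tiles) if t in chosen]

    def stats(recs, t=None):
        sel = [r for r in recs if t is None or r.type == t]
        csa = np.array([r.csa for r in sel], dtype=float)
        return len(sel), float(csa.mean()) if len(sel) else np.nan

    out = []
    for t in (*FIBER_TYPES, "all"):
        key = None if t == "all" else t
        wc, wm = stats(records, key)
        sc, sm = stats(subset, key)
        out.append({"type": t, "whole_count": wc, "subset_count": sc,
                    "whole_mean_csa": wm, "subset_mean_csa": sm,
                    "delta_count": sc - wc,
                    "delta_mean_csa": sm - wm if np.isfinite(sm) and
                    np.isfinite(wm) else np.nan})
    return pd.DataFrame(out).set_index("type")
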