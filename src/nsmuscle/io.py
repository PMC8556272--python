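"""Image and table I/O plus the run manifest.

Inputs: 8/16-bit TIFF (multi-channel or per-channel) and 8-bit PNG.
Outputs: per-fiber CSV (RFC-4180, dot decimal), summary JSON, 16-bit label
TIFF per class, RGB overlay PNG with dilated edges, and a JSON manifest
sufficient to replay the run bit-identically.  All writes are atomic
(write to a temp file in the target directory, then rename).

Coordinates everywhere are row/column, 0-based, pixel-center; areas are
whole pixels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import Config
from .morphology import LabelMap, extract_edges
from .ns_core import MultiChannelImage
from .segment import SegmentationResult

__all__ = ["read_image", "write_image", "read_labelmap", "write_outputs",
           "RunManifest"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly.

    Deliberately free of wall-clock timestamps so that identical runs
    produce byte-identical manifests.
    """

    inputs: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = __version__
    warnings: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)   # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _bit_depth(dtype) -> int:
    return int(np.iinfo(dtype).max) + 1 if np.issubdtype(dtype, np.integer) else 256


def read_image(path: str | Path, channel_roles: dict[str, int] | None = None,
               um_per_px: float = 0.0) -> MultiChannelImage:
    """Load a TIFF or PNG as a MultiChannelImage.

    Channel-first TIFF stacks (K <= 5 leading axis) are transposed to
    H x W x K.  When ``channel_roles`` is omitted, 3-channel images get
    red/green/blue roles and single-channel images the laminin role.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[0] <= 5 < min(arr.shape[1:]):
        arr = np.moveaxis(arr, 0, -1)
    if arr.ndim == 3 and arr.shape[2] == 4:      # drop PNG alpha
        arr = arr[:, :, :3]
    depth = _bit_depth(arr.dtype)
    k = 1 if arr.ndim == 2 else arr.shape[2]
    if channel_roles is None:
        if k == 3:
            channel_roles = {"red": 0, "green": 1, "blue": 2}
        elif k == 1:
            channel_roles = {"laminin": 0}
        else:
            raise ValueError(f"{path}: {k} channels need explicit "
                             f"channel_roles")
    for role, idx in channel_roles.items():
        if not 0 <= idx < k:
            raise ValueError(f"{path}: role {role!r} -> channel {idx}, "
                             f"image has {k} channels")
    return MultiChannelImage(arr.astype(float), dict(channel_roles),
                             bit_depth=depth, um_per_px=um_per_px)


def _atomic_bytes(path: Path, data: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_image(path: str | Path, array: np.ndarray) -> None:
    """Atomically write an array as TIFF (any dtype) or 8-bit PNG."""
    path = Path(path)
    import io as _io
    buf = _io.BytesIO()
    if path.suffix.lower() in (".tif", ".tiff"):
        kw = {}
        if array.ndim == 3 and array.shape[0] <= 5:    # channel-first stack
            kw["photometric"] = "minisblack"
        tifffile.imwrite(buf, array, **kw)
    else:
        iio.imwrite(buf, array, extension=path.suffix.lower())
    _atomic_bytes(path, buf.getvalue())


def read_labelmap(path: str | Path) -> LabelMap:
    arr = tifffile.imread(path).astype(np.int32)
    return LabelMap(arr, int(arr.max()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(outdir: str | Path,
                  results: dict[str, SegmentationResult],
                  fiber_table: pd.DataFrame | None = None,
                  report: dict | None = None,
                  img: MultiChannelImage | None = None,
                  cfg: Config | None = None,
                  inputs: list[str] | None = None,
                  warnings_seen: list[str] | None = None) -> RunManifest:
    """Write CSV/JSON/TIFF/PNG outputs plus the manifest; returns it."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    cfg = cfg or Config()
    written: list[Path] = []

    header = ("# nsmuscle per-fiber table; coordinates row/column 0-based "
              "pixel-center; areas in whole pixels"
              + ("" if cfg.um_per_px > 0
                 else "; area_um2 empty (uncalibrated)") + "\n")
    if fiber_table is None:
        fiber_table = results["all"].table.assign(type="", n_myonuclei=0) \
            if "all" in results else pd.DataFrame()
    csv_path = outdir / "fibers.csv"
    _atomic_bytes(csv_path,
                  (header + fiber_table.to_csv(index=False)).encode())
    written.append(csv_path)

    summary = {tag: res.summary for tag, res in results.items()}
    if report is not None:
        summary["report"] = report
    sj = outdir / "summary.json"
    _atomic_bytes(sj, json.dumps(summary, indent=2, sort_keys=True,
                                 default=float).encode())
    written.append(sj)

    for tag, res in results.items():
        if res.labelmap.n_components > np.iinfo(np.uint16).max:
            raise ValueError(f"class {tag}: too many components for uint16")
        p = outdir / f"labels_{tag}.tif"
        write_image(p, res.labelmap.labels.astype(np.uint16))
        written.append(p)

    if img is not None and "all" in results:
        edges = extract_edges(results["all"].labelmap, cfg.dilate_radius)
        if img.has_rgb:
            rgb = np.stack([img.channel("red"), img.channel("green"),
                            img.channel("blue")], axis=-1)
        else:
            g = img.pixels[:, :, 0]
            rgb = np.stack([g, g, g], axis=-1)
        rgb = rgb / max(rgb.max(), 1e-12)
        rgb[edges.mask] = (0.0, 0.3, 1.0)     # boundaries drawn in blue
        p = outdir / "overlay.png"
        write_image(p, (rgb * 255).astype(np.uint8))
        written.append(p)

    manifest = RunManifest(
        inputs=[str(x) for x in (inputs or [])],
        config=cfg.to_dict(),
        warnings=list(warnings_seen or []),
        outputs={p.name: _sha256(p) for p in sorted(written)},
    )
    _atomic_bytes(outdir / "manifest.json", manifest.to_json().encode())
    return manifest
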