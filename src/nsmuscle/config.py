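"""Run configuration: every unpublished knob of the pipeline in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .morphology import ThresholdStrategy

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    """Pipeline parameters with validated defaults.

    window_w:
        Odd side length (px) of the local-mean window used by the
        indeterminacy planes; ~ fiber-boundary scale at 10x magnification.
    nucleus_window_w:
        Local-mean window for single-channel nucleus detection; must be
        smaller than a nucleus diameter, otherwise the indeterminacy plane
        treats whole nuclei as local deviations and suppresses them.
    threshold_strategy:
        "auto" picks per plane type (otsu_strict for boundary/nuclei
        planes, multiotsu_upper for color/black membership maps);
        "otsu_strict" / "multiotsu_upper" force one; "fixed" uses
        ``fixed_threshold`` everywhere.
    strictness_factor / threshold_cap:
        Strict-threshold scaling of the Otsu split and its upper cap.
    min_area_fraction:
        Components below this fraction of the mean component area are
        discarded (the 20% rule).
    color_positivity_tau / black_positivity_tau:
        Absolute stain-positivity gates on the raw tau scale [0, 3].
        Min-max normalization always stretches *something* to T = 1, so a
        class absent from the image would otherwise still segment its
        best-scoring pixels.  A pixel can belong to a stained class only
        if its own channel clearly dominates (tau_k > 2.15, i.e. C_k
        exceeds the combined other-channel brightness by 0.15) and to the
        unstained class only if it is genuinely dark in all channels
        (tau_black > 2.65, i.e. total brightness below 0.35).
    dilate_radius:
        Disk radius for cosmetic edge thickening in overlays.
    um_per_px:
        Pixel pitch; 0 = uncalibrated, areas reported in px^2.
    sublaminar_px:
        Maximum distance (px) from the fiber boundary at which a
        Pax7+/DAPI+ blob counts as a satellite cell.
    exclude_border:
        Drop components touching the image border (off by default; no such
        exclusion is applied by the reference workflow).
    """

    window_w: int = 15
    nucleus_window_w: int = 5
    threshold_strategy: str = "auto"
    fixed_threshold: float | None = None
    strictness_factor: float = 1.2
    threshold_cap: float = 0.95
    min_area_fraction: float = 0.20
    color_positivity_tau: float = 2.15
    black_positivity_tau: float = 2.65
    dilate_radius: int = 2
    um_per_px: float = 0.0
    sublaminar_px: float = 2.0
    exclude_border: bool = False
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.window_w < 3 or self.window_w % 2 == 0:
            raise ValueError("window_w must be odd and >= 3")
        if self.nucleus_window_w < 3 or self.nucleus_window_w % 2 == 0:
            raise ValueError("nucleus_window_w must be odd and >= 3")
        if self.threshold_strategy not in ("auto", "otsu_strict",
                                           "multiotsu_upper", "fixed"):
            raise ValueError(f"bad threshold_strategy "
                             f"{self.threshold_strategy!r}")
        if self.threshold_strategy == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed strategy needs fixed_threshold")
        if not 0 < self.min_area_fraction < 1:
            raise ValueError("min_area_fraction must lie in (0, 1)")
        for gate in (self.color_positivity_tau, self.black_positivity_tau):
            if not 0 <= gate <= 3:
                raise ValueError("positivity gates live on the tau scale [0,3]")
        if self.dilate_radius < 0:
            raise ValueError("dilate_radius must be >= 0")
        if self.um_per_px < 0:
            raise ValueError("um_per_px must be >= 0")
        if self.sublaminar_px < 0:
            raise ValueError("sublaminar_px must be >= 0")
        if not 0 < self.strictness_factor <= 5:
            raise ValueError("strictness_factor out of range")
        if not 0 < self.threshold_cap <= 1:
            raise ValueError("threshold_cap must lie in (0, 1]")

    # -- threshold strategy resolution -----------------------------------
    def strategy_for(self, plane_kind: str) -> ThresholdStrategy:
        """Strategy for ``plane_kind`` in {boundary, color, black, single}."""
        if self.threshold_strategy == "fixed":
            return ThresholdStrategy("fixed", value=self.fixed_threshold)
        if self.threshold_strategy == "auto":
            kind = ("multiotsu_upper" if plane_kind in ("color", "black")
                    else "otsu_strict")
        else:
            kind = self.threshold_strategy
        return ThresholdStrategy(kind, strictness=self.strictness_factor,
                                 cap=self.threshold_cap)

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Build a Config from a TOML file plus keyword overrides.

    Precedence: explicit overrides > file values > built-in defaults.
    Override values of None are ignored.
    """
    values: dict = {}
    if path is not None:
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(Config)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return Config(**values)
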