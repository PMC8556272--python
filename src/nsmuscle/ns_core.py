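"""Neutrosophic-domain transforms for multi-channel muscle-section images.

A fluorescence section image is mapped into neutrosophic True (T),
Indeterminacy (I) and False (F) planes.  T measures how strongly a pixel
belongs to a target structure (fiber boundary, a stained fiber class, an
unstained "black" fiber, or a single-channel blob), I measures how far the
pixel deviates from its local neighbourhood mean (low I = confident
assignment), and F is the complement of T.  The fused membership map
M = T * (1 - I) combines both with an AND relation and is the plane that is
binarized downstream.

Channel indexing follows the 1-based red/green/blue convention:
k = 1 red (MyHC IIb), k = 2 green (MyHC IIa), k = 3 blue (MyHC I).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "MultiChannelImage",
    "NeutrosophicMaps",
    "MembershipMap",
    "normalize_channels",
    "theta",
    "channel_triplet",
    "local_mean",
    "minmax_scale",
    "boundary_maps",
    "color_maps",
    "black_maps",
    "single_channel_maps",
    "membership",
]

#: recognised channel roles
ROLES = ("red", "green", "blue", "laminin", "dapi", "pax7")

_COLOR_ROLE_BY_K = {1: "red", 2: "green", 3: "blue"}


@dataclass
class MultiChannelImage:
    """H x W x K intensity array with channel semantics.

    Parameters
    ----------
    pixels:
        ``(H, W, K)`` (or ``(H, W)`` for a single channel) array of
        intensities.  Stored as float64.
    channel_roles:
        Mapping from role name (one of :data:`ROLES`) to the 0-based channel
        index in ``pixels``.  The public red/green/blue channel number ``k``
        is 1-based and resolved through this mapping, so the storage order
        of channels never matters.
    bit_depth:
        Number of gray levels of the source data (256 for 8-bit).
    um_per_px:
        Pixel pitch in micrometres; 0 means uncalibrated (areas are then
        reported in px^2).
    normalized:
        True once every channel has been min-max scaled to [0, 1].
    """

    pixels: np.ndarray
    channel_roles: dict[str, int] = field(default_factory=dict)
    bit_depth: int = 256
    um_per_px: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[..., np.newaxis]
        if px.ndim != 3:
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {px.shape}")
        h, w, k = px.shape
        if h < 1 or w < 1 or not 1 <= k <= 5:
            raise ValueError(f"invalid image shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if self.um_per_px < 0:
            raise ValueError("um_per_px must be >= 0")
        for role, idx in self.channel_roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if not 0 <= idx < k:
                raise ValueError(f"role {role!r} points at channel {idx}, "
                                 f"image has {k}")
        self.pixels = px

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    # -- channel access ---------------------------------------------------
    def has_role(self, role: str) -> bool:
        return role in self.channel_roles

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D plane carrying ``role``."""
        try:
            return self.pixels[:, :, self.channel_roles[role]]
        except KeyError:
            raise KeyError(f"image has no {role!r} channel "
                           f"(roles: {sorted(self.channel_roles)})") from None

    def color_plane(self, k: int) -> np.ndarray:
        """Return the plane for 1-based color channel k (1=R, 2=G, 3=B)."""
        if k not in _COLOR_ROLE_BY_K:
            raise ValueError(f"color channel k must be 1, 2 or 3, got {k}")
        return self.channel(_COLOR_ROLE_BY_K[k])

    @property
    def has_rgb(self) -> bool:
        return all(r in self.channel_roles for r in ("red", "green", "blue"))


@dataclass
class NeutrosophicMaps:
    """Per-mode True / Indeterminacy / False planes, all in [0, 1]."""

    T: np.ndarray
    I: np.ndarray
    F: np.ndarray
    mode: str               # boundary | color | black | single
    channel_k: int
    window_w: int
    tau: np.ndarray | None = None    # raw tau before min-max normalization

    def __post_init__(self) -> None:
        if not (self.T.shape == self.I.shape == self.F.shape):
            raise ValueError("T, I, F must share one shape")


@dataclass
class MembershipMap:
    """Fused membership M = T * (1 - I)."""

    M: np.ndarray
    mode: str
    channel_k: int


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def minmax_scale(plane: np.ndarray, *, what: str = "plane") -> np.ndarray:
    """Min-max normalize ``plane`` to [0, 1] over the whole matrix.

    A degenerate plane (max == min) maps to all zeros and emits a warning:
    a constant input carries no information, and this avoids the division
    by zero of the raw formula.
    """
    plane = np.asarray(plane, dtype=float)
    lo = plane.min()
    hi = plane.max()
    if hi == lo:
        warnings.warn(f"degenerate min-max normalization: {what} is constant "
                      f"({lo!r}); output set to zeros", stacklevel=2)
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def normalize_channels(img: MultiChannelImage) -> MultiChannelImage:
    """Min-max scale every channel of ``img`` to [0, 1] independently."""
    out = np.empty_like(img.pixels)
    for c in range(img.n_channels):
        out[:, :, c] = minmax_scale(img.pixels[:, :, c], what=f"channel {c}")
    return MultiChannelImage(out, dict(img.channel_roles), img.bit_depth,
                             img.um_per_px, normalized=True)


def theta(h: int) -> int:
    """Wrap a channel-index sum back into {1, 2, 3}: h if h<=3 else h-2."""
    if h not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"theta defined on 1..6, got {h}")
    return h if h <= 3 else h - 2


def channel_triplet(k: int) -> tuple[int, int, int]:
    """Return ``(k, other1, other2)``, a permutation of {1, 2, 3}.

    The companions are ``max(3-k, 1)`` and ``theta(k + max(3-k, 1))``.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"channel k must be 1, 2 or 3, got {k}")
    o1 = max(3 - k, 1)
    o2 = theta(k + o1)
    return (k, o1, o2)


def local_mean(plane: np.ndarray, w: int) -> np.ndarray:
    """w x w sliding-window mean with replicate-edge padding.

    ``w`` must be odd and >= 3 and no larger than either image dimension.
    """
    plane = np.asarray(plane, dtype=float)
    if w < 3 or w % 2 == 0:
        raise ValueError(f"window w must be odd and >= 3, got {w}")
    if plane.shape[0] < w or plane.shape[1] < w:
        raise ValueError(f"image {plane.shape} smaller than {w}x{w} window")
    return uniform_filter(plane, size=w, mode="nearest")


def _indeterminacy(tau_like: np.ndarray, w: int) -> np.ndarray:
    """|x - local w x w mean of x|, min-max scaled."""
    phi = np.abs(tau_like - local_mean(tau_like, w))
    return minmax_scale(phi, what="phi (local-mean deviation)")


def _require_normalized(img: MultiChannelImage) -> None:
    if not img.normalized:
        raise ValueError("image must be normalized to [0,1] first "
                         "(use normalize_channels)")


# ---------------------------------------------------------------------------
# the four map constructions
# ---------------------------------------------------------------------------

def boundary_maps(img: MultiChannelImage, k: int = 1, w: int = 15) -> NeutrosophicMaps:
    """T/I/F for the fiber-boundary (laminin) structure.

    tau sums the triplet channels per pixel, so bright-in-all-channels
    laminin ridges attain the maximum.  T is the min-max scaled tau, the
    indeterminacy derives from the deviation of tau from its local w x w
    mean, and F = 1 - T.  When the image carries a dedicated single
    ``laminin`` channel instead of RGB, tau is that channel directly.
    """
    _require_normalized(img)
    if img.has_rgb:
        t1, t2, t3 = channel_triplet(k)
        tau = (img.color_plane(t1) + img.color_plane(t2) + img.color_plane(t3))
    elif img.has_role("laminin"):
        tau = img.channel("laminin").copy()
    elif img.n_channels == 1:
        tau = img.pixels[:, :, 0].copy()
    else:
        raise ValueError("boundary_maps needs RGB roles or a laminin channel")
    T = minmax_scale(tau, what="tau (boundary)")
    I = _indeterminacy(tau, w)
    return NeutrosophicMaps(T=T, I=I, F=1.0 - T, mode="boundary",
                            channel_k=k, window_w=w, tau=tau)


def color_maps(img: MultiChannelImage, k: int, w: int = 15) -> NeutrosophicMaps:
    """T/I/F for the stained fiber class carried by color channel k.

    tau_k = C_k + (1 - C_other1) + (1 - C_other2): a pixel scores high when
    bright in its own channel and dark in both others.  The indeterminacy
    uses the deviation of the single channel C_k from its local mean.
    """
    _require_normalized(img)
    if not img.has_rgb:
        raise ValueError("color_maps needs red/green/blue channel roles")
    kk, o1, o2 = channel_triplet(k)
    ck = img.color_plane(kk)
    tau = ck + (1.0 - img.color_plane(o1)) + (1.0 - img.color_plane(o2))
    T = minmax_scale(tau, what=f"tau (color k={k})")
    I = _indeterminacy(ck, w)
    return NeutrosophicMaps(T=T, I=I, F=1.0 - T, mode="color",
                            channel_k=k, window_w=w, tau=tau)


def black_maps(img: MultiChannelImage, w: int = 15) -> NeutrosophicMaps:
    """T/I/F for unstained ("black") fibers: tau = sum of (1 - C) over RGB.

    The darker a pixel is in all channels simultaneously, the higher its
    membership; lowering any single channel value strictly raises tau.
    """
    _require_normalized(img)
    if not img.has_rgb:
        raise ValueError("black_maps needs red/green/blue channel roles")
    t1, t2, t3 = channel_triplet(1)
    tau = ((1.0 - img.color_plane(t1)) + (1.0 - img.color_plane(t2))
           + (1.0 - img.color_plane(t3)))
    T = minmax_scale(tau, what="tau (black)")
    I = _indeterminacy(tau, w)
    return NeutrosophicMaps(T=T, I=I, F=1.0 - T, mode="black",
                            channel_k=1, window_w=w, tau=tau)


def single_channel_maps(plane: np.ndarray, w: int = 15) -> NeutrosophicMaps:
    """T/I/F for one grayscale channel (DAPI nuclei, Pax7 blobs).

    tau is the channel itself; indeterminacy is the min-max scaled local
    contrast |C - local mean|, which normalizes away smooth intensity
    variation across the section.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("single_channel_maps expects a 2-D plane")
    T = minmax_scale(plane, what="tau (single channel)")
    I = _indeterminacy(plane, w)
    return NeutrosophicMaps(T=T, I=I, F=1.0 - T, mode="single",
                            channel_k=1, window_w=w)


def membership(maps: NeutrosophicMaps) -> MembershipMap:
    """Fuse T and I with an AND relation: M = T * (1 - I), in [0, 1]."""
    return MembershipMap(M=maps.T * (1.0 - maps.I), mode=maps.mode,
                         channel_k=maps.channel_k)
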