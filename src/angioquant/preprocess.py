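"""Stack standardization: median filtering, grayscale normalization and
Gaussian background removal.

The raw observation unit is a 4-channel confocal volume (cytosolic stain,
nuclear stain, reflected light, transmitted light).  Fluorescence channels
carry a low, roughly Gaussian background; the background model is fit
robustly to the dominant low-intensity histogram mode and voxels that are
statistically indistinguishable from background are eliminated.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage

#: canonical channel order used when stacks are serialized
CHANNEL_ORDER = ("cyto", "hoechst", "reflectance", "transmitted")

#: channels that carry fluorescence (and hence a Gaussian background pedestal)
FLUORESCENCE_CHANNELS = ("cyto", "hoechst")


@dataclasses.dataclass
class ImageStack:
    """A 4-channel volumetric image of one gel growth region.

    Channels are stored as ``(nz, ny, nx)`` arrays sharing one shape; the
    voxel size is ``(dz, dy, dx)`` in micrometres.  ``y`` runs across the
    gel (normal to the monolayer at rest), ``x`` along the channel axis and
    ``z`` along the optical axis.
    """

    channels: Dict[str, np.ndarray]
    voxel_size_um: Tuple[float, float, float]
    timepoint_label: str = "0hr"
    device_id: str = "D0"
    region_index: int = 0
    #: affine map applied by normalization, per channel: raw = norm * scale + offset.
    #: Metrics use the scale to report integrals on the acquisition intensity
    #: scale, keeping them comparable across stacks.
    norm_transform: Dict[str, Tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channels: at least one channel required")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels: inconsistent shapes {shapes}")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel_size_um: all voxel sizes must be > 0")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def with_channels(self, channels: Dict[str, np.ndarray]) -> "ImageStack":
        return dataclasses.replace(self, channels=channels)


@dataclasses.dataclass(frozen=True)
class BackgroundModel:
    """Gaussian background fit: mean, width and elimination threshold."""

    mu: float
    sigma: float
    threshold: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma: must be >= 0")
        if self.threshold < self.mu:
            raise ValueError("threshold: must be >= mu")


def median_filter_stack(stack: ImageStack, window: int = 3) -> ImageStack:
    """Apply a two-dimensional median filter slice by slice.

    The filter acts within each z-section (window ``window`` x ``window``
    pixels) and never mixes z-planes.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window: must be an odd integer >= 1, got {window}")
    if window == 1:
        return stack.with_channels({k: v.copy() for k, v in stack.channels.items()})
    out = {
        name: ndimage.median_filter(arr, size=(1, window, window), mode="nearest")
        for name, arr in stack.channels.items()
    }
    return stack.with_channels(out)


def normalize_grayscale(stack: ImageStack) -> ImageStack:
    """Linearly rescale every channel to [0, 1] by its own min/max.

    Channels have unrelated dynamic ranges, so normalization is per-channel.
    A constant channel maps to all zeros (with a warning).  The applied
    affine map is recorded in ``norm_transform`` so downstream metrics can
    report integrals on the original intensity scale.
    """
    out = {}
    transforms = dict(stack.norm_transform)
    for name, arr in stack.channels.items():
        lo = float(arr.min())
        hi = float(arr.max())
        if hi - lo <= 0:
            warnings.warn(f"channel {name!r} is constant; normalized to zeros")
            out[name] = np.zeros_like(arr)
            transforms[name] = (lo, 1.0)
        else:
            out[name] = (arr - lo) / (hi - lo)
            transforms[name] = (lo, hi - lo)
    return dataclasses.replace(stack, channels=out, norm_transform=transforms)


def estimate_background(
    channel: np.ndarray, k_sigma: float = 3.0
) -> BackgroundModel:
    """Fit a Gaussian to the dominant low-intensity mode of a channel.

    Robust location/scale estimation (median and scaled MAD with iterative
    clipping) ignores the bright foreground tail, so a small fraction of
    high-intensity voxels does not perturb the fit.  The elimination
    threshold is ``mu + k_sigma * sigma``.
    """
    v = np.asarray(channel, dtype=float).ravel()
    if v.size < 1000:
        raise ValueError(f"need >= 1000 voxels to fit background, got {v.size}")
    med = np.median(v)
    sigma = 1.4826 * np.median(np.abs(v - med))
    keep = v
    if sigma > 0:
        for _ in range(3):
            keep = v[np.abs(v - med) <= 4.0 * sigma]
            if keep.size < 0.2 * v.size:
                raise ValueError(
                    "no clear background mode found; supply a manual threshold"
                )
            med = np.median(keep)
            new_sigma = 1.4826 * np.median(np.abs(keep - med))
            if new_sigma <= 0:
                break
            sigma = new_sigma
    mu = float(med)
    sigma = float(sigma)
    return BackgroundModel(mu=mu, sigma=sigma, threshold=mu + k_sigma * sigma)


def subtract_background(
    stack: ImageStack,
    models: Mapping[str, BackgroundModel],
    channels: Optional[Iterable[str]] = None,
) -> ImageStack:
    """Eliminate background from the given channels.

    Voxels at or below the model threshold are set to zero; voxels above it
    have the fitted background mean removed.  Removing the pedestal (rather
    than keeping supra-threshold values untouched) keeps the integral growth
    metrics unbiased by the background level under bright structures.
    """
    names = tuple(channels) if channels is not None else tuple(models)
    out = {}
    for name, arr in stack.channels.items():
        if name in names:
            model = models[name]
            res = np.where(arr > model.threshold, arr - model.mu, 0.0)
            out[name] = np.clip(res, 0.0, None)
        else:
            out[name] = arr.copy()
    return stack.with_channels(out)


def preprocess_stack(
    stack: ImageStack,
    median_window: int = 3,
    background_k_sigma: float = 3.0,
) -> Tuple[ImageStack, Dict[str, BackgroundModel]]:
    """Standard preprocessing chain: median filter, normalize, remove background.

    Background elimination is applied to the fluorescence channels only;
    reflectance keeps its bimodal gel/PDMS histogram for boundary detection.
    """
    st = median_filter_stack(stack, median_window)
    st = normalize_grayscale(st)
    models = {
        name: estimate_background(st.channels[name], background_k_sigma)
        for name in FLUORESCENCE_CHANNELS
        if name in st.channels
    }
    st = subtract_background(st, models)
    return st, models
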