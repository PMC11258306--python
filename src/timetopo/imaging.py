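"""Image-domain front-end: preprocessing, cell detection, rendering, OME-TIFF I/O.

Real DSP exports are 3-channel 20x immunofluorescence ROI scans (nuclei /
PanCk / CD45).  This module reproduces the preprocessing step (rolling-ball
background subtraction) and provides a deliberately simple maxima-based
detector/classifier that turns such an image into a classified CellTable.
It is a documented stand-in for external deep-learning segmentation: the
downstream pipeline only requires cell centroids and classes, and users
with their own segmentation can import those tables directly.

:func:`render_cell_image` is the inverse operation — it paints a synthetic
3-channel image from a known CellTable, which makes detection testable
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.restoration import rolling_ball

from .graphstats import TUMOR, IMMUNE, OTHER

CHANNEL_NAMES = ("nuclei", "panck", "cd45")


@dataclass
class ROIImage:
    """Named 2-D intensity channels for one ROI, plus the pixel scale."""

    channels: dict
    pixel_size_um: float = 0.4

    def __post_init__(self):
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share the same dimensions")
        for name, arr in self.channels.items():
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"channel {name!r} has negative intensities")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ValueError(f"missing channel: {name!r}")
        return np.asarray(self.channels[name], dtype=float)

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


def rolling_ball_subtract(image: np.ndarray, radius_px: float = 100) -> np.ndarray:
    """Subtract a rolling-ball background estimate, clipping at zero.

    The classic flat-field correction: a ball of the given radius rolled
    under the intensity surface defines the background.  A flat image is
    removed entirely; structures much smaller than the ball survive.
    """
    image = np.asarray(image, dtype=float)
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if image.ndim != 2:
        raise ValueError("expected a 2-D intensity array")
    if radius_px > max(image.shape):
        raise ValueError(
            f"rolling-ball radius {radius_px} exceeds both image dimensions "
            f"{image.shape}"
        )
    background = rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0, None)


@dataclass
class DetectionParams:
    """Maxima-based nucleus detection and fixed-disc class assignment."""

    min_distance_px: int = 5          # two nuclei closer than this merge
    smooth_sigma_px: float = 1.5
    nuclei_threshold: float = 20.0    # absolute peak threshold after smoothing
    sample_radius_px: int = 3         # disc radius for channel evidence
    panck_threshold: float = 15.0
    cd45_threshold: float = 15.0
    subtract_background: bool = False
    rolling_radius_px: float = 100.0


def _disc_mean(channel: np.ndarray, yx: np.ndarray, radius: int) -> np.ndarray:
    """Mean intensity inside a fixed-radius disc around each centroid."""
    size = 2 * radius + 1
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disc = (yy**2 + xx**2) <= radius**2
    kernel = disc / disc.sum()
    smoothed = ndimage.convolve(channel, kernel, mode="nearest")
    return smoothed[yx[:, 0], yx[:, 1]]


def detect_cells(
    image: ROIImage,
    params: DetectionParams | None = None,
    roi_id: str = "ROI001",
) -> pd.DataFrame:
    """Detect and classify cells from a 3-channel ROI image.

    Centroids are local maxima of the (optionally background-subtracted,
    Gaussian-smoothed) nuclei channel.  Each cell is classified from the
    mean PanCk and CD45 in a fixed-radius disc around its centroid: tumor
    if PanCk clears its threshold and exceeds the CD45 evidence, immune if
    CD45 analogously dominates, otherwise "other" (ties are conservatively
    "other").  Nuclei closer than ``min_distance_px`` merge into one
    detection.
    """
    params = params or DetectionParams()
    for required in CHANNEL_NAMES:
        image.channel(required)  # raises on a missing channel
    nuclei = image.channel("nuclei")
    if params.subtract_background:
        nuclei = rolling_ball_subtract(nuclei, params.rolling_radius_px)
    smoothed = ndimage.gaussian_filter(nuclei, params.smooth_sigma_px)
    peaks = peak_local_max(
        smoothed,
        min_distance=params.min_distance_px,
        threshold_abs=params.nuclei_threshold,
        exclude_border=False,
    )
    cols = ["roi_id", "cell_id", "x_px", "y_px", "cls"]
    if len(peaks) == 0:
        return pd.DataFrame(columns=cols)
    panck = _disc_mean(image.channel("panck"), peaks, params.sample_radius_px)
    cd45 = _disc_mean(image.channel("cd45"), peaks, params.sample_radius_px)
    cls = np.full(len(peaks), OTHER, dtype=object)
    tumor = (panck >= params.panck_threshold) & (panck > cd45)
    immune = (cd45 >= params.cd45_threshold) & (cd45 > panck)
    cls[tumor] = TUMOR
    cls[immune] = IMMUNE
    return pd.DataFrame(
        {
            "roi_id": roi_id,
            "cell_id": [f"c{k:05d}" for k in range(len(peaks))],
            "x_px": peaks[:, 1].astype(float),
            "y_px": peaks[:, 0].astype(float),
            "cls": cls,
        }
    )


@dataclass
class RenderParams:
    """Synthetic immunofluorescence rendering of a CellTable."""

    nuclei_amplitude: float = 100.0
    nuclei_sigma_px: float = 2.0
    marker_amplitude: float = 80.0
    marker_sigma_px: float = 3.0
    noise_sd: float = 2.0
    background: float = 5.0
    seed: int = 0


def _stamp(canvas: np.ndarray, yx: np.ndarray, amplitude: float, sigma: float):
    radius = int(np.ceil(4 * sigma))
    size = 2 * radius + 1
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    kernel = amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    h, w = canvas.shape
    for y, x in yx:
        y0, x0 = int(round(y)) - radius, int(round(x)) - radius
        ys, xs = slice(max(y0, 0), min(y0 + size, h)), slice(max(x0, 0), min(x0 + size, w))
        kys = slice(ys.start - y0, ys.stop - y0)
        kxs = slice(xs.start - x0, xs.stop - x0)
        canvas[ys, xs] += kernel[kys, kxs]


def render_cell_image(
    cells: pd.DataFrame,
    shape: tuple[int, int] = (256, 256),
    params: RenderParams | None = None,
    pixel_size_um: float = 0.4,
) -> ROIImage:
    """Paint a synthetic 3-channel image from a classified CellTable.

    Every cell gets a Gaussian nucleus spot; tumor cells additionally light
    up the PanCk channel and immune cells the CD45 channel.  Gaussian read
    noise and a flat background are added, clipped at zero.
    """
    params = params or RenderParams()
    rng = np.random.default_rng(params.seed)
    chans = {name: np.zeros(shape, dtype=float) for name in CHANNEL_NAMES}
    yx = cells[["y_px", "x_px"]].to_numpy(dtype=float)
    _stamp(chans["nuclei"], yx, params.nuclei_amplitude, params.nuclei_sigma_px)
    for cls_name, channel in ((TUMOR, "panck"), (IMMUNE, "cd45")):
        sub = cells[cells["cls"] == cls_name][["y_px", "x_px"]].to_numpy(dtype=float)
        _stamp(chans[channel], sub, params.marker_amplitude, params.marker_sigma_px)
    for name in CHANNEL_NAMES:
        noisy = (
            chans[name]
            + params.background
            + rng.normal(scale=params.noise_sd, size=shape)
        )
        chans[name] = np.clip(noisy, 0, None)
    return ROIImage(channels=chans, pixel_size_um=pixel_size_um)


def read_roi_image(
    path,
    channel_map: dict | None = None,
    pixel_size_um: float = 0.4,
) -> ROIImage:
    """Read a multi-channel (C, Y, X) OME-TIFF into an ROIImage.

    ``channel_map`` maps channel names to plane indices; the default assumes
    the nuclei / PanCk / CD45 plane order of DSP exports.
    """
    channel_map = channel_map or {"nuclei": 0, "panck": 1, "cd45": 2}
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {
        name: np.asarray(stack[idx], dtype=float)
        for name, idx in channel_map.items()
    }
    return ROIImage(channels=channels, pixel_size_um=pixel_size_um)


def write_roi_image(path, image: ROIImage,
                    order: tuple[str, ...] = CHANNEL_NAMES) -> None:
    """Write an ROIImage as a (C, Y, X) OME-TIFF."""
    stack = np.stack([image.channel(name) for name in order]).astype(np.float32)
    tifffile.imwrite(
        path, stack, ome=True,
        metadata={"axes": "CYX", "Channel": {"Name": list(order)}},
    )
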