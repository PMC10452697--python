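"""Chamber recovery from fluorescence images: grid registration,
intensity extraction and positive/negative classification.

The chamber grid is always known from the chip layout, so registration is
geometry-driven: a synthetic template of disks at the nominal positions is
cross-correlated with the image to find the global translation, which
yields exactly ``total_chambers`` centres in row-major order.  Free blob
detection is deliberately avoided — it could miss or merge chambers and
break the count ``n`` the Poisson estimate divides by.

Thresholding defaults to exact two-class 1-D k-means (midpoint of the two
cluster centroids); Otsu is available by configuration.  Intermediate
"rain" intensities are handled solely by the threshold, with no exclusion
band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .chip_model import (
    ChipLayout,
    PanelConfig,
    grid_centres_px,
    grid_image_shape,
    total_chambers,
)

__all__ = [
    "GridDetection",
    "ChannelClassification",
    "ChamberCallTable",
    "detect_grid",
    "extract_intensities",
    "classify_chambers",
    "analyze_chip",
    "read_image",
    "write_qc_overlay",
]


class GridRegistrationError(RuntimeError):
    """Raised when the chamber grid cannot be registered to the image."""


@dataclass
class GridDetection:
    """Registered chamber centres plus diagnostics."""

    centres: np.ndarray      # (n, 2) float, (x, y) pixels, row-major
    shift: tuple             # (dx, dy) applied to the nominal grid
    score: float             # normalised correlation at the chosen shift

    def __len__(self) -> int:
        return len(self.centres)


def _grid_template(layout: ChipLayout, pixel_scale: float) -> np.ndarray:
    shape = grid_image_shape(layout, pixel_scale)
    centres = grid_centres_px(layout, pixel_scale)
    tpl = np.zeros(shape, dtype=np.float32)
    radius = max(layout.chamber_diameter / 2.0 / pixel_scale, 1.0)
    from skimage.draw import disk as _draw_disk
    rr0, cc0 = _draw_disk((0, 0), radius)
    cy = np.round(centres[:, 1]).astype(int)
    cx = np.round(centres[:, 0]).astype(int)
    tpl[(cy[:, None] + rr0[None, :]).ravel(),
        (cx[:, None] + cc0[None, :]).ravel()] = 1.0
    return tpl


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def detect_grid(image: np.ndarray, layout: ChipLayout, pixel_scale: float,
                size_tolerance: float = 0.25,
                min_score: float = 0.05) -> GridDetection:
    """Register the chamber grid to an image and return all centres.

    The nominal grid (from the layout) is shifted by the translation found
    by phase cross-correlation against a synthetic disk template; the
    result always contains exactly ``total_chambers(layout)`` centres in
    row-major order.  Robust to global translations up to about half a
    pitch.

    Raises
    ------
    ValueError
        If the image dimensions are inconsistent with
        ``layout x pixel_scale`` beyond ``size_tolerance``.
    GridRegistrationError
        If the correlation score at the chosen shift falls below
        ``min_score`` (diagnostic score included in the message).
    """
    expected = grid_image_shape(layout, pixel_scale)
    for dim, exp in zip(image.shape, expected):
        if abs(dim - exp) > size_tolerance * exp:
            raise ValueError(
                f"image shape {image.shape} inconsistent with layout-expected "
                f"{expected} (tolerance {size_tolerance:.0%})"
            )
    tpl = _grid_template(layout, pixel_scale)
    img = image.astype(np.float32)
    # pad/crop image to the template's shape for correlation
    work = np.zeros_like(tpl)
    h = min(tpl.shape[0], img.shape[0])
    w = min(tpl.shape[1], img.shape[1])
    work[:h, :w] = img[:h, :w]
    shift_yx, _, _ = phase_cross_correlation(work, tpl,
                                             upsample_factor=10,
                                             normalization=None)
    dy, dx = float(shift_yx[0]), float(shift_yx[1])
    centres = grid_centres_px(layout, pixel_scale) + np.array([dx, dy])
    # diagnostic: correlate template shifted by the integer part of the shift
    tpl_shift = np.roll(tpl, (int(round(dy)), int(round(dx))), axis=(0, 1))
    score = _ncc(work, tpl_shift)
    if score < min_score:
        raise GridRegistrationError(
            f"grid registration failed: correlation score {score:.3f} "
            f"< {min_score} at shift ({dx:.1f}, {dy:.1f}) px"
        )
    return GridDetection(centres=centres, shift=(dx, dy), score=score)


def extract_intensities(image: np.ndarray, centres: np.ndarray,
                        layout: ChipLayout, pixel_scale: float,
                        shrink: float = 0.8) -> np.ndarray:
    """Mean intensity inside a disk at each chamber centre.

    The disk radius is ``diameter/2 / pixel_scale * shrink``; the default
    shrink of 0.8 keeps the mask inside the chamber and away from edge
    pixels.  Raises if any disk exceeds the image bounds.
    """
    if not 0 < shrink <= 1:
        raise ValueError("shrink must be in (0, 1]")
    radius = max(layout.chamber_diameter / 2.0 / pixel_scale * shrink, 1.0)
    from skimage.draw import disk as _draw_disk
    rr0, cc0 = _draw_disk((0, 0), radius)
    cy = np.round(centres[:, 1]).astype(int)
    cx = np.round(centres[:, 0]).astype(int)
    rows = cy[:, None] + rr0[None, :]
    cols = cx[:, None] + cc0[None, :]
    if rows.min() < 0 or cols.min() < 0 or \
            rows.max() >= image.shape[0] or cols.max() >= image.shape[1]:
        raise ValueError("chamber disk exceeds image bounds")
    return image[rows, cols].mean(axis=1, dtype=np.float64)


@dataclass
class ChannelClassification:
    """Boolean calls for one channel plus the threshold that produced them."""

    calls: np.ndarray
    threshold: float
    no_positive_population: bool = False
    centroids: tuple = (np.nan, np.nan)


def _two_means_1d(x: np.ndarray):
    """Exact 1-D two-class k-means via the optimal sorted split point.

    Returns (lower centroid, upper centroid, pooled within-class SD).
    Deterministic and equivariant under increasing affine maps of x.
    """
    xs = np.sort(x.astype(np.float64))
    n = xs.size
    cs = np.cumsum(xs)
    css = np.cumsum(xs * xs)
    k = np.arange(1, n)                      # left-cluster sizes
    left_sum = cs[k - 1]
    right_sum = cs[-1] - left_sum
    sse = (css[k - 1] - left_sum**2 / k) + \
          (css[-1] - css[k - 1] - right_sum**2 / (n - k))
    best = int(np.argmin(sse))
    kb = best + 1
    c0 = left_sum[best] / kb
    c1 = right_sum[best] / (n - kb)
    pooled_sd = float(np.sqrt(max(sse[best], 0.0) / n))
    return c0, c1, pooled_sd


def classify_chambers(intensities: np.ndarray, method: str = "kmeans",
                      separation_factor: float = 4.0) -> ChannelClassification:
    """Split chamber intensities into negative and positive populations.

    ``kmeans`` (default): exact two-class 1-D clustering; the threshold is
    the midpoint of the two centroids.  If the centroids are closer than
    ``separation_factor`` times the pooled within-class spread, no positive
    population exists and every chamber is called negative.  ``otsu`` uses
    Otsu's histogram threshold instead (same separation guard).

    A call is ``intensity >= threshold``.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("no intensities to classify")
    if x.size < 2 or np.allclose(x, x[0]):
        return ChannelClassification(
            calls=np.zeros(x.size, dtype=bool), threshold=np.inf,
            no_positive_population=True,
        )
    c0, c1, pooled_sd = _two_means_1d(x)
    if (c1 - c0) <= separation_factor * pooled_sd:
        return ChannelClassification(
            calls=np.zeros(x.size, dtype=bool), threshold=np.inf,
            no_positive_population=True, centroids=(c0, c1),
        )
    if method == "kmeans":
        threshold = (c0 + c1) / 2.0
    elif method == "otsu":
        threshold = float(threshold_otsu(x))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return ChannelClassification(
        calls=x >= threshold, threshold=float(threshold),
        centroids=(c0, c1),
    )


@dataclass
class ChamberCallTable:
    """Per-chamber, per-channel intensities and calls for one chip.

    ``frame`` has one row per layout chamber (chamber_id, row, col, x_px,
    y_px, filled, intensity_<ch>, call_<ch>); ``thresholds`` and ``flags``
    record, per channel, the threshold used and whether a positive
    population was found.  Calls are defined only for filled chambers.
    """

    frame: pd.DataFrame
    thresholds: dict
    flags: dict = field(default_factory=dict)
    channels: tuple = ()

    def positives(self, channel: str) -> int:
        f = self.frame
        return int((f[f"call_{channel}"] & f["filled"]).sum())

    def counted(self, count_unfilled: bool = False) -> int:
        """Chambers counted as ``n``: filled only, unless told otherwise."""
        return len(self.frame) if count_unfilled else int(self.frame["filled"].sum())

    # ---- persistence: CSV table + JSON sidecar for thresholds ----
    def write(self, csv_path) -> None:
        csv_path = Path(csv_path)
        self.frame.to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".thresholds.json")
        sidecar.write_text(json.dumps({
            "channels": list(self.channels),
            "thresholds": {k: (None if np.isinf(v) else v)
                           for k, v in self.thresholds.items()},
            "flags": self.flags,
        }, indent=2))

    @classmethod
    def read(cls, csv_path) -> "ChamberCallTable":
        csv_path = Path(csv_path)
        frame = pd.read_csv(csv_path)
        channels = tuple(c[len("call_"):] for c in frame.columns
                         if c.startswith("call_"))
        thresholds, flags = {}, {}
        sidecar = csv_path.with_suffix(".thresholds.json")
        if sidecar.exists():
            doc = json.loads(sidecar.read_text())
            thresholds = {k: (np.inf if v is None else v)
                          for k, v in doc.get("thresholds", {}).items()}
            flags = doc.get("flags", {})
            channels = tuple(doc.get("channels", channels))
        return cls(frame=frame, thresholds=thresholds, flags=flags,
                   channels=channels)


def analyze_chip(images: dict, layout: ChipLayout, pixel_scale: float,
                 reference_channel: str | None = None,
                 method: str = "kmeans", shrink: float = 0.8,
                 separation_factor: float = 4.0,
                 fill_threshold: float | None = None) -> ChamberCallTable:
    """Full image-to-calls pipeline for one chip.

    The grid is registered on the reference channel (or the first channel)
    and the same centres are reused for every channel.  ``fill_threshold``,
    if given, marks a chamber unfilled when its intensity in *every*
    channel falls below it (filled chambers always carry at least the
    negative-population fluorescence; an unfilled chamber reads image
    background).  By default all chambers are assumed filled.
    """
    if not images:
        raise ValueError("no images supplied")
    channels = list(images)
    anchor = reference_channel if reference_channel in images else channels[0]
    grid = detect_grid(images[anchor], layout, pixel_scale)

    n = total_chambers(layout)
    rows = np.repeat(np.arange(layout.n_rows), layout.chambers_per_row)
    cols = np.tile(np.arange(layout.chambers_per_row), layout.n_rows)
    data = {
        "chamber_id": np.arange(n),
        "row": rows,
        "col": cols,
        "x_px": grid.centres[:, 0],
        "y_px": grid.centres[:, 1],
    }
    intens = {}
    for ch in channels:
        intens[ch] = extract_intensities(images[ch], grid.centres, layout,
                                         pixel_scale, shrink=shrink)
    if fill_threshold is not None:
        stacked = np.column_stack([intens[ch] for ch in channels])
        filled = (stacked >= fill_threshold).any(axis=1)
    else:
        filled = np.ones(n, dtype=bool)
    data["filled"] = filled

    thresholds, flags = {}, {}
    for ch in channels:
        cls_ = classify_chambers(intens[ch][filled], method=method,
                                 separation_factor=separation_factor)
        calls = np.zeros(n, dtype=bool)
        calls[filled] = cls_.calls
        data[f"intensity_{ch}"] = intens[ch]
        data[f"call_{ch}"] = calls
        thresholds[ch] = cls_.threshold
        flags[ch] = {"no_positive_population": cls_.no_positive_population,
                     "grid_score": grid.score}
    return ChamberCallTable(frame=pd.DataFrame(data), thresholds=thresholds,
                            flags=flags, channels=tuple(channels))


def read_image(path) -> np.ndarray:
    """Read a 16-bit TIFF (or PNG) as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    return img


def write_qc_overlay(image: np.ndarray, table: ChamberCallTable,
                     channel: str, layout: ChipLayout, pixel_scale: float,
                     out_path) -> None:
    """Write a QC PNG with called-positive chambers circled in red."""
    from skimage.draw import circle_perimeter
    lo, hi = np.percentile(image, (1, 99.9))
    scaled = np.clip((image.astype(float) - lo) / max(hi - lo, 1), 0, 1)
    rgb = np.stack([scaled] * 3, axis=-1)
    radius = int(round(layout.chamber_diameter / 2.0 / pixel_scale)) + 2
    f = table.frame
    pos = f[f[f"call_{channel}"] & f["filled"]]
    for _, row in pos.iterrows():
        rr, cc = circle_perimeter(int(round(row["y_px"])),
                                  int(round(row["x_px"])), radius,
                                  shape=image.shape)
        rgb[rr, cc] = (1.0, 0.1, 0.1)
    iio.imwrite(Path(out_path), (rgb * 255).astype(np.uint8))
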