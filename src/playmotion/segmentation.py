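"""Difference-image segmentation and morphological blob cleanup.

Consecutive infrared frames are differenced and thresholded (foreground where
the absolute difference exceeds the pixel threshold); frames with more than
T = 14,000 foreground pixels are flagged unevaluable (too noisy to segment).
The binary difference image is then refined by a fixed chain:

    Sobel edge enhancement -> 3x3 majority fill (sum > 5) ->
    morphological closing (disk r=9) -> reconstruction (marker = closed
    image constrained to the difference mask) -> 25x25-square dilation
    (merges an object's fragments into one component) -> 8-connected hole
    fill -> one thinning pass

after which 8-connected components smaller than 375 pixels are discarded and
the survivors are summarized as blobs (label, size, centroid, bounding box).

The morphology is evaluated on the bounding box of the difference-mask
foreground plus a margin that covers every structuring element, which is
exactly equivalent to whole-frame evaluation with zero padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .config import RunConfig

_EIGHT = np.ones((3, 3), dtype=bool)
#: margin covering closing disk (9) + merging dilation (12) + thinning (1)
_ROI_MARGIN = 40


@dataclass
class DifferenceMask:
    """Thresholded absolute difference between two infrared frames."""

    mask: np.ndarray          # (H, W) bool
    foreground_count: int
    evaluable: bool


@dataclass
class Blob:
    """One connected foreground component."""

    label: int
    pixel_count: int
    centroid: tuple[float, float]          # (x_px, y_px)
    bbox: tuple[int, int, int, int]        # (x_min, y_min, width, height)


def difference_mask(
    frame_i,
    frame_j,
    pixel_threshold: int = 1400,
    frame_threshold: int = 14000,
) -> DifferenceMask:
    """Foreground where |frame_i - frame_j| exceeds ``pixel_threshold``.

    The difference is taken on signed integers (no uint16 wraparound).  The
    mask is unevaluable when its foreground count exceeds
    ``frame_threshold`` (T): such frames are too noisy to segment.
    """
    fi = np.asarray(frame_i)
    fj = np.asarray(frame_j)
    if fi.shape != fj.shape:
        raise ValueError(f"frame shapes differ: {fi.shape} vs {fj.shape}")
    if pixel_threshold <= 0:
        raise ValueError("pixel_threshold must be positive")
    d = np.abs(fi.astype(np.int64) - fj.astype(np.int64)) > pixel_threshold
    count = int(d.sum())
    return DifferenceMask(mask=d, foreground_count=count, evaluable=count <= frame_threshold)


def edge_enhance(mask) -> np.ndarray:
    """Binarized 3x3 Sobel gradient magnitude (horizontal + vertical)."""
    img = mask.mask if isinstance(mask, DifferenceMask) else np.asarray(mask)
    img = img.astype(float)
    grad = np.hypot(filters.sobel_h(img), filters.sobel_v(img))
    return grad > 0


def majority_fill(img) -> np.ndarray:
    """Output 1 where the zero-padded 3x3 neighborhood sum exceeds 5."""
    img = np.asarray(img).astype(np.uint8)
    sums = ndi.convolve(img, np.ones((3, 3), dtype=np.uint8), mode="constant", cval=0)
    return sums > 5


def _consolidate_core(img, diff_mask, disk_radius, square_width, thin_iterations):
    closed = morphology.closing(img, morphology.disk(disk_radius))
    # reconstruction-by-dilation needs marker <= mask; the closed image can
    # exceed the difference mask, so constrain it first
    marker = closed & diff_mask
    if not marker.any():
        return np.zeros_like(img)
    recon = morphology.reconstruction(marker, diff_mask, method="dilation").astype(bool)
    merged = morphology.dilation(
        recon, morphology.footprint_rectangle((square_width, square_width))
    )
    filled = ndi.binary_fill_holes(merged, structure=_EIGHT)
    if thin_iterations <= 0:
        return filled
    return morphology.thin(filled, max_num_iter=thin_iterations)


def consolidate(
    img,
    diff: DifferenceMask,
    disk_radius: int = 9,
    square_width: int = 25,
    thin_iterations: int = 1,
) -> np.ndarray:
    """Morphological cleanup chain: closing, constrained reconstruction,
    merging dilation, hole fill, thinning.  Empty input yields empty output.
    """
    img = np.asarray(img).astype(bool)
    dmask = diff.mask if isinstance(diff, DifferenceMask) else np.asarray(diff).astype(bool)
    if img.shape != dmask.shape:
        raise ValueError("image and difference mask shapes differ")
    support = img | dmask
    if not support.any():
        return np.zeros_like(img)
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    r0 = max(rows[0] - _ROI_MARGIN, 0)
    r1 = min(rows[-1] + _ROI_MARGIN + 1, img.shape[0])
    c0 = max(cols[0] - _ROI_MARGIN, 0)
    c1 = min(cols[-1] + _ROI_MARGIN + 1, img.shape[1])
    out = np.zeros_like(img)
    out[r0:r1, c0:c1] = _consolidate_core(
        img[r0:r1, c0:c1], dmask[r0:r1, c0:c1],
        disk_radius, square_width, thin_iterations,
    )
    return out


def extract_blobs(img, min_component_size: int = 375) -> list[Blob]:
    """8-connected components of ``img`` at least ``min_component_size`` px.

    Labels follow raster-scan order of first appearance; centroids are
    arithmetic means of member pixel coordinates; bounding boxes are tight.
    """
    img = np.asarray(img).astype(bool)
    labels = measure.label(img, connectivity=2)
    blobs = []
    for region in measure.regionprops(labels):
        if region.num_pixels < min_component_size:
            continue
        cy, cx = region.centroid
        rmin, cmin, rmax, cmax = region.bbox
        blobs.append(
            Blob(
                label=region.label,
                pixel_count=int(region.num_pixels),
                centroid=(float(cx), float(cy)),
                bbox=(int(cmin), int(rmin), int(cmax - cmin), int(rmax - rmin)),
            )
        )
    return blobs


@dataclass
class FrameBlobs:
    """Segmentation output for one frame (differenced against its predecessor)."""

    timestamp_ms: int
    evaluable: bool
    blobs: list[Blob]


def segment_pair(frame_i, frame_j, config: RunConfig = RunConfig()):
    """Full chain for one consecutive frame pair -> (DifferenceMask, blobs)."""
    diff = difference_mask(
        frame_i.infrared if hasattr(frame_i, "infrared") else frame_i,
        frame_j.infrared if hasattr(frame_j, "infrared") else frame_j,
        pixel_threshold=config.pixel_threshold,
        frame_threshold=config.frame_threshold,
    )
    if not diff.evaluable or not diff.mask.any():
        return diff, []
    # evaluate the (local) chain on the foreground bounding box + margin;
    # identical to whole-frame evaluation with zero padding
    rows = np.flatnonzero(diff.mask.any(axis=1))
    cols = np.flatnonzero(diff.mask.any(axis=0))
    r0 = max(rows[0] - _ROI_MARGIN, 0)
    r1 = min(rows[-1] + _ROI_MARGIN + 1, diff.mask.shape[0])
    c0 = max(cols[0] - _ROI_MARGIN, 0)
    c1 = min(cols[-1] + _ROI_MARGIN + 1, diff.mask.shape[1])
    dmask = diff.mask[r0:r1, c0:c1]
    edges = edge_enhance(dmask)
    filled = majority_fill(edges)
    cleaned = np.zeros_like(diff.mask)
    cleaned[r0:r1, c0:c1] = _consolidate_core(
        filled, dmask,
        config.disk_radius, config.square_width, config.thin_iterations,
    )
    return diff, extract_blobs(cleaned, min_component_size=config.min_component)


def segment_sequence(frames, config: RunConfig = RunConfig()) -> list[FrameBlobs]:
    """Segment every consecutive infrared pair of a frame sequence.

    Output i corresponds to frames[i+1] differenced against frames[i];
    unevaluable frames carry no blobs.
    """
    out = []
    for prev, cur in zip(frames, frames[1:]):
        diff, blobs = segment_pair(prev, cur, config)
        out.append(
            FrameBlobs(timestamp_ms=int(cur.timestamp_ms), evaluable=diff.evaluable, blobs=blobs)
        )
    return out


def save_debug_stages(frame_i, frame_j, out_dir, config: RunConfig = RunConfig()) -> None:
    """Dump each stage of the chain as 8-bit PNGs for visual inspection."""
    from pathlib import Path  # noqa: PLC0415

    import imageio.v3 as iio  # noqa: PLC0415

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diff = difference_mask(
        frame_i.infrared, frame_j.infrared,
        pixel_threshold=config.pixel_threshold,
        frame_threshold=config.frame_threshold,
    )
    edges = edge_enhance(diff)
    filled = majority_fill(edges)
    cleaned = consolidate(filled, diff, config.disk_radius, config.square_width, config.thin_iterations)
    for name, img in [
        ("a_difference", diff.mask),
        ("b_sobel", edges),
        ("c_majority", filled),
        ("d_consolidated", cleaned),
    ]:
        iio.imwrite(out / f"{name}.png", (img.astype(np.uint8) * 255))
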