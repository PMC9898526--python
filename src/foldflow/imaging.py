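"""Bespoke image operators: apical-surface topography, offset projection,
basal fiber segmentation/orientation, and curvature-binned intensity.

These reproduce the measurement chain used on fluorescence stacks of a curved
epithelium: the apical surface is found per pixel as the most apical peak of
the along-z variance profile; any channel can then be projected at a signed
slice offset from that surface.  Basal actin fibers are segmented by
background subtraction, thresholding and skeletonisation, with skeleton
branch points removed so that each fiber contributes a simple linear path;
orientation is taken from the path endpoints and folded into [0°, 90°]
relative to the ML axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure, morphology, restoration, transform

from .exceptions import ConfigurationError, DataError
from .simulate import fold_angle

#: Curvature bin width (µm⁻¹) for intensity-vs-curvature profiles.
CURVATURE_BIN_WIDTH = 0.001

#: Minimum fiber length (µm) retained by the segmentation.
MIN_FIBER_LENGTH_UM = 0.8


@dataclass
class HeightMap:
    """Topographic map of the apical surface: per-pixel z index."""

    z: np.ndarray
    pixel_size: float = 1.0
    z_spacing: float = 1.0


# ---------------------------------------------------------------------------
# apical surface detection and projection
# ---------------------------------------------------------------------------

def apical_zmap(stack: np.ndarray, downscale: int = 10,
                background_radius_px: float | None = None,
                texture_radius_px: int | None = None,
                peak_prominence_frac: float = 0.2,
                pixel_size: float = 1.0, z_spacing: float = 1.0) -> HeightMap:
    """Detect the apical surface of a (z, y, x) stack.

    Processing chain: optional rolling-ball background subtraction per slice;
    optional *lateral* variance filter per slice (``texture_radius_px``),
    which converts membrane texture into a bright band at the surface —
    useful on junctional markers, unnecessary on already-bright surfaces;
    lateral downscaling; then, per pixel, the surface is the most apical
    (smallest z) peak of the z-intensity profile whose prominence exceeds
    ``peak_prominence_frac`` times the profile range — not necessarily the
    global maximum, so a second deeper (basal) band never wins.  The map is
    finally upscaled back to the original lateral shape by linear
    interpolation.

    A stack whose z-profiles are constant everywhere carries no surface
    information and raises :class:`DataError`.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ConfigurationError("stack must be 3-D (z, y, x) with >= 3 slices")
    if background_radius_px:
        stack = np.stack([sl - restoration.rolling_ball(sl, radius=background_radius_px)
                          for sl in stack])
    if texture_radius_px:
        w = 2 * int(texture_radius_px) + 1
        mean = np.stack([ndimage.uniform_filter(sl, w) for sl in stack])
        meansq = np.stack([ndimage.uniform_filter(sl**2, w) for sl in stack])
        stack = np.clip(meansq - mean**2, 0.0, None)
    if downscale > 1:
        small = np.stack([measure.block_reduce(sl, (downscale, downscale), np.mean)
                          for sl in stack])
    else:
        small = stack
    nz, ny, nx = small.shape
    ranges = small.max(axis=0) - small.min(axis=0)
    if not np.any(ranges > 0):
        raise DataError("flat stack: constant z-profiles everywhere, no surface detected")
    zmap = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            prof = small[:, i, j]
            rng = ranges[i, j]
            if rng <= 0:
                zmap[i, j] = 0.0
                continue
            peaks, _ = find_peaks(prof, prominence=peak_prominence_frac * rng)
            if peaks.size:
                zmap[i, j] = float(peaks[0])  # most apical accepted peak
            else:
                zmap[i, j] = float(np.argmax(prof))
    if downscale > 1:
        zmap = transform.resize(zmap, stack.shape[1:], order=1, mode="edge",
                                anti_aliasing=False)
    return HeightMap(z=zmap, pixel_size=pixel_size, z_spacing=z_spacing)


def project_offset(stack: np.ndarray, zmap: HeightMap, offset_slices: int = 0,
                   reducer: str = "max", window_slices: int = 1) -> np.ndarray:
    """Project a stack at a signed slice offset from the detected surface.

    Per pixel the ``reducer`` (max or mean) is applied over a
    ``window_slices``-thick window centered at ``zmap + offset_slices``;
    offsets beyond the stack are clamped to the first/last slice with a
    warning.
    """
    stack = np.asarray(stack, float)
    nz = stack.shape[0]
    if reducer not in ("max", "mean"):
        raise ConfigurationError("reducer must be 'max' or 'mean'")
    target = np.rint(zmap.z).astype(int) + int(offset_slices)
    if target.min() < 0 or target.max() > nz - 1:
        import warnings

        warnings.warn("projection offset reaches beyond the stack; clamped")
    target = np.clip(target, 0, nz - 1)
    half = (window_slices - 1) // 2
    lo = np.clip(target - half, 0, nz - 1)
    hi = np.clip(target + half, 0, nz - 1)
    ny, nx = target.shape
    out = np.empty((ny, nx))
    zs = np.arange(nz)[:, None, None]
    mask = (zs >= lo[None]) & (zs <= hi[None])
    if reducer == "max":
        out = np.where(mask, stack, -np.inf).max(axis=0)
    else:
        out = np.where(mask, stack, 0.0).sum(axis=0) / mask.sum(axis=0)
    return out


# ---------------------------------------------------------------------------
# fiber segmentation and orientation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSegment:
    """A segmented linear fiber portion."""

    endpoint1: tuple[float, float]
    endpoint2: tuple[float, float]
    length: float
    orientation: float  # degrees in [0, 90] relative to the ML (x) axis

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.endpoint1[0] + self.endpoint2[0]) / 2,
                (self.endpoint1[1] + self.endpoint2[1]) / 2)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def segment_fibers(image: np.ndarray, binarize_threshold: float,
                   background_radius_px: float | None = 3.0,
                   min_length_um: float = MIN_FIBER_LENGTH_UM,
                   pixel_size_um: float = 1.0) -> list[FiberSegment]:
    """Segment bright linear fibers in a 2-D image.

    Steps: rolling-ball background subtraction, fixed-threshold binarisation
    (the threshold is an operator input — there is no principled default),
    skeletonisation, removal of skeleton branch points (so crossing fibers
    split into linear portions that never span a junction), then one
    :class:`FiberSegment` per remaining connected path.  Length is the
    euclidean distance between the path endpoints; segments with length
    <= ``min_length_um`` are dropped; orientation comes from the endpoints,
    folded into [0°, 90°].
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ConfigurationError("image must be 2-D grayscale")
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be positive")
    if background_radius_px:
        img = img - restoration.rolling_ball(img, radius=background_radius_px)
    binary = img > binarize_threshold
    if not binary.any():
        return []
    skel = morphology.skeletonize(binary)
    # remove branch points: pixels with more than 2 skeleton neighbours
    nb = _neighbor_count(skel)
    skel = skel & (nb <= 2)
    labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
    fibers: list[FiberSegment] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if ys.size < 2:
            continue
        pts = np.stack([xs, ys], axis=1).astype(float)
        # endpoints: the pair of pixels at maximal separation along the path;
        # for a linear path these are the two 1-neighbour pixels
        comp = labels == lab
        nb_comp = _neighbor_count(comp)
        endpts = np.argwhere(comp & (nb_comp == 1))
        if endpts.shape[0] >= 2:
            cand = endpts[:, ::-1].astype(float)  # (x, y)
            d = np.linalg.norm(cand[:, None] - cand[None], axis=-1)
            i, j = np.unravel_index(np.argmax(d), d.shape)
            e1, e2 = cand[i], cand[j]
        else:
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            i, j = np.unravel_index(np.argmax(d), d.shape)
            e1, e2 = pts[i], pts[j]
        e1u = tuple(e1 * pixel_size_um)
        e2u = tuple(e2 * pixel_size_um)
        length = float(np.linalg.norm(np.subtract(e2u, e1u)))
        if length <= min_length_um:
            continue
        theta = np.rad2deg(np.arctan2(e2u[1] - e1u[1], e2u[0] - e1u[0]))
        fibers.append(FiberSegment(endpoint1=e1u, endpoint2=e2u, length=length,
                                   orientation=float(fold_angle(theta))))
    return fibers


def weighted_mean_orientation(fibers: list[FiberSegment],
                              roi: tuple[float, float, float, float] | None = None) -> float:
    """Length-weighted mean orientation Σ(length·θ)/Σ(length) over the fibers
    whose midpoint lies inside ``roi`` = (x0, y0, x1, y1) in µm (all fibers if
    None).  Returns NaN when no fiber qualifies (missing-value signal)."""
    if roi is not None:
        x0, y0, x1, y1 = roi
        fibers = [f for f in fibers
                  if x0 <= f.midpoint[0] <= x1 and y0 <= f.midpoint[1] <= y1]
    if not fibers:
        return float("nan")
    w = np.array([f.length for f in fibers])
    th = np.array([f.orientation for f in fibers])
    return float(np.sum(w * th) / np.sum(w))


# ---------------------------------------------------------------------------
# curvature-binned intensity
# ---------------------------------------------------------------------------

def intensity_vs_curvature(intensity: np.ndarray, curvature: np.ndarray,
                           bin_width: float = CURVATURE_BIN_WIDTH) -> pd.DataFrame:
    """Bin an intensity profile by matched local curvature.

    Curvature is binned in fixed-width bins (default 0.001 µm⁻¹, edges at
    integer multiples of the width); per-bin mean intensity is then divided by
    the *unbinned* all-sample mean, so the pixel-count-weighted mean of the
    normalised bins is exactly 1.  Empty bins are dropped.

    Returns columns ``bin_left, bin_right, normalized_intensity, n_pixels``.
    """
    inten = np.asarray(intensity, float)
    kappa = np.asarray(curvature, float)
    if inten.shape != kappa.shape or inten.ndim != 1:
        raise ConfigurationError("profiles must be 1-D and matched in length")
    ok = np.isfinite(inten) & np.isfinite(kappa)
    inten, kappa = inten[ok], kappa[ok]
    if inten.size == 0:
        raise DataError("empty profiles")
    overall = inten.mean()
    if overall == 0:
        raise DataError("zero mean intensity; cannot normalise")
    idx = np.floor(kappa / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        m = idx == b
        rows.append((b * bin_width, (b + 1) * bin_width,
                     float(inten[m].mean() / overall), int(m.sum())))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right",
                                       "normalized_intensity", "n_pixels"])
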