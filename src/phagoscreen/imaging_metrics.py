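"""Image-based microglia quantifications.

Four independent measurements share this module:

* **Surveillance area** — from a time-lapse of binary cell masks, the area
  of the max projection (logical OR over frames) divided by the initial
  cell area. A stationary cell scores exactly 1; a cell translating a
  distance ``d`` sweeps a stadium of area ``pi r^2 + 2 r d``, giving the
  analytic limit ``1 + 2 d / (pi r)``.
* **Colocalization** — Pearson correlation of two channels over in-mask
  pixels plus Manders overlap coefficients M1/M2 against per-channel
  thresholds.
* **Viability** — live/dead nucleus classification from a vital-dye
  intensity threshold (fixed or Otsu over the population).
* **Dot-array quantification** — replicate-averaged, background-subtracted
  intensities for antibody dot arrays.

A synthetic moving-disk generator produces intensity stacks with exact
ground-truth masks so segmentation, stabilization and the surveillance
metric can be verified end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import draw as skdraw
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_objects

__all__ = [
    "MaskStack",
    "SurveillanceResult",
    "ColocResult",
    "generate_timelapse",
    "segment_frames",
    "stabilize_stack",
    "surveillance_area",
    "colocalize",
    "classify_viability",
    "quantify_dot_array",
]

logger = logging.getLogger(__name__)


@dataclass
class MaskStack:
    """T binary frames of identical shape; optional physical calibration."""

    frames: np.ndarray  # (T, H, W) bool
    pixel_size: float | None = None  # um / px
    frame_interval: float | None = None  # seconds

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames).astype(bool)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("mask stack must be (T, H, W) with T >= 1")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SurveillanceResult:
    initial_area: int
    union_area: int

    @property
    def ratio(self) -> float:
        return self.union_area / self.initial_area


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float  # NaN when a channel is constant in-mask
    m1: float
    m2: float
    n_pixels: int


def generate_timelapse(
    shape: tuple[int, int],
    radius: float,
    trajectory: np.ndarray | Sequence[tuple[float, float]],
    seed: int = 0,
    noise_sd: float = 0.0,
    foreground: float = 1.0,
) -> tuple[np.ndarray, MaskStack]:
    """Render a disk moving along a trajectory; return intensities and truth masks.

    ``trajectory`` is a (T, 2) array of (row, col) centers. The disk must fit
    entirely inside the frame at every timepoint. Gaussian intensity noise
    of ``noise_sd`` is added to the float intensity stack; truth masks are
    exact regardless of noise.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must be (T, 2) of (row, col) centers")
    H, W = shape
    if ((traj[:, 0] - radius < 0).any() or (traj[:, 0] + radius > H - 1).any()
            or (traj[:, 1] - radius < 0).any() or (traj[:, 1] + radius > W - 1).any()):
        raise ValueError("trajectory leaves the frame")
    rng = np.random.default_rng(seed)
    T = traj.shape[0]
    masks = np.zeros((T, H, W), dtype=bool)
    for t, (r, c) in enumerate(traj):
        rr, cc = skdraw.disk((r, c), radius, shape=(H, W))
        masks[t, rr, cc] = True
    intensity = masks.astype(float) * foreground
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return intensity, MaskStack(masks)


def brownian_trajectory(start: tuple[float, float], step_sd: float, T: int,
                        seed: int = 0) -> np.ndarray:
    """Brownian (Gaussian-increment) trajectory helper for the generator."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=(T - 1, 2))
    return np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)]) + np.asarray(start)


def segment_frames(intensity: np.ndarray, threshold: float | None = None,
                   min_size: int = 0, single_cell: bool = False) -> MaskStack:
    """Threshold + connected-components segmentation of an intensity stack.

    ``threshold=None`` uses Otsu per stack (global); components smaller than
    ``min_size`` pixels are removed; ``single_cell=True`` keeps only the
    largest component per frame. All-background frames yield empty masks
    with a logged warning.
    """
    stack = np.asarray(intensity, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("intensity stack must be (T, H, W)")
    thr = threshold_otsu(stack) if threshold is None else threshold
    masks = np.zeros(stack.shape, dtype=bool)
    for t in range(stack.shape[0]):
        binary = stack[t] > thr
        if min_size > 0:
            # drop components strictly smaller than min_size pixels
            binary = remove_small_objects(binary, max_size=min_size - 1)
        if not binary.any():
            logger.warning("frame %d segmented to empty mask", t)
            continue
        if single_cell:
            lab = label(binary)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            binary = lab == sizes.argmax()
        masks[t] = binary
    return MaskStack(masks)


def stabilize_stack(masks: MaskStack, max_shift: int = 10
                    ) -> tuple[MaskStack, list[tuple[int, int]]]:
    """Register each frame to frame 0 by integer-pixel translation.

    The shift within ``+-max_shift`` maximizing binary overlap with frame 0
    is applied (cross-correlation of the masks); frames slide with background
    padding. If the best shift lies on the search boundary the jitter
    exceeded the search range, which is an error. Returns the stabilized
    stack and the per-frame (dr, dc) shifts (frame 0 is always (0, 0)).
    """
    ref = masks.frames[0]
    if not ref.any():
        raise ValueError("frame 0 is empty; nothing to register to")
    T = len(masks)
    out = np.zeros_like(masks.frames)
    out[0] = ref
    shifts: list[tuple[int, int]] = [(0, 0)]
    offsets = range(-max_shift, max_shift + 1)
    for t in range(1, T):
        frame = masks.frames[t]
        best, best_shift = -1, (0, 0)
        for dr in offsets:
            for dc in offsets:
                overlap = int(np.sum(_translate(frame, dr, dc) & ref))
                if overlap > best:
                    best, best_shift = overlap, (dr, dc)
        if max(abs(best_shift[0]), abs(best_shift[1])) == max_shift:
            raise ValueError(
                f"frame {t}: best shift {best_shift} hits the +-{max_shift} "
                "search bound; increase max_shift"
            )
        out[t] = _translate(frame, *best_shift)
        shifts.append(best_shift)
    return MaskStack(out, masks.pixel_size, masks.frame_interval), shifts


def _translate(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a binary image by (dr, dc), padding with background."""
    out = np.zeros_like(mask)
    H, W = mask.shape
    rs_src = slice(max(0, -dr), min(H, H - dr))
    cs_src = slice(max(0, -dc), min(W, W - dc))
    rs_dst = slice(max(0, dr), min(H, H + dr))
    cs_dst = slice(max(0, dc), min(W, W + dc))
    out[rs_dst, cs_dst] = mask[rs_src, cs_src]
    return out


def surveillance_area(masks: MaskStack) -> SurveillanceResult:
    """Union (max-projection) area over frames, normalized to frame-0 area."""
    initial = int(masks.frames[0].sum())
    if initial == 0:
        raise ValueError("frame 0 is empty; initial area undefined")
    union = int(np.logical_or.reduce(masks.frames, axis=0).sum())
    return SurveillanceResult(initial, union)


def colocalize(channel_a: np.ndarray, channel_b: np.ndarray,
               mask: np.ndarray | None = None,
               threshold_a: float | None = None,
               threshold_b: float | None = None) -> ColocResult:
    """Pearson correlation and Manders overlap of two channels within a mask.

    ``m1`` is the fraction of channel-A intensity lying on B-positive pixels
    (B above its threshold) and ``m2`` the mirror image. Thresholds default
    to Otsu computed per channel within the mask. A constant channel leaves
    Pearson undefined (NaN) while Manders remains defined.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    av, bv = a[mask], b[mask]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(av, bv).statistic)
    ta = threshold_otsu(av) if threshold_a is None else threshold_a
    tb = threshold_otsu(bv) if threshold_b is None else threshold_b
    sum_a, sum_b = av.sum(), bv.sum()
    m1 = float(av[bv > tb].sum() / sum_a) if sum_a > 0 else 0.0
    m2 = float(bv[av > ta].sum() / sum_b) if sum_b > 0 else 0.0
    return ColocResult(r, m1, m2, int(mask.sum()))


def classify_viability(intensities: Sequence[float],
                       threshold: float | None = None
                       ) -> tuple[np.ndarray, float]:
    """Label nuclei live/dead by vital-dye intensity; return labels + dead fraction.

    Dead iff mean intensity exceeds the threshold; ``threshold=None``
    computes Otsu over the population (needs a genuinely bimodal input).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no nuclei to classify")
    thr = threshold_otsu(x) if threshold is None else threshold
    dead = x > thr
    labels = np.where(dead, "dead", "live")
    return labels, float(dead.mean())


def read_mask_stack(path, pixel_size: float | None = None,
                    frame_interval: float | None = None) -> MaskStack:
    """Read a (multi-page) TIFF stack as binary masks (nonzero = foreground)."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return MaskStack(arr != 0, pixel_size, frame_interval)


def write_mask_stack(masks: MaskStack, path) -> None:
    """Write masks as an 8-bit multi-page TIFF (255 = foreground)."""
    import tifffile

    tifffile.imwrite(path, (masks.frames.astype(np.uint8) * 255))


def quantify_dot_array(dots: pd.DataFrame, negative_label: str = "negative",
                       analyte_col: str = "analyte",
                       intensity_col: str = "intensity") -> pd.Series:
    """Replicate-averaged, background-subtracted dot intensities per analyte.

    Technical-replicate dots of each analyte are averaged, then the mean of
    the negative-control dots is subtracted. Values below zero are reported
    as-is (no clipping). The negative group itself is excluded from output.
    """
    if analyte_col not in dots.columns or intensity_col not in dots.columns:
        raise ValueError(f"need columns {analyte_col!r} and {intensity_col!r}")
    groups = dots.groupby(analyte_col)[intensity_col].mean()
    if negative_label not in groups.index:
        raise ValueError(f"no negative-control group {negative_label!r}")
    background = groups[negative_label]
    out = (groups - background).drop(negative_label)
    out.name = "background_subtracted_mean"
    return out
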