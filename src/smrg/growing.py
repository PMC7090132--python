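"""The SmRG main loop: local statistics, voxel admission, reseeding.

Starting from one or more seed voxels the algorithm repeatedly

1. extracts a small crop centred on the current seed (on-plane size is the
   stack size over ``crop_fraction``, never below ``crop_min``; depth
   ``crop_depth`` planes),
2. tests the crop histogram for unimodality with Hartigan's dip test:
   multimodal crops are thresholded with Otsu's method, unimodal crops get
   the EM-fitted background/signal mixture and voxels are admitted when
   their posterior probability of signal membership exceeds ``tau``,
3. keeps only admitted voxels 26-connected to the seed within the crop and
   ORs them into the global mask,
4. reseeds from the regional maxima of the per-plane Euclidean distance
   transform of the newly segmented crop,

until the seed queue is exhausted.  The mask only ever grows, so the
procedure terminates; every retained voxel is 26-connected to an initial
seed through retained voxels.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.morphology import local_maxima
from skimage.morphology import skeletonize as skeletonize_2d

from .mixture import fit_em, signal_posterior
from .thresholding import dip_test, otsu_threshold

__all__ = [
    "ImageStack",
    "Seed",
    "GrowConfig",
    "SegmentationMask",
    "extract_crop",
    "segment_crop",
    "next_seeds",
    "grow",
    "detect_somata",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class Seed(NamedTuple):
    """A voxel position, 0-based (z, y, x)."""

    z: int
    y: int
    x: int


@dataclass
class ImageStack:
    """A 3-D integer intensity volume with anisotropic voxel size (µm)."""

    voxels: np.ndarray                      # (z, y, x)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("stack must be 3-D (z, y, x)")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def contains(self, seed: Seed) -> bool:
        return all(0 <= c < s for c, s in zip(seed, self.shape))


@dataclass(frozen=True)
class GrowConfig:
    """Tunable knobs of the growing loop (defaults follow the method)."""

    posterior_threshold: float = 0.999   # tau: admission rule 1-alpha_y > tau
    crop_fraction: int = 8               # on-plane crop edge = stack edge / 8
    crop_min: int = 32                   # floor of the on-plane crop edge
    crop_depth: int = 3                  # planes per crop
    dip_alpha: float = 0.01              # unimodality rejection level
    connectivity: int = 26

    def __post_init__(self):
        if not (0.0 < self.posterior_threshold < 1.0):
            raise ValueError("posterior_threshold must be in (0, 1)")
        if self.crop_min < 32:
            raise ValueError("crop_min must be at least 32")
        if self.crop_depth % 2 != 1:
            raise ValueError("crop_depth must be odd")
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity is supported")


@dataclass
class SegmentationMask:
    """Boolean segmentation volume plus the seeds that were processed."""

    mask: np.ndarray
    seed_history: list[Seed] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def _window(center: int, size: int, extent: int) -> tuple[int, int]:
    """1-D window of `size` voxels containing `center`, shifted inside [0, extent)."""
    size = min(size, extent)
    start = center - size // 2
    start = max(0, min(start, extent - size))
    return start, start + size


def extract_crop(stack: ImageStack, seed: Seed, config: GrowConfig = GrowConfig()
                 ) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Crop centred on the seed; returns (sub-volume, offset).

    The on-plane size is ``floor(edge / crop_fraction)`` raised to
    ``crop_min``; depth is ``crop_depth``.  Near the borders the window is
    shifted toward the interior (never padded) so the histogram sample size
    stays constant whenever the stack is large enough; for stacks smaller
    than the window it is clipped.  ``crop[c] == stack.voxels[c + offset]``.
    """
    if not stack.contains(seed):
        raise ValueError(f"seed {tuple(seed)} outside stack {stack.shape}")
    nz, ny, nx = stack.shape
    wy = max(ny // config.crop_fraction, config.crop_min)
    wx = max(nx // config.crop_fraction, config.crop_min)
    z0, z1 = _window(seed.z, config.crop_depth, nz)
    y0, y1 = _window(seed.y, wy, ny)
    x0, x1 = _window(seed.x, wx, nx)
    return stack.voxels[z0:z1, y0:y1, x0:x1], (z0, y0, x0)


def segment_crop(crop: np.ndarray, seed_local: Seed, config: GrowConfig = GrowConfig()
                 ) -> np.ndarray:
    """Segment one crop and keep the 26-connected component of the seed.

    Multimodal crops (dip test, p < dip_alpha) are thresholded with Otsu;
    unimodal crops with the mixture posterior.  Returns a boolean mask of
    the crop, empty when the seed itself fails the admission rule.
    """
    crop = np.asarray(crop)
    decision = dip_test(crop, alpha=config.dip_alpha)
    admitted = None
    if decision.multimodal:
        admitted = crop > otsu_threshold(crop)
    else:
        report = fit_em(crop)
        if report.converged:
            post = signal_posterior(crop, report.params)
            admitted = post > config.posterior_threshold
        else:
            log.warning("EM did not converge on crop; falling back to Otsu")
            try:
                admitted = crop > otsu_threshold(crop)
            except ValueError:      # constant crop: nothing to admit
                admitted = np.zeros(crop.shape, dtype=bool)

    if not admitted[tuple(seed_local)]:
        return np.zeros(crop.shape, dtype=bool)
    labels, _ = ndimage.label(admitted, structure=_STRUCT26)
    return labels == labels[tuple(seed_local)]


def next_seeds(local_mask: np.ndarray, offset: tuple[int, int, int] = (0, 0, 0)
               ) -> list[Seed]:
    """New seeds: ridge maxima of the per-plane distance transform.

    For every z-plane of the segmented crop the ridge of the 2-D Euclidean
    distance transform (the plane's medial axis, i.e. its distance-transform
    maxima including plateaus cut by the crop boundary) is extracted; every
    connected ridge component contributes the voxel nearest its centroid.
    Components elongated relative to their thickness — tube cross sections
    running along the plane — additionally contribute their ridge tips, so
    the growth front always reaches the crop boundary and the next crop can
    carry it onward.  A strict regional-maximum rule would stall here: on a
    clean straight tube the ridge is one constant plateau attached to any
    slightly thicker region, hence never locally maximal.
    """
    seeds: list[Seed] = []
    oz, oy, ox = offset
    eight = np.ones((3, 3), dtype=bool)
    ny, nx = local_mask.shape[1:]
    for z in range(local_mask.shape[0]):
        plane = local_mask[z]
        if not plane.any():
            continue
        edt = ndimage.distance_transform_edt(plane)
        # ridge of the distance transform: 2-D thinning (edge-padded so the
        # ridge of a window-cut tube runs to the window edge) plus genuine
        # regional maxima of the EDT
        pad = 8
        thin = skeletonize_2d(np.pad(plane, pad, mode="edge"))[pad:-pad, pad:-pad]
        ridge = (thin & plane) | (local_maxima(edt, connectivity=2) & plane)
        labels, n = ndimage.label(ridge, structure=eight)
        for lab in range(1, n + 1):
            ys, xs = np.nonzero(labels == lab)
            cy, cx = ys.mean(), xs.mean()
            d2c = (ys - cy) ** 2 + (xs - cx) ** 2
            k = int(np.argmin(d2c))
            seeds.append(Seed(z + oz, int(ys[k]) + oy, int(xs[k]) + ox))
            # elongated ridge (a tube running along the plane): seed both
            # extremities too, so the front reaches the crop boundary
            thick = edt[ys, xs].max()
            if d2c.max() > (3.0 * thick) ** 2:
                e1 = int(np.argmax(d2c))
                d2e = (ys - ys[e1]) ** 2 + (xs - xs[e1]) ** 2
                e2 = int(np.argmax(d2e))
                for e in (e1, e2):
                    seeds.append(Seed(z + oz, int(ys[e]) + oy, int(xs[e]) + ox))
            # one continuation point per touched crop edge: a structure cut
            # by the window continues in the neighbouring crop
            for edge_sel in (ys <= 1, ys >= ny - 2, xs <= 1, xs >= nx - 2):
                if edge_sel.any():
                    j = int(np.nonzero(edge_sel)[0][0])
                    seeds.append(Seed(z + oz, int(ys[j]) + oy, int(xs[j]) + ox))
    return sorted(set(seeds))


def grow(stack: ImageStack, seeds, config: GrowConfig = GrowConfig()
         ) -> SegmentationMask:
    """Run the full region-growing loop from one or more seeds.

    Breadth-first over a FIFO seed queue; each seed position is processed at
    most once, newly discovered seeds are deduplicated against everything
    already queued, and crop results are ORed into the global mask (voxels
    are never removed).  Deterministic for a given stack, seed list and
    configuration.
    """
    seeds = [Seed(*s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed is required")
    for s in seeds:
        if not stack.contains(s):
            raise ValueError(f"seed {tuple(s)} outside stack {stack.shape}")

    mask = np.zeros(stack.shape, dtype=bool)
    queue: deque[Seed] = deque(seeds)
    seen: set[Seed] = set(seeds)
    history: list[Seed] = []

    while queue:
        seed = queue.popleft()
        history.append(seed)
        crop, offset = extract_crop(stack, seed, config)
        local_seed = Seed(*(c - o for c, o in zip(seed, offset)))
        local = segment_crop(crop, local_seed, config)
        if not local.any():
            continue
        view = mask[offset[0]:offset[0] + local.shape[0],
                    offset[1]:offset[1] + local.shape[1],
                    offset[2]:offset[2] + local.shape[2]]
        view |= local
        for s in next_seeds(local, offset):
            if s not in seen:
                seen.add(s)
                queue.append(s)

    if not mask.any():
        log.warning("no voxel passed the admission rule; empty segmentation")
    return SegmentationMask(mask=mask, seed_history=history)


def detect_somata(stack: ImageStack, radius_range: tuple[float, float],
                  min_score: float = 0.33) -> list[Seed]:
    """Automatic seeding: spherical Hough transform for somata.

    Foreground boundary voxels (Otsu binarisation minus its erosion) vote
    for sphere centres by FFT correlation with spherical-shell kernels over
    the radius range; accumulator peaks above ``min_score`` (fraction of the
    shell covered by boundary voxels) become seeds, strongest first, with
    non-maximum suppression at the detected radius.
    """
    rmin, rmax = radius_range
    if not (0 < rmin <= rmax):
        raise ValueError("radius range must be positive")
    vox = stack.voxels
    flat = vox.ravel()
    if flat.max() == flat.min():
        return []
    fg = vox > otsu_threshold(flat)
    if not fg.any():
        return []
    edges = fg & ~ndimage.binary_erosion(fg)

    best_score = np.zeros(vox.shape)
    best_radius = np.zeros(vox.shape)
    for r in np.arange(float(rmin), float(rmax) + 0.5, 1.0):
        half = int(np.ceil(r)) + 1
        zz, yy, xx = np.mgrid[-half:half + 1, -half:half + 1, -half:half + 1]
        dist = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
        shell = (np.abs(dist - r) <= 0.75).astype(float)
        acc = fftconvolve(edges.astype(float), shell, mode="same") / shell.sum()
        better = acc > best_score
        best_score[better] = acc[better]
        best_radius[better] = r

    seeds: list[Seed] = []
    score = best_score.copy()
    while True:
        idx = np.unravel_index(np.argmax(score), score.shape)
        s = score[idx]
        if s < min_score:
            break
        seeds.append(Seed(*(int(c) for c in idx)))
        r = best_radius[idx]
        zz, yy, xx = np.ogrid[:score.shape[0], :score.shape[1], :score.shape[2]]
        d2 = (zz - idx[0]) ** 2 + (yy - idx[1]) ** 2 + (xx - idx[2]) ** 2
        score[d2 <= (2 * r) ** 2] = 0.0
    return seeds
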