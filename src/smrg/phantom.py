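"""Synthetic neuron phantoms with exact ground truth.

A phantom is a branching tree of tapered tubes (capsules) plus an optional
spherical soma, rasterised into a boolean voxel mask with an SWC ground
truth centerline.  Rendering draws every background voxel from the discrete
normal K0 + round(N(0, vB)) (clipped at zero) and every structure voxel
from K0 + NegativeBinomial(r, p) — exactly the mixture the segmentation
model assumes, so generator parameters double as recovery oracles.

``standard_suite`` provides fixed named phantoms (straight tube, Y-branch,
a Purkinje-like tree with soma, two touching somata) at three contrast
tiers, muS/sqrt(vB) ≈ 10, 5 and 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growing import ImageStack
from .mixture import MixtureParams
from .skeleton import Reconstruction, _SWC_COLUMNS

__all__ = ["Branch", "PhantomSpec", "PhantomTruth",
           "rasterize", "render", "standard_suite", "STANDARD_NAMES", "TIERS"]

#: noise parameters per contrast tier: K0=100, vB=25, signal vS = 2 muS
TIERS = {
    "high": MixtureParams(K0=100, vB=25.0, alpha=0.5, r=50.0, p=0.5),
    "medium": MixtureParams(K0=100, vB=25.0, alpha=0.5, r=25.0, p=0.5),
    "low": MixtureParams(K0=100, vB=25.0, alpha=0.5, r=12.5, p=0.5),
}

STANDARD_NAMES = ("tube", "ybranch", "purkinje", "somata")


@dataclass(frozen=True)
class Branch:
    """A tapered tube from start to end (µm), radii interpolated linearly."""

    start: tuple[float, float, float]   # (z, y, x) µm
    end: tuple[float, float, float]
    r_start: float
    r_end: float

    def __post_init__(self):
        if self.r_start <= 0 or self.r_end <= 0:
            raise ValueError("branch radii must be positive")


@dataclass
class PhantomSpec:
    tree: list[Branch]
    soma: tuple[tuple[float, float, float], float] | None
    stack_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise: MixtureParams = field(default_factory=lambda: TIERS["high"])
    rng_seed: int = 0


@dataclass
class PhantomTruth:
    mask: np.ndarray
    centerline: Reconstruction
    spec: PhantomSpec


def _voxel_grid(shape, voxel_size):
    dz, dy, dx = voxel_size
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return zz * dz, yy * dy, xx * dx


def rasterize(spec: PhantomSpec) -> PhantomTruth:
    """Voxelise the phantom; voxel centers inside any solid become mask."""
    mask = np.zeros(spec.stack_shape, dtype=bool)
    dz, dy, dx = spec.voxel_size

    def check_bounds(*points):
        for pt in points:
            for axis, c in enumerate(pt):
                extent = (spec.stack_shape[axis] - 1) * spec.voxel_size[axis]
                if not (0.0 <= c <= extent):
                    raise ValueError(
                        f"phantom geometry outside the stack: coordinate {c} "
                        f"on axis {axis} (extent {extent})")

    def bbox_slices(lo, hi, margin):
        sl = []
        for axis, (a, b) in enumerate(zip(lo, hi)):
            d = spec.voxel_size[axis]
            i0 = max(0, int(np.floor((min(a, b) - margin) / d)) - 1)
            i1 = min(spec.stack_shape[axis], int(np.ceil((max(a, b) + margin) / d)) + 2)
            if i0 >= i1:
                raise ValueError("phantom geometry outside the stack")
            sl.append(slice(i0, i1))
        return tuple(sl)

    for br in spec.tree:
        a = np.asarray(br.start, dtype=float)
        b = np.asarray(br.end, dtype=float)
        check_bounds(a, b)
        margin = max(br.r_start, br.r_end)
        sl = bbox_slices(a, b, margin)
        zz, yy, xx = _voxel_grid(spec.stack_shape, spec.voxel_size)
        zz = zz[sl[0], :, :]
        yy = yy[:, sl[1], :]
        xx = xx[:, :, sl[2]]
        ab = b - a
        L2 = float(ab @ ab)
        pz, py, px = zz - a[0], yy - a[1], xx - a[2]
        if L2 == 0:
            t = np.zeros(np.broadcast_shapes(pz.shape, py.shape, px.shape))
        else:
            t = (pz * ab[0] + py * ab[1] + px * ab[2]) / L2
            t = np.clip(t, 0.0, 1.0)
        d2 = ((pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2
              + (px - t * ab[2]) ** 2)
        r = br.r_start + t * (br.r_end - br.r_start)
        mask[sl] |= d2 <= r ** 2

    if spec.soma is not None:
        c, r = np.asarray(spec.soma[0], dtype=float), float(spec.soma[1])
        check_bounds(c)
        sl = bbox_slices(c, c, r)
        zz, yy, xx = _voxel_grid(spec.stack_shape, spec.voxel_size)
        zz = zz[sl[0], :, :]
        yy = yy[:, sl[1], :]
        xx = xx[:, :, sl[2]]
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        mask[sl] |= d2 <= r ** 2

    centerline = _centerline(spec)
    return PhantomTruth(mask=mask, centerline=centerline, spec=spec)


def _centerline(spec: PhantomSpec) -> Reconstruction:
    """Ground-truth SWC: sampled branch axes, chained from the root outward.

    Branch start points are attached to the nearest already-emitted node
    when one lies within a branch radius (so children chain onto their
    parent's tip); otherwise they start a new root.
    """
    dz, dy, dx = spec.voxel_size
    step = min(spec.voxel_size)
    rows: list[tuple] = []
    coords: list[np.ndarray] = []

    def emit(zyx, radius, parent) -> int:
        nid = len(rows) + 1
        z, y, x = zyx
        rows.append((nid, 1 if parent == -1 else 3,
                     x, y, z, radius, parent))
        coords.append(np.asarray(zyx, dtype=float))
        return nid

    if spec.soma is not None:
        emit(spec.soma[0], spec.soma[1], -1)

    for br in spec.tree:
        a = np.asarray(br.start, dtype=float)
        b = np.asarray(br.end, dtype=float)
        length = float(np.linalg.norm(b - a))
        n_samples = max(2, int(np.ceil(length / step)) + 1)
        attach = -1
        if coords:
            d = [float(np.linalg.norm(c - a)) for c in coords]
            k = int(np.argmin(d))
            if d[k] <= max(br.r_start, 1.5 * step) + 1e-9:
                attach = k + 1
        parent = attach
        for t in np.linspace(0.0, 1.0, n_samples):
            pos = a + t * (b - a)
            if parent != -1 and t == 0.0 and attach != -1:
                # skip duplicating the attachment point itself
                if np.linalg.norm(coords[attach - 1] - pos) < 0.5 * step:
                    continue
            radius = br.r_start + t * (br.r_end - br.r_start)
            parent = emit(pos, radius, parent)

    if not rows:
        raise ValueError("phantom has neither branches nor a soma")
    return Reconstruction(pd.DataFrame(rows, columns=_SWC_COLUMNS))


def render(truth: PhantomTruth, rng_seed: int | None = None) -> ImageStack:
    """Draw intensities for a rasterised phantom (pure function of the seed)."""
    spec = truth.spec
    seed = spec.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    pars = spec.noise
    shape = spec.stack_shape
    bg = pars.K0 + np.round(rng.normal(0.0, np.sqrt(pars.vB), shape)).astype(np.int64)
    bg = np.clip(bg, 0, None)
    fg = pars.K0 + rng.negative_binomial(pars.r, pars.p, shape)
    vox = np.where(truth.mask, fg, bg).astype(np.int64)
    return ImageStack(voxels=vox, voxel_size=spec.voxel_size)


def _standard_spec(name: str, tier: str) -> PhantomSpec:
    noise = TIERS[tier]
    seed = 1000 + 10 * list(STANDARD_NAMES).index(name) \
        + list(TIERS).index(tier)
    if name == "tube":
        tree = [Branch((8, 64, 14), (8, 64, 114), 3.0, 3.0)]
        return PhantomSpec(tree, None, (16, 128, 128), noise=noise, rng_seed=seed)
    if name == "ybranch":
        tree = [
            Branch((8, 108, 64), (8, 68, 64), 3.0, 3.0),
            Branch((8, 68, 64), (6, 24, 36), 3.0, 2.0),
            Branch((8, 68, 64), (10, 24, 92), 3.0, 2.0),
        ]
        return PhantomSpec(tree, None, (16, 128, 128), noise=noise, rng_seed=seed)
    if name == "purkinje":
        soma = ((10, 120, 72), 8.0)
        tree = [
            Branch((10, 114, 72), (10, 88, 72), 4.0, 3.0),
            Branch((10, 88, 72), (8, 56, 44), 3.0, 2.0),
            Branch((10, 88, 72), (12, 56, 100), 3.0, 2.0),
            Branch((8, 56, 44), (8, 20, 28), 2.0, 1.5),
            Branch((8, 56, 44), (6, 24, 64), 2.0, 1.5),
            Branch((12, 56, 100), (12, 20, 84), 2.0, 1.5),
            Branch((12, 56, 100), (14, 24, 120), 2.0, 1.5),
        ]
        return PhantomSpec(tree, soma, (20, 144, 144), noise=noise, rng_seed=seed)
    if name == "somata":
        soma = ((8, 64, 54), 8.0)
        tree = [Branch((8, 64, 70), (8, 64, 70.01), 8.0, 8.0)]
        return PhantomSpec(tree, soma, (16, 128, 128), noise=noise, rng_seed=seed)
    raise ValueError(f"unknown phantom name {name!r}; choose from {STANDARD_NAMES}")


def standard_suite(name: str, tier: str = "high") -> tuple[ImageStack, PhantomTruth]:
    """A fixed named phantom at a contrast tier, rendered with a fixed seed."""
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; choose from {tuple(TIERS)}")
    spec = _standard_spec(name, tier)
    truth = rasterize(spec)
    return render(truth), truth
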