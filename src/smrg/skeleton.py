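"""Centerline extraction and SWC reconstructions.

The volumetric segmentation is reduced to a one-voxel-wide centerline with
the Lee medial-surface-axis thinning algorithm and converted to the
standard SWC tree (one node per skeleton voxel, radius from the Euclidean
distance transform of the mask), so that voxel segmentations can be
compared with point-based gold standards.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = ["Reconstruction", "skeletonize", "skeleton_to_swc",
           "read_swc", "write_swc"]

_SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class SwcError(ValueError):
    """Malformed SWC content."""


@dataclass
class Reconstruction:
    """An SWC-style node table.

    Columns: id (1-based, contiguous), type (SWC structure code), x, y, z
    (physical coordinates, µm), radius (µm), parent (id, -1 for a root).
    Parents always precede their children.
    """

    nodes: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.nodes, columns=_SWC_COLUMNS).reset_index(drop=True)
        df = df.astype({"id": int, "type": int, "parent": int,
                        "x": float, "y": float, "z": float, "radius": float})
        if len(df) == 0:
            raise SwcError("empty reconstruction")
        if not (df["id"] == np.arange(1, len(df) + 1)).all():
            raise SwcError("node ids must be contiguous from 1")
        seen = set()
        for i, (nid, parent) in enumerate(zip(df["id"], df["parent"]), start=1):
            if parent != -1 and parent not in seen:
                raise SwcError(f"line {i}: parent {parent} does not precede node {nid}")
            seen.add(nid)
        self.nodes = df

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def coords(self) -> np.ndarray:
        """Node coordinates as an (n, 3) array in (x, y, z) order."""
        return self.nodes[["x", "y", "z"]].to_numpy()

    @property
    def roots(self) -> np.ndarray:
        return self.nodes.loc[self.nodes["parent"] == -1, "id"].to_numpy()


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Medial-axis thinning (Lee) of a 3-D boolean mask.

    The result is a subset of the mask with the same number of 26-connected
    components and no fully-set 2x2x2 block.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        return np.zeros(mask.shape, dtype=bool)
    return _sk_skeletonize(mask).astype(bool)


def skeleton_to_swc(skeleton: np.ndarray, mask: np.ndarray,
                    voxel_size: tuple[float, float, float],
                    root) -> Reconstruction:
    """Spanning tree over 26-adjacent skeleton voxels, as a Reconstruction.

    The tree is rooted at the skeleton voxel nearest the given root seed
    (which must lie within 10 voxels of the skeleton); any further connected
    components are rooted at their lowest-index voxel.  Node radius is the
    mask's Euclidean distance transform at the voxel, scaled by the mean
    on-plane voxel size (isotropic approximation of neurite thickness), and
    coordinates are scaled to µm.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise ValueError("empty skeleton")
    dz, dy, dx = voxel_size
    vox = np.argwhere(skeleton)                       # (n, 3) in (z, y, x)
    root = np.asarray(tuple(root), dtype=float)
    d2 = np.sum((vox - root) ** 2, axis=1)
    start = int(np.argmin(d2))
    if d2[start] > 10.0 ** 2:
        raise ValueError("root seed is farther than 10 voxels from the skeleton")

    index = {tuple(v): i for i, v in enumerate(map(tuple, vox))}
    offsets = [(a, b, c)
               for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]

    edt = ndimage.distance_transform_edt(np.asarray(mask, dtype=bool))
    radius_scale = 0.5 * (dy + dx)

    parent = np.full(len(vox), -2, dtype=int)         # -2 = unvisited
    order: list[int] = []
    pending = deque()

    def bfs(seed_i: int):
        parent[seed_i] = -1
        pending.append(seed_i)
        while pending:
            i = pending.popleft()
            order.append(i)
            z, y, x = vox[i]
            for a, b, c in offsets:
                j = index.get((z + a, y + b, x + c))
                if j is not None and parent[j] == -2:
                    parent[j] = i
                    pending.append(j)

    bfs(start)
    for i in range(len(vox)):                          # remaining components
        if parent[i] == -2:
            bfs(i)

    swc_id = np.empty(len(vox), dtype=int)
    rows = []
    for new_id, i in enumerate(order, start=1):
        swc_id[i] = new_id
        z, y, x = vox[i]
        p = parent[i]
        rows.append((
            new_id,
            1 if p == -1 else 3,
            x * dx, y * dy, z * dz,
            float(edt[z, y, x]) * radius_scale,
            -1 if p == -1 else int(swc_id[p]),
        ))
    return Reconstruction(pd.DataFrame(rows, columns=_SWC_COLUMNS))


def write_swc(recon: Reconstruction, path, header: str | None = None) -> None:
    """Write a reconstruction as whitespace-delimited 7-column SWC."""
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    if header:
        lines = [f"# {h}" for h in header.splitlines()] + lines
    for row in recon.nodes.itertuples(index=False):
        lines.append(f"{row.id} {row.type} {row.x:.4f} {row.y:.4f} "
                     f"{row.z:.4f} {row.radius:.4f} {row.parent}")
    path.write_text("\n".join(lines) + "\n")


def read_swc(path) -> Reconstruction:
    """Read and validate a 7-column SWC file ('#' comments allowed)."""
    rows = []
    ids = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, ntype = int(parts[0]), int(parts[1])
                x, y, z, radius = map(float, parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcError(f"line {lineno}: {exc}") from None
            if nid in ids:
                raise SwcError(f"line {lineno}: duplicate id {nid}")
            if parent != -1 and parent not in ids:
                raise SwcError(f"line {lineno}: parent {parent} not defined yet")
            ids.add(nid)
            rows.append((nid, ntype, x, y, z, radius, parent))
    if not rows:
        raise SwcError(f"{path}: no SWC nodes found")
    df = pd.DataFrame(rows, columns=_SWC_COLUMNS)
    if not (df["id"] == np.arange(1, len(df) + 1)).all():
        raise SwcError("node ids must be contiguous from 1")
    return Reconstruction(df)
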