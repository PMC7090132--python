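"""Reconstruction-comparison metrics.

Two point-set reconstructions A (test) and B (reference) are compared by

* SD, the spatial distance: the two directed mean nearest-node distances,
  averaged:  SD = sum_i d_AB(i) / (2|A|) + sum_j d_BA(j) / (2|B|);
* SSD, the substantial spatial distance: the same construction restricted
  to nodes whose nearest-neighbour distance exceeds a tolerance S (the mean
  of each surviving set, halved and summed), with SSD% the percentage of
  nodes contributing;
* precision / recall / F-score under greedy one-to-one matching of nodes by
  ascending distance, a pair being a true positive when its distance is at
  most S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ComparisonResult",
    "PRFResult",
    "nearest_distances",
    "spatial_distance",
    "substantial_spatial_distance",
    "precision_recall_f",
    "compare_reconstructions",
]


@dataclass(frozen=True)
class ComparisonResult:
    sd: float
    ssd: float
    ssd_pct: float
    threshold_S: float
    n_A: int
    n_B: int


@dataclass(frozen=True)
class PRFResult:
    precision: float
    recall: float
    f_score: float
    threshold_S: float


def _as_points(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] == 0:
        raise ValueError("node set must be a non-empty (n, d) array")
    return a


def nearest_distances(a, b) -> np.ndarray:
    """d_AB: for each node of A, the distance to its nearest node of B."""
    a, b = _as_points(a), _as_points(b)
    d, _ = cKDTree(b).query(a)
    return d


def spatial_distance(a, b) -> float:
    """SD: symmetric mean nearest-node distance."""
    dab = nearest_distances(a, b)
    dba = nearest_distances(b, a)
    return float(dab.sum() / (2 * len(dab)) + dba.sum() / (2 * len(dba)))


def substantial_spatial_distance(a, b, s: float) -> tuple[float, float]:
    """(SSD, SSD%) for tolerance S: discrepancy from nodes farther than S.

    Directions with no node beyond S contribute 0 to the SSD mean; when no
    node at all exceeds S the result is (0, 0) — no substantial discrepancy.
    """
    if s < 0:
        raise ValueError("tolerance S must be non-negative")
    dab = nearest_distances(a, b)
    dba = nearest_distances(b, a)
    Dab = dab[dab > s]
    Dba = dba[dba > s]
    mab = Dab.mean() if Dab.size else 0.0
    mba = Dba.mean() if Dba.size else 0.0
    ssd = float(mab / 2 + mba / 2)
    ssd_pct = 100.0 * (Dab.size + Dba.size) / (len(dab) + len(dba))
    return ssd, float(ssd_pct)


def precision_recall_f(a, b, s: float, matching: str = "nearest") -> PRFResult:
    """P/R/F of test nodes A against reference B at tolerance S.

    ``matching="nearest"`` (default) scores the spatial overlap between
    closest corresponding nodes: precision is the fraction of test nodes
    with a reference node within S, recall the fraction of reference nodes
    with a test node within S.  This tolerates the different node densities
    of a voxel-wise skeleton and a sparsely traced gold standard.

    ``matching="one_to_one"`` instead matches nodes greedily in ascending
    pair-distance order, each node used at most once; pairs with distance
    <= S are true positives.  Stricter: a reconstruction that over- or
    under-samples a stretch of the reference is penalised even when the
    geometry is perfect.
    """
    if s <= 0:
        raise ValueError("tolerance S must be positive")
    a, b = _as_points(a), _as_points(b)
    if matching == "nearest":
        precision = float(np.mean(nearest_distances(a, b) <= s))
        recall = float(np.mean(nearest_distances(b, a) <= s))
    elif matching == "one_to_one":
        # candidate pairs within S only: farther pairs can never match
        pairs = cKDTree(a).query_ball_tree(cKDTree(b), r=s)
        cand = [(float(np.linalg.norm(a[i] - b[j])), i, j)
                for i, js in enumerate(pairs) for j in js]
        cand.sort()
        used_a = np.zeros(len(a), dtype=bool)
        used_b = np.zeros(len(b), dtype=bool)
        tp = 0
        for _, i, j in cand:
            if not used_a[i] and not used_b[j]:
                used_a[i] = used_b[j] = True
                tp += 1
        precision = tp / len(a)
        recall = tp / len(b)
    else:
        raise ValueError(f"unknown matching {matching!r}")
    denom = precision + recall
    f = 2 * precision * recall / denom if denom > 0 else 0.0
    return PRFResult(precision, recall, f, s)


def compare_reconstructions(a, b, s: float = 2.0) -> ComparisonResult:
    """SD / SSD / SSD% of two node sets at tolerance S (default 2 voxels)."""
    a, b = _as_points(a), _as_points(b)
    sd = spatial_distance(a, b)
    ssd, pct = substantial_spatial_distance(a, b, s)
    return ComparisonResult(sd, ssd, pct, s, len(a), len(b))
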