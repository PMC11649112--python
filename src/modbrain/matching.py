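"""Cross-atlas network comparison via the mean-of-closest centroid distance.

Two brain networks, each a set of ROI centroids in world (mm) coordinates,
are compared with the symmetrized mean-of-closest-point distance

    d_MoC(A, B) = [d(A, B) + d(B, A)] / 2,
    d(A, B) = mean over a in A of min over b in B of ||a - b||.

d_MoC is symmetric by construction but is not a metric (no triangle
inequality); it ranks geometric proximity of centroid sets of possibly
different sizes.  Networks from two decompositions are paired one-to-one
greedily by globally smallest remaining d_MoC; an optimal (Hungarian)
assignment is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["BrainNetwork", "MatchResult", "moc_distance", "pair_networks"]


@dataclass
class BrainNetwork:
    """One column of the loading matrix as a set of ROIs with centroids."""

    network_index: int
    roi_indices: set[int]
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if len(self.roi_indices) < 1:
            raise ValueError("a brain network must contain at least one ROI")
        if self.centroids.shape != (len(self.roi_indices), 3):
            raise ValueError("centroids must be m-by-3 with m = |roi_indices|")

    @property
    def size(self) -> int:
        return len(self.roi_indices)


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]
    distances: list[float]
    unmatched: list[int]


def moc_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetrized mean-of-closest Euclidean distance between centroid sets (mm)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("centroid sets must be non-empty")
    D = cdist(A, B)
    return float((D.min(axis=1).mean() + D.min(axis=0).mean()) / 2.0)


def pair_networks(list1: list[BrainNetwork], list2: list[BrainNetwork],
                  method: str = "greedy") -> MatchResult:
    """One-to-one pairing of networks by d_MoC.

    ``greedy`` repeatedly takes the globally smallest remaining distance
    (ties broken by lexicographically smallest index pair) until the smaller
    list is exhausted; ``optimal`` minimizes the total distance via the
    Hungarian algorithm.  Leftover networks of the longer list are reported
    as unmatched.
    """
    if not list1 or not list2:
        raise ValueError("both network lists must be non-empty")
    n1, n2 = len(list1), len(list2)
    D = np.array([[moc_distance(a.centroids, b.centroids) for b in list2] for a in list1])

    pairs: list[tuple[int, int]] = []
    if method == "greedy":
        used1: set[int] = set()
        used2: set[int] = set()
        for _ in range(min(n1, n2)):
            best = None
            for i in range(n1):
                if i in used1:
                    continue
                for j in range(n2):
                    if j in used2:
                        continue
                    key = (D[i, j], i, j)
                    if best is None or key < best:
                        best = key
            assert best is not None
            _, i, j = best
            used1.add(i)
            used2.add(j)
            pairs.append((i, j))
    elif method == "optimal":
        rows, cols = linear_sum_assignment(D)
        pairs = sorted(zip(rows.tolist(), cols.tolist()))
    else:
        raise ValueError(f"unknown method {method!r}")

    distances = [float(D[i, j]) for i, j in pairs]
    if n1 >= n2:
        matched = {i for i, _ in pairs}
        unmatched = [i for i in range(n1) if i not in matched]
    else:
        matched = {j for _, j in pairs}
        unmatched = [j for j in range(n2) if j not in matched]
    return MatchResult(pairs=pairs, distances=distances, unmatched=unmatched)
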