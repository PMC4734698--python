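"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is a deliberately naive implementation (literal loops, full
enumeration) kept separate from the library code paths it checks.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from itertools import combinations

import numpy as np


def flood_fill_labels(mask: np.ndarray) -> np.ndarray:
    """BFS flood-fill labeling with 8-connectivity (raster-order seeds)."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                q = deque([(r0, c0)])
                labels[r0, c0] = nxt
                while q:
                    r, c = q.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h and 0 <= cc < w
                                and mask[rr, cc] and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = nxt
                                q.append((rr, cc))
    return labels


def partition_of(labels: np.ndarray) -> set[frozenset]:
    """Label raster -> set of pixel-index sets (label-renaming invariant)."""
    out: dict[int, set] = {}
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            lab = labels[r, c]
            if lab > 0:
                out.setdefault(int(lab), set()).add(r * w + c)
    return {frozenset(v) for v in out.values()}


def kmeans_objective_double_loop(points, centroids, assignment) -> float:
    total = 0.0
    for i in range(len(points)):
        c = centroids[assignment[i]]
        for d in range(len(points[i])):
            total += (points[i][d] - c[d]) ** 2
    return total


def entropy_of_counts(counts) -> float:
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            h -= (c / n) * math.log2(c / n)
    return h


def information_gain_direct(parent, left, right) -> float:
    pc, lc, rc = Counter(parent), Counter(left), Counter(right)
    n, nl, nr = sum(pc.values()), sum(lc.values()), sum(rc.values())
    return (
        entropy_of_counts(pc.values())
        - (nl / n) * entropy_of_counts(lc.values())
        - (nr / n) * entropy_of_counts(rc.values())
    )


def exhaustive_interval_gain(values, labels, candidates) -> float:
    """Best information gain over every (tau2, tau1) candidate pair."""
    best = 0.0
    values = list(values)
    labels = list(labels)
    for t2, t1 in combinations(sorted(candidates), 2):
        left = [l for v, l in zip(values, labels) if t2 < v < t1]
        right = [l for v, l in zip(values, labels) if not (t2 < v < t1)]
        if not left or not right:
            continue
        best = max(best, information_gain_direct(labels, left, right))
    return best


def gift_wrap_hull(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Jarvis march convex hull (counter-clockwise), O(n*h)."""
    pts = sorted(set(points))
    if len(pts) < 3:
        return pts
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
    hull = []
    start = min(pts)
    p = start
    while True:
        hull.append(p)
        q = pts[0] if pts[0] != p else pts[1]
        for r in pts:
            if r == p:
                continue
            c = cross(p, q, r)
            if c < 0 or (c == 0 and
                         (r[0] - p[0]) ** 2 + (r[1] - p[1]) ** 2
                         > (q[0] - p[0]) ** 2 + (q[1] - p[1]) ** 2):
                q = r
        p = q
        if p == start:
            break
    return hull


def shoelace_area(poly: list[tuple[float, float]]) -> float:
    n = len(poly)
    if n < 3:
        return 0.0
    s = 0.0
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def structure_features_brute(rows, cols, intensities):
    """Literal-loop re-derivation of the six structure features."""
    n = len(rows)
    area = n
    diameter = math.sqrt(4.0 * area / math.pi)
    rbar = sum(rows) / n
    cbar = sum(cols) / n
    crr = sum((r - rbar) ** 2 for r in rows) / n
    ccc = sum((c - cbar) ** 2 for c in cols) / n
    crc = sum((r - rbar) * (c - cbar) for r, c in zip(rows, cols)) / n
    half_tr = 0.5 * (crr + ccc)
    disc = max(half_tr**2 - (crr * ccc - crc**2), 0.0)
    l1 = half_tr + math.sqrt(disc)
    l2 = max(half_tr - math.sqrt(disc), 0.0)
    major, minor = 4 * math.sqrt(l1), 4 * math.sqrt(l2)
    aspect = max(1.0, major / max(minor, 1.0))
    corners = []
    for r, c in zip(rows, cols):
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                corners.append((r + dr, c + dc))
    hull_area = shoelace_area(gift_wrap_hull(corners))
    solidity = 1.0 if hull_area == 0 else min(1.0, area / hull_area)
    mean_intensity = sum(intensities) / n
    return {
        "area_px": area,
        "diameter_px": diameter,
        "length_px": major,
        "solidity": solidity,
        "aspect_ratio": aspect,
        "mean_intensity": mean_intensity,
    }


def random_polyomino(rng: np.random.Generator, n_px: int, size: int = 24):
    """Random connected pixel set grown by neighbor accretion."""
    pts = {(size // 2, size // 2)}
    while len(pts) < n_px:
        r, c = list(pts)[rng.integers(len(pts))]
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        rr, cc = int(np.clip(r + dr, 0, size - 1)), int(np.clip(c + dc, 0, size - 1))
        pts.add((rr, cc))
    return pts


def greedy_match_oracle(ious: dict[tuple[int, int], float], threshold: float):
    """Literal greedy bipartite matching: repeatedly take the best remaining
    pair (descending IoU, ties toward lower ids)."""
    pairs = sorted(
        ((iou, p, t) for (p, t), iou in ious.items() if iou >= threshold),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    used_p, used_t, out = set(), set(), {}
    for iou, p, t in pairs:
        if p in used_p or t in used_t:
            continue
        out[p] = t
        used_p.add(p)
        used_t.add(t)
    return out
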