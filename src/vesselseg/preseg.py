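"""Foreground/background pixel clustering of Gabor features via k-means.

Lloyd iteration minimizing the squared-error objective

    J = sum_j sum_{i in cluster j} || x_i - c_j ||^2

with assignment to the nearest centroid and centroid update as the barycenter
of members, iterated until no assignment changes. Feature channels are
z-scored before clustering (otherwise the low-frequency channels, whose
magnitudes are largest, dominate the metric). The foreground cluster is the
one whose centroid has the larger L2 norm in the raw magnitude space:
stained, textured structures respond more strongly across the bank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gabor import PixelFeatureStack
from .io import BinaryMask


@dataclass(frozen=True)
class KMeansResult:
    centroids: np.ndarray  # (k, d) in the clustered (standardized) space
    assignment: np.ndarray  # (n,) int
    objective_j: float
    n_iterations: int
    objective_history: tuple[float, ...]
    converged: bool


def kmeans_objective(
    points: np.ndarray, centroids: np.ndarray, assignment: np.ndarray
) -> float:
    """Squared-error objective J for a given clustering configuration."""
    points = np.asarray(points, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    assignment = np.asarray(assignment)
    if assignment.shape[0] != points.shape[0]:
        raise ValueError("assignment length must equal number of points")
    if assignment.size and assignment.max() >= centroids.shape[0]:
        raise ValueError("assignment refers to a missing centroid")
    diff = points - centroids[assignment]
    return float((diff * diff).sum())


def _standardize(points: np.ndarray) -> np.ndarray:
    mu = points.mean(axis=0)
    sd = points.std(axis=0)
    out = points - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def _farthest_point_init(points: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k-means++-style greedy seeding: random first center, then repeatedly
    the point farthest from the chosen set. Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    n = points.shape[0]
    centers = [int(rng.integers(n))]
    d2 = ((points - points[centers[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(nxt)
        d2 = np.minimum(d2, ((points - points[nxt]) ** 2).sum(axis=1))
    return points[centers].copy()


def _sq_dists(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # ||x||^2 - 2 x.c + ||c||^2 ; clip tiny negatives from cancellation
    d2 = (
        (points * points).sum(axis=1)[:, None]
        - 2.0 * points @ centroids.T
        + (centroids * centroids).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def fit_kmeans(
    features: PixelFeatureStack | np.ndarray,
    k: int = 2,
    init: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 300,
    standardize: bool = True,
) -> KMeansResult:
    """Cluster per-pixel feature vectors with Lloyd's algorithm.

    ``init`` may supply explicit starting centroids (k, d) — this is how
    supervised initialization from annotated exemplar pixels enters (see
    :func:`supervised_init`); otherwise farthest-point seeding from ``seed``
    is used. An emptied cluster is re-seeded at the point farthest from its
    assigned centroid. Raises if the data has fewer than ``k`` distinct
    feature vectors.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    points = (
        features.as_points() if isinstance(features, PixelFeatureStack) else np.asarray(features)
    ).astype(np.float64)
    if points.ndim != 2:
        raise ValueError("features must be 2-D (n_points, n_features)")
    if np.unique(points, axis=0).shape[0] < k:
        raise ValueError(f"need at least k={k} distinct feature vectors")
    work = _standardize(points) if standardize else points.copy()
    work = work.astype(np.float32)  # halves the Lloyd-iteration cost

    if init is not None:
        centroids = np.asarray(init).astype(work.dtype)
        if centroids.shape != (k, work.shape[1]):
            raise ValueError("init centroids must have shape (k, n_features)")
    else:
        centroids = _farthest_point_init(work, k, seed)

    assignment = np.full(work.shape[0], -1, dtype=np.int32)
    history: list[float] = []
    converged = False
    it = 0
    n = work.shape[0]
    rows = np.arange(n)
    x2 = (work * work).sum(axis=1)  # constant across iterations
    for it in range(1, max_iter + 1):
        d2 = np.maximum(
            x2[:, None] - 2.0 * work @ centroids.T
            + (centroids * centroids).sum(axis=1)[None, :],
            0.0,
        )
        new_assignment = np.argmin(d2, axis=1).astype(np.int32)
        # empty-cluster repair: relocate to the point farthest from its centroid
        for j in range(k):
            if not (new_assignment == j).any():
                worst = int(np.argmax(d2[rows, new_assignment]))
                centroids[j] = work[worst]
                d2[:, j] = np.maximum(
                    x2 - 2.0 * work @ centroids[j] + (centroids[j] ** 2).sum(), 0.0
                )
                new_assignment[worst] = j
        j_now = float(d2[rows, new_assignment].sum(dtype=np.float64))
        if history and j_now > history[-1] + 1e-6 * max(1.0, history[-1]):
            raise AssertionError("k-means objective increased between iterations")
        history.append(j_now)
        if (new_assignment == assignment).all():
            converged = True
            assignment = new_assignment
            break
        assignment = new_assignment
        for j in range(k):
            centroids[j] = work[assignment == j].mean(axis=0)
    if not converged:
        warnings.warn(f"k-means reached max_iter={max_iter} before convergence")
    # the in-loop J uses the expanded-form distances (fast but subject to
    # cancellation); report the final value from the exact difference form
    final_j = kmeans_objective(work, centroids, assignment)
    history[-1] = final_j
    return KMeansResult(
        centroids=centroids,
        assignment=assignment,
        objective_j=final_j,
        n_iterations=it,
        objective_history=tuple(history),
        converged=converged,
    )


def supervised_init(
    features: PixelFeatureStack | np.ndarray,
    foreground: np.ndarray,
    standardize: bool = True,
) -> np.ndarray:
    """Centroids from annotated exemplar pixels (mean feature vector of the
    annotated foreground and background sets), ordered (background, foreground).

    This is the supervision mechanism for seeding :func:`fit_kmeans` when a
    training annotation is available.
    """
    points = (
        features.as_points() if isinstance(features, PixelFeatureStack) else np.asarray(features)
    ).astype(np.float64)
    fg = np.asarray(foreground, dtype=bool).ravel()
    if fg.shape[0] != points.shape[0]:
        raise ValueError("annotation size does not match number of pixels")
    if not fg.any() or fg.all():
        raise ValueError("annotation must contain both foreground and background pixels")
    work = _standardize(points) if standardize else points
    return np.stack([work[~fg].mean(axis=0), work[fg].mean(axis=0)])


def stain_od(image, background_window_px: int = 31) -> np.ndarray:
    """Per-pixel optical density against a locally estimated background.

    Brightfield stain attenuates light multiplicatively, so staining is
    measured as OD = -log(I / I_background) with the background estimated
    by a median filter wide enough to span the stained structures (the
    median is computed on a 2x-decimated image for speed; at a 31 px
    window the approximation is negligible).
    """
    from scipy import ndimage

    px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    f = px.astype(np.float64) / 65535.0
    small = f[::2, ::2]
    med = ndimage.median_filter(small, size=max(3, (background_window_px // 2) | 1))
    bg = ndimage.zoom(med, (f.shape[0] / small.shape[0], f.shape[1] / small.shape[1]),
                      order=1, grid_mode=True, mode="nearest")
    return -np.log(np.maximum(f, 1e-3) / np.maximum(bg, 1e-3))


def stain_gate(
    image, od_threshold: float = 0.10, background_window_px: int = 31,
    od: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of pixels whose optical density exceeds a threshold.

    Used to refine the k-means foreground to stain-dark pixels, which trims
    the bright response halo that texture filtering spreads around
    structures. A precomputed ``od`` map may be passed to avoid recomputing
    the background estimate.
    """
    if od is None:
        od = stain_od(image, background_window_px)
    return od > od_threshold


def refine_mask(
    mask: BinaryMask,
    image,
    od_threshold: float = 0.10,
    strong_od_threshold: float = 0.22,
    background_window_px: int = 31,
    fill_holes: bool = True,
    od: np.ndarray | None = None,
) -> BinaryMask:
    """Post-process the k-means foreground with the stain gate.

    Keeps foreground pixels that are at least weakly stained (trimming the
    bright response halo that texture filtering spreads around structures),
    always keeps deeply stained pixels even if the clustering missed them
    (flat interiors of wide structures respond only at their edges), and
    finally fills fully enclosed holes.
    """
    from scipy import ndimage

    if od is None:
        od = stain_od(image, background_window_px)
    weak = od > od_threshold
    strong = od > strong_od_threshold
    out = (mask.pixels & weak) | strong
    if fill_holes:
        out = ndimage.binary_fill_holes(out)
    return BinaryMask(out)


def select_foreground(
    result: KMeansResult, features: PixelFeatureStack
) -> BinaryMask:
    """Pick the foreground cluster (k=2) and return its pixel mask.

    The foreground cluster is the one whose centroid has the larger L2 norm
    in raw Gabor-magnitude space; an exact tie breaks toward cluster 0 with a
    warning. Invariant to swapping the two cluster indices.
    """
    if result.centroids.shape[0] != 2:
        raise ValueError("select_foreground requires k=2")
    raw = features.as_points().astype(np.float64)
    norms = np.empty(2)
    for j in range(2):
        members = raw[result.assignment == j]
        norms[j] = np.linalg.norm(members.mean(axis=0)) if members.size else 0.0
    if norms[0] == norms[1]:
        warnings.warn("centroid norms tie exactly; selecting cluster 0 as foreground")
        fg = 0
    else:
        fg = int(np.argmax(norms))
    h, w, _ = features.values.shape
    mask = (result.assignment == fg).reshape(h, w)
    return BinaryMask(mask)
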