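"""Hierarchical clustering of pixel fingerprints into tissue clusters.

Vector-normalized fingerprint spectra (1800-800 cm^-1) of unmasked
pixels are clustered with agglomerative linkage (Ward + Euclidean by
default, the standard choice for spectral histology) into a fixed
number of clusters k — the study design chose k = 7, corresponding to
epidermis, shoot cortex, root cap, meristematic tip, vasculature, root
cortex, and pith + vascular ring. Above ``max_pixels`` a seeded uniform
subsample is clustered and remaining pixels are assigned to the nearest
cluster centroid. Labels are renumbered by descending cluster area;
label 0 marks masked pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .io_spectra import HyperCube, truncate_range

__all__ = ["ClusterResult", "extract_fingerprints", "hcluster", "cluster_cube", "cluster_mask"]

_LINKAGES = ("ward", "average", "complete")


def extract_fingerprints(
    cube: HyperCube, lo: float = 800.0, hi: float = 1800.0
) -> np.ndarray:
    """Unmasked pixel spectra restricted to [lo, hi], row-major order."""
    if not cube.mask.any():
        raise ValueError("empty mask: no pixels to extract")
    return truncate_range(cube, lo, hi).masked_spectra()


def hcluster(
    fingerprints: np.ndarray,
    k: int,
    linkage: str = "ward",
    max_pixels: int = 20000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Cluster fingerprint rows into k groups.

    Returns (labels in 1..k renumbered by descending cluster size,
    linkage matrix — computed on the seeded subsample when n exceeds
    ``max_pixels``). Deterministic given the seed.
    """
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2:
        raise ValueError("fingerprints must be 2-D")
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds pixel count {n}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")

    if n > max_pixels:
        rng = np.random.default_rng(seed)
        subset = np.sort(rng.choice(n, size=max_pixels, replace=False))
        Z = hierarchy.linkage(X[subset], method=linkage)
        sub_labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        centroids = np.stack(
            [X[subset][sub_labels == c].mean(axis=0) for c in range(1, k + 1)]
        )
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1) + 1
        labels[subset] = sub_labels
    else:
        Z = hierarchy.linkage(X, method=linkage)
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    # Renumber by descending area for stable, comparable ids.
    counts = np.bincount(labels, minlength=k + 1)[1:]
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k + 1, dtype=int)
    remap[0] = 0
    for new, old in enumerate(order, start=1):
        remap[old + 1] = new
    return remap[labels], Z


@dataclass
class ClusterResult:
    """Label image plus per-cluster summaries for one cube."""

    labels: np.ndarray  # rows x cols, 0 = masked, 1..k otherwise
    k: int
    linkage_tree: np.ndarray | None
    cluster_mean_spectra: np.ndarray  # k x n_channels (fingerprint range)
    cluster_areas: np.ndarray  # k pixel counts
    pixel_size_um: float

    def __post_init__(self) -> None:
        unmasked = self.labels[self.labels > 0]
        if unmasked.size and (unmasked.min() < 1 or unmasked.max() > self.k):
            raise ValueError("labels outside 1..k")
        if int(self.cluster_areas.sum()) != int((self.labels > 0).sum()):
            raise ValueError("cluster areas do not sum to unmasked pixel count")

    def area_um2(self, cluster: int) -> float:
        return float(self.cluster_areas[cluster - 1]) * self.pixel_size_um**2


def _result_from_labels(
    cube: HyperCube, fp: np.ndarray, flat_labels: np.ndarray, k: int, Z
) -> ClusterResult:
    labels = np.zeros(cube.mask.shape, dtype=int)
    labels[cube.mask] = flat_labels
    areas = np.bincount(flat_labels, minlength=k + 1)[1:]
    means = np.full((k, fp.shape[1]), np.nan)
    for c in range(1, k + 1):
        member = flat_labels == c
        if member.any():
            means[c - 1] = fp[member].mean(axis=0)
    return ClusterResult(labels, k, Z, means, areas, cube.pixel_size_um)


def cluster_cube(
    cubes: HyperCube | list[HyperCube],
    k: int,
    linkage: str = "ward",
    max_pixels: int = 20000,
    seed: int = 0,
    lo: float = 800.0,
    hi: float = 1800.0,
) -> ClusterResult | list[ClusterResult]:
    """Cluster one cube, or several jointly under a shared cluster scheme.

    Joint clustering concatenates the unmasked fingerprints of all cubes
    before linkage so cluster ids are comparable across genotypes, then
    splits the labels back per cube. Returns one ClusterResult per input.
    """
    single = isinstance(cubes, HyperCube)
    cube_list = [cubes] if single else list(cubes)
    fps = [extract_fingerprints(c, lo, hi) for c in cube_list]
    joint = np.vstack(fps)
    flat, Z = hcluster(joint, k=k, linkage=linkage, max_pixels=max_pixels, seed=seed)
    results = []
    start = 0
    for cube, fp in zip(cube_list, fps):
        stop = start + fp.shape[0]
        results.append(_result_from_labels(cube, fp, flat[start:stop], k, Z))
        start = stop
    return results[0] if single else results


def cluster_mask(result: ClusterResult, clusters: set[int]) -> np.ndarray:
    """Boolean image true exactly where the label is in ``clusters``."""
    bad = set(clusters) - set(range(1, result.k + 1))
    if bad:
        raise ValueError(f"unknown cluster ids {sorted(bad)}")
    return np.isin(result.labels, sorted(clusters))
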