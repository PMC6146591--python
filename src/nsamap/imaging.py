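"""Single-cell FISH / SC35 colocalization analysis on 3D two-channel stacks.

A stack holds a FISH channel, an SC35 (speckle marker) channel and a binary
nucleus mask on one (z, y, x) voxel grid.  Both channels are binarized by
Otsu's threshold computed over voxels inside the nucleus (a fixed threshold
can be supplied instead), followed by 3D connected-component labelling with
26-connectivity.

Colocalization uses the conservative pixel-overlap rule: a FISH spot is
*isolated* only when none of its voxels carries SC35 signal; a single
SC35-positive voxel makes it colocalized.  Distances are center-to-center
Euclidean distances in voxel units (voxel anisotropy is metadata only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

log = logging.getLogger(__name__)


@dataclass
class ImageStack:
    """3D two-channel voxel grid with a nucleus mask.

    ``fish`` and ``sc35`` are (z, y, x) float arrays; ``mask`` is boolean on
    the same grid; ``voxel_size`` (z, y, x in um) is metadata only.
    """

    fish: np.ndarray
    sc35: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if not (self.fish.shape == self.sc35.shape == self.mask.shape):
            raise ValueError("channels and mask must share dimensions")
        if self.fish.ndim != 3:
            raise ValueError("expected 3D (z, y, x) stacks")
        self.mask = self.mask.astype(bool)

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"fish": self.fish, "sc35": self.sc35}[name]
        except KeyError:
            raise ValueError(f"unknown channel {name!r}") from None


@dataclass(frozen=True)
class Spot:
    """A 26-connected component: voxel coordinates, centroid, intensity."""

    id: int
    voxels: np.ndarray  # (n, 3) int array of (z, y, x)
    centroid: tuple[float, float, float]
    total_intensity: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class ClusterSet:
    """Labelled SC35 components with centroids."""

    clusters: list[Spot]

    @property
    def count(self) -> int:
        return len(self.clusters)

    @property
    def centroids(self) -> np.ndarray:
        if not self.clusters:
            return np.empty((0, 3))
        return np.array([c.centroid for c in self.clusters])


@dataclass
class ColocResult:
    """Per-spot colocalization flags and distances for one image."""

    flags: list[bool]
    distances: np.ndarray  # per-spot nearest-cluster center distance, voxels

    @property
    def fraction(self) -> float:
        if not self.flags:
            raise ValueError("no spots in image")
        return sum(self.flags) / len(self.flags)


# ---------------------------------------------------------------------------
# segmentation


def binarize(
    image: np.ndarray,
    mask: np.ndarray,
    threshold_method: Union[str, float] = "otsu",
) -> np.ndarray:
    """Binary foreground inside the nucleus mask.

    ``threshold_method`` is ``"otsu"`` (computed over in-mask voxels) or a
    fixed numeric threshold.  Otsu on rescaled data yields the same
    binarization, so segmentation is invariant to positive intensity
    scaling.
    """
    if not mask.any():
        raise ValueError("empty nucleus mask")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        inside = image[mask]
        if np.ptp(inside) == 0:
            return np.zeros_like(mask, dtype=bool)
        thr = threshold_otsu(inside)
    else:
        thr = float(threshold_method)
    return (image > thr) & mask


def _components(
    image: np.ndarray,
    binary: np.ndarray,
    min_voxels: int,
) -> list[Spot]:
    labels = cc_label(binary, connectivity=3)  # 26-connectivity in 3D
    spots: list[Spot] = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_voxels:
            continue
        weights = image[tuple(coords.T)].astype(float)
        total = float(weights.sum())
        centroid = tuple(
            float(x) for x in (coords * weights[:, None]).sum(axis=0) / total
        )
        spots.append(
            Spot(
                id=len(spots),
                voxels=coords,
                centroid=centroid,
                total_intensity=total,
            )
        )
    return spots


def detect_spots(
    stack: ImageStack,
    channel: str = "fish",
    threshold_method: Union[str, float] = "otsu",
    min_voxels: int = 2,
) -> list[Spot]:
    """Threshold within the nucleus, then 3D connected components.

    Components smaller than ``min_voxels`` are discarded.  Deterministic:
    the same stack always yields the same spot list.
    """
    image = stack.channel(channel)
    binary = binarize(image, stack.mask, threshold_method)
    return _components(image, binary, min_voxels)


def segment_clusters(
    stack: ImageStack,
    channel: str = "sc35",
    threshold_method: Union[str, float] = "otsu",
    min_voxels: int = 2,
) -> ClusterSet:
    """SC35 cluster segmentation (shared machinery with spot detection)."""
    return ClusterSet(detect_spots(stack, channel, threshold_method, min_voxels))


def sc35_mask(
    stack: ImageStack, threshold_method: Union[str, float] = "otsu"
) -> np.ndarray:
    """Binary SC35-positive mask inside the nucleus."""
    return binarize(stack.sc35, stack.mask, threshold_method)


# ---------------------------------------------------------------------------
# colocalization


def call_colocalization(spot: Spot, sc35_binary_mask: np.ndarray) -> bool:
    """Conservative pixel-overlap rule.

    A spot is isolated only when zero of its voxels are SC35-positive;
    otherwise it is colocalized.
    """
    return bool(sc35_binary_mask[tuple(spot.voxels.T)].any())


def image_summary(flags: Sequence[bool]) -> float:
    """Fraction of colocalized spots in one image (>= 1 spot required)."""
    if len(flags) == 0:
        raise ValueError("image without spots; exclude it upstream")
    return sum(bool(f) for f in flags) / len(flags)


def summarize_images(per_image_flags: Sequence[Sequence[bool]]) -> list[float]:
    """Per-image colocalized fractions; spotless images are excluded."""
    out = []
    for i, flags in enumerate(per_image_flags):
        if len(flags) == 0:
            log.warning("image %d has no FISH spots; excluded", i)
            continue
        out.append(image_summary(flags))
    return out


def nearest_cluster_distances(
    spots: Sequence[Spot], clusters: ClusterSet
) -> np.ndarray:
    """3D center-to-center distance (voxels) to the nearest SC35 cluster."""
    if clusters.count == 0:
        raise ValueError("no SC35 clusters; distances undefined")
    if len(spots) == 0:
        return np.empty(0)
    sc = np.array([s.centroid for s in spots])
    cc = clusters.centroids
    diff = sc[:, None, :] - cc[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def distance_histogram(
    distances: Sequence[float], max_bin: int = 10
) -> tuple[np.ndarray, int]:
    """Counts at integer distances 1..max_bin.

    Bin ``d`` holds distances in (d-1, d]; a distance of exactly 0 falls in
    bin 1.  Distances beyond ``max_bin`` go to the overflow count, so bins
    plus overflow conserve the sample size.
    """
    counts = np.zeros(max_bin, dtype=int)
    overflow = 0
    for d in distances:
        if d < 0:
            raise ValueError("negative distance")
        b = max(1, int(np.ceil(d)))
        if b > max_bin:
            overflow += 1
        else:
            counts[b - 1] += 1
    return counts, overflow


def analyze_stack(
    stack: ImageStack,
    threshold_method: Union[str, float] = "otsu",
    min_spot_voxels: int = 2,
    min_cluster_voxels: int = 2,
) -> tuple[list[Spot], ClusterSet, ColocResult]:
    """Full per-image analysis: spots, clusters, colocalization, distances."""
    spots = detect_spots(stack, "fish", threshold_method, min_spot_voxels)
    clusters = segment_clusters(stack, "sc35", threshold_method, min_cluster_voxels)
    mask = sc35_mask(stack, threshold_method)
    flags = [call_colocalization(s, mask) for s in spots]
    if clusters.count and spots:
        dists = nearest_cluster_distances(spots, clusters)
    else:
        dists = np.full(len(spots), np.nan)
    return spots, clusters, ColocResult(flags=flags, distances=dists)


# ---------------------------------------------------------------------------
# group comparison


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float], test: str = "t"
) -> tuple[float, float]:
    """Two-group comparison of per-image fractions or pooled distances.

    ``test="t"`` is Welch's t-test (errors when both groups are constant);
    ``test="ks"`` is the two-sample Kolmogorov-Smirnov test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    if test == "t":
        if a.std() == 0 and b.std() == 0:
            raise ValueError("degenerate zero-variance groups; t-test undefined")
        res = sps.ttest_ind(a, b, equal_var=False)
    elif test == "ks":
        res = sps.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# TIFF IO


def read_stack(fish_path, sc35_path, mask_path) -> ImageStack:
    """Read per-channel multi-page TIFF z-stacks into an :class:`ImageStack`."""
    import tifffile

    fish = tifffile.imread(fish_path).astype(float)
    sc35 = tifffile.imread(sc35_path).astype(float)
    mask = tifffile.imread(mask_path) > 0
    return ImageStack(fish=fish, sc35=sc35, mask=mask)


def write_stack(stack: ImageStack, fish_path, sc35_path, mask_path) -> None:
    import tifffile

    tifffile.imwrite(fish_path, stack.fish.astype(np.float32))
    tifffile.imwrite(sc35_path, stack.sc35.astype(np.float32))
    tifffile.imwrite(mask_path, stack.mask.astype(np.uint8))
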