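"""Spatial statistics for single-molecule localization (STORM) data.

Localization lists (x, y in nm, one per nucleus and channel) are clustered
by density-based clustering; nearest-neighbour distances (NND) between
cluster centroids — within one channel or across two channels — are
histogrammed from 0 to 500 nm in 5 nm steps and compared against a
complete-spatial-randomness (CSR) null simulated per nucleus at matched
centroid count inside the nuclear mask. Mask-based enrichment is quantified
as the ratio of localization densities inside vs outside a signal mask
(e.g. the S9.6 RNA:DNA-hybrid mask); a ratio above 1 is enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

NND_BIN_EDGES = np.arange(0, 505, 5, dtype=float)  # 0..500 nm, 5 nm steps


@dataclass
class MaskRaster:
    """Binary raster mask with physical pixel size in nm. ``role`` is
    ``nuclear`` or ``s96``."""

    grid: np.ndarray
    pixel_size: float
    role: str = "nuclear"

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def area_um2(self) -> float:
        """Pixel count times pixel area."""
        return float(self.grid.sum()) * (self.pixel_size / 1000.0) ** 2

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (n, 2) nm coordinates; x maps to columns,
        y to rows."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        col = np.floor(points[:, 0] / self.pixel_size).astype(int)
        row = np.floor(points[:, 1] / self.pixel_size).astype(int)
        inside = (
            (row >= 0) & (row < self.grid.shape[0])
            & (col >= 0) & (col < self.grid.shape[1])
        )
        out = np.zeros(len(points), dtype=bool)
        out[inside] = self.grid[row[inside], col[inside]]
        return out

    def difference(self, other: "MaskRaster") -> "MaskRaster":
        if self.grid.shape != other.grid.shape or self.pixel_size != other.pixel_size:
            raise ValueError("masks must share a raster")
        return MaskRaster(self.grid & ~other.grid, self.pixel_size, role="difference")


def disc_mask(radius_nm: float, pixel_size: float = 20.0,
              role: str = "nuclear") -> MaskRaster:
    """Disc of the given radius, rasterized with the disc centre at the
    raster centre."""
    n = int(np.ceil(2 * radius_nm / pixel_size)) + 2
    centers = (np.arange(n) + 0.5) * pixel_size
    cx = cy = n * pixel_size / 2
    xx, yy = np.meshgrid(centers, centers)
    grid = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_nm**2
    return MaskRaster(grid, pixel_size, role=role)


@dataclass
class PointPattern:
    nucleus_id: str
    channel: str
    points: np.ndarray  # (n, 2) in nm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("localization coordinates must be finite")


@dataclass
class ClusterSet:
    nucleus_id: str
    channel: str
    centroids: np.ndarray  # (n, 2) in nm
    sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.sizes = np.asarray(self.sizes, dtype=int)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class NNDHistogram:
    """NND probability mass over 0-500 nm in 5 nm bins. Distances beyond
    500 nm are excluded from the normalisation and counted in
    ``n_overflow``."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_total: int
    n_overflow: int


@dataclass(frozen=True)
class MaskRatioResult:
    nucleus_id: str
    density_in: float  # localizations per um^2
    density_out: float
    ratio: float  # inf flagged when density_out == 0


def identify_clusters(points: PointPattern, eps: float = 50.0,
                      min_pts: int = 10) -> ClusterSet:
    """Density-based clustering of localizations (DBSCAN with ``eps`` nm
    neighbourhoods and ``min_pts`` core size); cluster centroid = unweighted
    mean of member coordinates, unclustered points are noise."""
    if eps <= 0 or min_pts < 2:
        raise ValueError("need eps > 0 and min_pts >= 2")
    if len(points.points) == 0:
        return ClusterSet(points.nucleus_id, points.channel, np.empty((0, 2)))
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points.points)
    ids = np.unique(labels[labels >= 0])
    centroids = np.array([points.points[labels == i].mean(axis=0) for i in ids]
                         ).reshape(-1, 2)
    sizes = np.array([(labels == i).sum() for i in ids], dtype=int)
    return ClusterSet(points.nucleus_id, points.channel, centroids, sizes)


def localization_density(points: PointPattern, mask: MaskRaster) -> float:
    """Localizations inside the mask per um^2 of mask area."""
    area = mask.area_um2
    if area == 0:
        raise ValueError("zero-area mask")
    return float(mask.contains(points.points).sum()) / area


def nearest_neighbor_distances(query: ClusterSet,
                               reference: ClusterSet | None = None) -> np.ndarray:
    """One NND (nm) per query centroid.

    Self mode (``reference`` is None): nearest other centroid in the same
    set, excluding only the self-match by index — genuine zero distances
    between duplicate centroids are kept. Cross mode: nearest reference
    centroid, exact coordinate matches included.
    """
    q = query.centroids
    if reference is None:
        if len(q) < 2:
            raise ValueError("self-mode NND needs >= 2 centroids")
        tree = cKDTree(q)
        dist, idx = tree.query(q, k=2)
        # take the first neighbour that is not the point itself
        take_second = idx[:, 0] == np.arange(len(q))
        return np.where(take_second, dist[:, 1], dist[:, 0])
    if len(reference.centroids) < 1:
        raise ValueError("cross-mode NND needs >= 1 reference centroid")
    dist, _ = cKDTree(reference.centroids).query(q, k=1)
    return np.asarray(dist, dtype=float)


def nnd_histogram(nnds, null: NNDHistogram | None = None,
                  ) -> NNDHistogram | tuple[NNDHistogram, np.ndarray]:
    """Histogram NNDs into the 0-500 nm / 5 nm grid, normalised to
    probability mass over in-range bins; with a null, also return the
    per-bin difference curve (experimental minus null frequencies)."""
    nnds = np.asarray(list(nnds), dtype=float)
    if np.any(~np.isfinite(nnds)) or np.any(nnds < 0):
        raise ValueError("NNDs must be finite and non-negative")
    counts, _ = np.histogram(nnds, bins=NND_BIN_EDGES)
    n_total = len(nnds)
    n_overflow = int((nnds >= NND_BIN_EDGES[-1]).sum())
    in_range = n_total - n_overflow
    freqs = counts / in_range if in_range else counts.astype(float)
    hist = NNDHistogram(NND_BIN_EDGES.copy(), freqs, n_total, n_overflow)
    if null is None:
        return hist
    return hist, hist.frequencies - null.frequencies


def sample_uniform_in_mask(mask: MaskRaster, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """n points uniform over the mask area: a uniformly chosen true pixel
    plus a uniform offset within the pixel (rejection sampling at raster
    resolution)."""
    rows, cols = np.nonzero(mask.grid)
    if len(rows) == 0:
        raise ValueError("cannot sample from an empty mask")
    pick = rng.integers(0, len(rows), size=n)
    offsets = rng.random((n, 2))
    x = (cols[pick] + offsets[:, 0]) * mask.pixel_size
    y = (rows[pick] + offsets[:, 1]) * mask.pixel_size
    return np.column_stack([x, y])


def csr_null(cluster_set: ClusterSet, nuclear_mask: MaskRaster,
             n_reps: int = 10, seed: int | np.random.Generator = 0,
             reference_set: ClusterSet | None = None) -> NNDHistogram:
    """Simulated-random NND null for one nucleus.

    Per replicate, the same number of centroids as observed is placed
    uniformly inside the nuclear mask (and likewise for the reference set in
    cross mode); NNDs are computed in the matching mode and the replicate
    histograms averaged into one normalised histogram.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs, totals, overflows = [], 0, 0
    for _ in range(n_reps):
        sim_q = ClusterSet(
            cluster_set.nucleus_id, cluster_set.channel,
            sample_uniform_in_mask(nuclear_mask, len(cluster_set), rng),
        )
        sim_ref = None
        if reference_set is not None:
            sim_ref = ClusterSet(
                reference_set.nucleus_id, reference_set.channel,
                sample_uniform_in_mask(nuclear_mask, len(reference_set), rng),
            )
        hist = nnd_histogram(nearest_neighbor_distances(sim_q, sim_ref))
        freqs.append(hist.frequencies)
        totals += hist.n_total
        overflows += hist.n_overflow
    return NNDHistogram(NND_BIN_EDGES.copy(), np.mean(freqs, axis=0),
                        totals, overflows)


def mask_density_ratio(points: PointPattern, s96: MaskRaster,
                       nuclear: MaskRaster) -> MaskRatioResult:
    """Density of localizations inside the signal mask over the density in
    the rest of the nucleus."""
    outside = nuclear.difference(s96)
    area_in, area_out = s96.area_um2, outside.area_um2
    if area_in == 0 or area_out == 0:
        raise ValueError("both mask regions must have positive area")
    density_in = float(s96.contains(points.points).sum()) / area_in
    density_out = float(outside.contains(points.points).sum()) / area_out
    if density_out == 0:
        ratio = np.inf if density_in > 0 else np.nan
    else:
        ratio = density_in / density_out
    return MaskRatioResult(points.nucleus_id, density_in, density_out, ratio)
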