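"""Hi-C contact-hotspot detection and aggregate enrichment grids.

A hotspot is a connected cluster of high-scoring, long-range contacts. The
caller subsets score-annotated intra-chromosomal contacts to score >= 60
within a separation band of 10 kb - 70 Mb, links each retained contact to
its k nearest neighbours (Euclidean distance in the (pos1, pos2) plane,
k = 250 by default), and takes connected components of the resulting
undirected graph; components smaller than 100 members are dropped. Each
hotspot is summarised by its score-weighted centre and 2D bounding box.

Aggregate grids pool observed contact counts and distance-decay expected
mass over windows (+/- 250 kb, 1 kb bins) around all pairs of hotspot
centre projections whose separation falls in a requested band; windows
without any score >= 60 contact are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

CONTACT_COLUMNS = ("chrom", "pos1", "pos2", "score")


@dataclass(frozen=True)
class HotspotParams:
    """Caller thresholds: the contact score cut (score_min), the separation
    band in bp, the neighbour count k and the minimum component size."""

    score_min: float = 60.0
    band_min: float = 1e4
    band_max: float = 7e7
    k_neighbors: int = 250
    min_members: int = 100
    # Neighbour search runs within the already-filtered high-scoring set by
    # default; search_all searches among all band-contacts and then subsets
    # the neighbours to high-scorers.
    search_all: bool = False
    # Union-kNN by default; mutual requires both directions.
    mutual: bool = False
    # Component size counted in member contacts by default; "fends" counts
    # distinct fragment-end coordinates instead.
    count_mode: str = "contacts"
    # Optional maximum neighbour distance (bp in the contact plane).
    d_max: float | None = None

    def __post_init__(self):
        if not self.band_min < self.band_max:
            raise ValueError("band_min must be below band_max")
        if self.k_neighbors < 1 or self.min_members < 1:
            raise ValueError("k_neighbors and min_members must be >= 1")
        if self.count_mode not in ("contacts", "fends"):
            raise ValueError("count_mode must be 'contacts' or 'fends'")


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    member_ids: np.ndarray
    n_members: int
    weighted_centre: tuple[float, float]
    extent: tuple[float, float, float, float]  # (min1, max1, min2, max2)


@dataclass(frozen=True)
class AggregateGrid:
    band: tuple[float, float]
    half_window: float
    bin_size: float
    observed: np.ndarray
    expected: np.ndarray
    n_windows: int

    def enrichment(self) -> np.ndarray:
        return np.log2((self.observed + 1) / (self.expected + 1))


def _check_single_chrom(contacts: pd.DataFrame) -> None:
    chroms = contacts["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"expected one chromosome per call, got {list(chroms)}")


def filter_contacts(contacts: pd.DataFrame,
                    params: HotspotParams = HotspotParams()) -> pd.DataFrame:
    """Contacts with score >= score_min and band_min <= pos2 - pos1 <=
    band_max (inclusive boundaries); input order preserved."""
    _check_single_chrom(contacts)
    sep = contacts["pos2"] - contacts["pos1"]
    keep = (
        (contacts["score"] >= params.score_min)
        & (sep >= params.band_min)
        & (sep <= params.band_max)
    )
    return contacts.loc[keep]


def knn_edges(positions: np.ndarray, k_neighbors: int,
              d_max: float | None = None) -> np.ndarray:
    """Undirected, deduplicated kNN edges over contact indices.

    Each contact contributes edges to its k nearest neighbours in the
    (pos1, pos2) plane; the self-match at distance zero is discarded by
    index, so zero-distance edges between distinct duplicate contacts
    survive. k >= n is clamped to n - 1 with a warning.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(positions)
    if n < 2:
        raise ValueError("need at least 2 contacts for neighbour search")
    if k_neighbors >= n:
        warnings.warn(f"k={k_neighbors} >= n={n}; clamping to {n - 1}", stacklevel=2)
        k_neighbors = n - 1
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(positions)
    dist, idx = nn.kneighbors(positions)
    edges = set()
    for i in range(n):
        neighbours = [(j, d) for j, d in zip(idx[i], dist[i]) if j != i]
        for j, d in neighbours[:k_neighbors]:
            if d_max is not None and d > d_max:
                continue
            edges.add((min(i, j), max(i, j)))
    return np.array(sorted(edges), dtype=int).reshape(-1, 2)


def _mutual_edges(positions: np.ndarray, k_neighbors: int,
                  d_max: float | None) -> np.ndarray:
    """Mutual-kNN variant: an edge requires each endpoint among the other's
    k nearest neighbours."""
    directed = set()
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(positions)
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(positions)
    dist, idx = nn.kneighbors(positions)
    for i in range(n):
        neighbours = [(j, d) for j, d in zip(idx[i], dist[i]) if j != i][:k]
        for j, d in neighbours:
            if d_max is None or d <= d_max:
                directed.add((i, j))
    return np.array(
        sorted((i, j) for i, j in directed if i < j and (j, i) in directed),
        dtype=int,
    ).reshape(-1, 2)


def call_hotspots(contacts: pd.DataFrame,
                  params: HotspotParams = HotspotParams()) -> list[Hotspot]:
    """Connected components of the kNN graph over filtered contacts.

    Components with fewer than min_members members are dropped; the
    weighted centre is the score-weighted mean of member (pos1, pos2), the
    extent their bounding box. Output sorted by chromosome then centre.
    """
    _check_single_chrom(contacts)
    filtered = filter_contacts(contacts, params)
    if len(filtered) == 0:
        return []
    chrom = str(filtered["chrom"].iloc[0])
    if params.search_all:
        band_params = HotspotParams(
            score_min=-np.inf, band_min=params.band_min, band_max=params.band_max,
            k_neighbors=params.k_neighbors, min_members=params.min_members,
        )
        pool = filter_contacts(contacts, band_params)
        high = (pool["score"] >= params.score_min).to_numpy()
        pool_pos = pool[["pos1", "pos2"]].to_numpy(dtype=float)
        edge_fn = _mutual_edges if params.mutual else knn_edges
        raw = edge_fn(pool_pos, params.k_neighbors, params.d_max) \
            if len(pool) > 1 else np.empty((0, 2), dtype=int)
        # keep only edges whose both endpoints are high-scoring, then
        # reindex into the filtered (high-scoring) frame
        remap = -np.ones(len(pool), dtype=int)
        remap[high] = np.arange(high.sum())
        edges = np.array(
            [(remap[i], remap[j]) for i, j in raw if high[i] and high[j]],
            dtype=int,
        ).reshape(-1, 2)
    else:
        pos = filtered[["pos1", "pos2"]].to_numpy(dtype=float)
        if len(pos) == 1:
            edges = np.empty((0, 2), dtype=int)
        else:
            edge_fn = _mutual_edges if params.mutual else knn_edges
            edges = edge_fn(pos, params.k_neighbors, params.d_max)

    n = len(filtered)
    if len(edges):
        adj = coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)

    pos1 = filtered["pos1"].to_numpy(dtype=float)
    pos2 = filtered["pos2"].to_numpy(dtype=float)
    score = filtered["score"].to_numpy(dtype=float)
    index = filtered.index.to_numpy()
    hotspots = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if params.count_mode == "fends":
            size = len(np.unique(np.concatenate([pos1[members], pos2[members]])))
        else:
            size = len(members)
        if size < params.min_members:
            continue
        w = score[members]
        c1 = float(np.average(pos1[members], weights=w))
        c2 = float(np.average(pos2[members], weights=w))
        hotspots.append(
            Hotspot(
                chrom=chrom,
                member_ids=index[members],
                n_members=len(members),
                weighted_centre=(c1, c2),
                extent=(
                    float(pos1[members].min()), float(pos1[members].max()),
                    float(pos2[members].min()), float(pos2[members].max()),
                ),
            )
        )
    hotspots.sort(key=lambda h: (h.chrom, h.weighted_centre[0]))
    return hotspots


def distance_decay_expected(contacts: pd.DataFrame, bin_size: float,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical expected contact frequency by separation bin.

    Returns (bin_edges, expected_counts): the separation histogram itself,
    so expected mass is proportional to the genome-wide separation density
    and sums to the total observed contact count.
    """
    if len(contacts) == 0:
        raise ValueError("need at least one contact")
    sep = (contacts["pos2"] - contacts["pos1"]).to_numpy(dtype=float)
    n_bins = int(np.floor(sep.max() / bin_size)) + 1
    edges = np.arange(n_bins + 1) * bin_size
    counts, _ = np.histogram(sep, bins=edges)
    return edges, counts.astype(float)


def aggregate_grid(contacts: pd.DataFrame, centres: np.ndarray,
                   band: tuple[float, float],
                   half_window: float = 250_000.0, bin_size: float = 1000.0,
                   score_min: float = 60.0) -> AggregateGrid:
    """Observed/expected pileup over windows around centre pairs.

    Windows are all unordered centre pairs (a, b), a < b, with separation
    inside ``band``, spanning [a +/- half_window] x [b +/- half_window] and
    split into ``bin_size`` bins; windows lacking any contact of score >=
    ``score_min`` are discarded. Expected mass per window follows the
    empirical distance-decay separation density of all supplied contacts,
    normalised to the window's observed contact count.
    """
    centres = np.sort(np.asarray(centres, dtype=float))
    if len(centres) == 0:
        raise ValueError("centres must be non-empty")
    side = int(round(2 * half_window / bin_size))
    observed = np.zeros((side, side))
    expected = np.zeros((side, side))

    edges, decay = distance_decay_expected(contacts, bin_size)
    decay_density = decay / decay.sum()

    pos1 = contacts["pos1"].to_numpy(dtype=float)
    pos2 = contacts["pos2"].to_numpy(dtype=float)
    score = contacts["score"].to_numpy(dtype=float)

    n_windows = 0
    for ai in range(len(centres)):
        for bi in range(ai + 1, len(centres)):
            a, b = centres[ai], centres[bi]
            if not band[0] <= b - a <= band[1]:
                continue
            in_win = (
                (pos1 >= a - half_window) & (pos1 < a + half_window)
                & (pos2 >= b - half_window) & (pos2 < b + half_window)
            )
            if not np.any(score[in_win] >= score_min):
                continue
            n_windows += 1
            i_bins = ((pos1[in_win] - (a - half_window)) // bin_size).astype(int)
            j_bins = ((pos2[in_win] - (b - half_window)) // bin_size).astype(int)
            np.add.at(observed, (i_bins, j_bins), 1.0)
            # expected: distance-decay density at each bin's separation,
            # normalised to the window's observed total
            offsets = (np.arange(side) + 0.5) * bin_size
            sep_grid = (b - half_window + offsets)[None, :] - \
                       (a - half_window + offsets)[:, None]
            sep_idx = np.clip((sep_grid // bin_size).astype(int), 0, len(decay_density) - 1)
            win_exp = decay_density[sep_idx]
            win_exp[sep_grid <= 0] = 0.0
            total = win_exp.sum()
            if total > 0:
                win_exp *= in_win.sum() / total
            expected += win_exp
    if n_windows == 0:
        warnings.warn("no windows retained; returning zero grids", stacklevel=2)
    return AggregateGrid(
        band=tuple(band), half_window=half_window, bin_size=bin_size,
        observed=observed, expected=expected, n_windows=n_windows,
    )


def hotspot_centre_projections(hotspots: list[Hotspot]) -> np.ndarray:
    """Pooled 1D feature positions: both axis projections of every hotspot's
    weighted centre."""
    return np.array(
        [c for h in hotspots for c in h.weighted_centre], dtype=float
    )
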