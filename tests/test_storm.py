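"""STORM clustering, NND statistics, CSR null and mask-ratio enrichment."""

import numpy as np
import pytest
from scipy.stats import chisquare

from stagkit import simulate as sim
from stagkit import storm as st


def square_mask(side_um=10.0, pixel_size=20.0):
    n = int(side_um * 1000 / pixel_size)
    return st.MaskRaster(np.ones((n, n), bool), pixel_size)


# ---------------------------------------------------------------------------
# Cluster identification


def test_identify_clusters_simple_triplet():
    pts = np.array([[0, 0], [30, 0], [0, 30], [5000, 5000]])
    pattern = st.PointPattern("n1", "c", pts)
    clusters = st.identify_clusters(pattern, eps=50, min_pts=3)
    assert len(clusters) == 1
    np.testing.assert_allclose(clusters.centroids[0], [10, 10])
    assert clusters.sizes[0] == 3


def test_identify_clusters_isolated_point_is_noise():
    pattern = st.PointPattern("n1", "c", np.array([[100.0, 100.0]]))
    assert len(st.identify_clusters(pattern, eps=50, min_pts=2)) == 0


def test_identify_clusters_order_invariant(rng):
    # well-separated blobs: no ambiguous border points, so the partition
    # must be identical under any point ordering
    centres = rng.uniform(0, 50_000, size=(8, 2))
    pts = np.vstack([rng.normal(c, 20.0, size=(30, 2)) for c in centres])
    pattern = st.PointPattern("n1", "c", pts)
    shuffled = st.PointPattern("n1", "c", pts[rng.permutation(len(pts))])
    a = st.identify_clusters(pattern, eps=120, min_pts=5)
    b = st.identify_clusters(shuffled, eps=120, min_pts=5)
    key = lambda cs: sorted(map(tuple, np.round(cs.centroids, 6)))
    assert key(a) == key(b)


def test_localization_density():
    mask = square_mask(side_um=5.0)  # 25 um^2
    pts = st.PointPattern("n1", "c", np.tile([2500.0, 2500.0], (50, 1)))
    assert st.localization_density(pts, mask) == pytest.approx(2.0)
    empty = st.PointPattern("n1", "c", np.empty((0, 2)))
    assert st.localization_density(empty, mask) == 0.0


def test_density_scales_with_pixel_size():
    grid = np.ones((100, 100), bool)
    pts = st.PointPattern("n1", "c", np.array([[10.0, 10.0]]))
    d1 = st.localization_density(pts, st.MaskRaster(grid, 20.0))
    d2 = st.localization_density(pts, st.MaskRaster(grid, 40.0))
    assert d1 == pytest.approx(4 * d2)


# ---------------------------------------------------------------------------
# Nearest-neighbour distances


def test_nnd_self_mode_pair_and_triangle():
    pair = st.ClusterSet("n1", "c", np.array([[0, 0], [80, 0]]))
    np.testing.assert_allclose(st.nearest_neighbor_distances(pair), [80, 80])
    # right triangle with sides 30 / 40 / 50
    tri = st.ClusterSet("n1", "c", np.array([[0, 0], [30, 0], [0, 40]]))
    np.testing.assert_allclose(
        sorted(st.nearest_neighbor_distances(tri)), [30, 30, 40]
    )


def test_nnd_cross_mode_keeps_exact_matches():
    a = st.ClusterSet("n1", "a", np.array([[10.0, 10.0], [50.0, 50.0]]))
    b = st.ClusterSet("n1", "b", np.array([[10.0, 10.0], [50.0, 50.0]]))
    np.testing.assert_allclose(st.nearest_neighbor_distances(a, b), [0, 0])


def test_nnd_self_mode_duplicates_zero():
    dup = st.ClusterSet("n1", "c", np.array([[5.0, 5.0], [5.0, 5.0], [99.0, 0.0]]))
    nnds = st.nearest_neighbor_distances(dup)
    assert nnds[0] == 0 and nnds[1] == 0 and nnds[2] > 0


def test_nnd_requires_enough_centroids():
    single = st.ClusterSet("n1", "c", np.array([[0.0, 0.0]]))
    with pytest.raises(ValueError):
        st.nearest_neighbor_distances(single)
    empty_ref = st.ClusterSet("n1", "c", np.empty((0, 2)))
    with pytest.raises(ValueError):
        st.nearest_neighbor_distances(single, empty_ref)


def test_mean_nnd_decreases_with_density(rng):
    mask = square_mask()
    means = []
    for n in (50, 200, 800):
        pts = st.sample_uniform_in_mask(mask, n, rng)
        cs = st.ClusterSet("n1", "c", pts)
        means.append(st.nearest_neighbor_distances(cs).mean())
    assert means[0] > means[1] > means[2]


# ---------------------------------------------------------------------------
# Histograms and the CSR null


def test_nnd_histogram_binning_and_overflow():
    hist = st.nnd_histogram([82.0] * 10)
    assert hist.frequencies[16] == 1.0  # bin [80, 85)
    assert hist.frequencies.sum() == pytest.approx(1.0)
    with_overflow = st.nnd_histogram([82.0] * 9 + [600.0])
    assert with_overflow.n_overflow == 1
    assert with_overflow.frequencies.sum() == pytest.approx(1.0)


def test_difference_curve_zero_for_identical_and_sums_to_zero():
    nnds = [10.0, 60.0, 60.0, 130.0]
    base = st.nnd_histogram(nnds)
    _, diff = st.nnd_histogram(nnds, null=base)
    np.testing.assert_allclose(diff, 0.0)
    other = st.nnd_histogram([5.0, 200.0, 350.0])
    _, diff2 = st.nnd_histogram(nnds, null=other)
    assert diff2.sum() == pytest.approx(0.0, abs=1e-12)


def test_csr_null_reproducible_and_matches_closed_form():
    mask = square_mask()  # 10 x 10 um, lambda = 4 per um^2 with 400 points
    centroids = st.ClusterSet(
        "n1", "c", st.sample_uniform_in_mask(mask, 400, np.random.default_rng(7))
    )
    a = st.csr_null(centroids, mask, n_reps=2, seed=11)
    b = st.csr_null(centroids, mask, n_reps=2, seed=11)
    np.testing.assert_array_equal(a.frequencies, b.frequencies)

    # mean of the simulated NNDs ~ 1/(2 sqrt(lambda)) = 250 nm
    rng = np.random.default_rng(1)
    sim_means = [
        st.nearest_neighbor_distances(
            st.ClusterSet("n1", "c", st.sample_uniform_in_mask(mask, 400, rng))
        ).mean()
        for _ in range(10)
    ]
    assert np.mean(sim_means) == pytest.approx(250.0, abs=15.0)


def test_csr_experimental_agrees_with_null_in_aggregate():
    """Across seeds, a CSR pattern's NND histogram should not be
    distinguishable from the simulated null (chi-square screen)."""
    mask = square_mask(side_um=5.0)
    rng = np.random.default_rng(3)
    rejections = 0
    n_seeds = 15
    for _ in range(n_seeds):
        pts = st.sample_uniform_in_mask(mask, 150, rng)
        cs = st.ClusterSet("n1", "c", pts)
        nnds = st.nearest_neighbor_distances(cs)
        null = st.csr_null(cs, mask, n_reps=40, seed=rng)
        hist = st.nnd_histogram(nnds)
        n_in = hist.n_total - hist.n_overflow
        expected = null.frequencies * n_in
        observed = hist.frequencies * n_in
        keep = expected >= 5
        if keep.sum() < 2:
            continue
        stat, p = chisquare(
            np.append(observed[keep], observed[~keep].sum()),
            np.append(expected[keep], expected[~keep].sum()),
        )
        if p < 0.01:
            rejections += 1
    assert rejections <= 3


# ---------------------------------------------------------------------------
# Mask density ratio


def test_mask_ratio_uniform_points_near_one(rng):
    nuclear = square_mask()
    s96_grid = np.zeros_like(nuclear.grid)
    s96_grid[:, :125] = True  # left quarter
    s96 = st.MaskRaster(s96_grid, nuclear.pixel_size, role="s96")
    pts = st.PointPattern("n1", "c", st.sample_uniform_in_mask(nuclear, 10_000, rng))
    result = st.mask_density_ratio(pts, s96, nuclear)
    assert result.ratio == pytest.approx(1.0, abs=0.08)


def test_mask_ratio_planted_enrichment():
    config = sim.SimConfig(seed=21, mask_enrichment=2.0, n_localizations=10_000)
    nucleus = sim.gen_nucleus(config)
    result = st.mask_density_ratio(
        nucleus.mask_points, nucleus.s96_mask, nucleus.nuclear_mask
    )
    assert result.ratio == pytest.approx(2.0, rel=0.05)


def test_mask_ratio_zero_points_flagged():
    nuclear = square_mask(side_um=1.0)
    s96_grid = np.zeros_like(nuclear.grid)
    s96_grid[:10, :10] = True
    s96 = st.MaskRaster(s96_grid, nuclear.pixel_size, role="s96")
    empty = st.PointPattern("n1", "c", np.empty((0, 2)))
    result = st.mask_density_ratio(empty, s96, nuclear)
    assert result.density_in == 0 and np.isnan(result.ratio)


def test_mask_ratio_rotation_invariant(rng):
    """Rotating points and masks together by 90 degrees preserves the
    ratio exactly (the raster rotates losslessly)."""
    nuclear = square_mask(side_um=4.0)
    s96_grid = np.zeros_like(nuclear.grid)
    s96_grid[20:80, 40:130] = True
    s96 = st.MaskRaster(s96_grid, nuclear.pixel_size, role="s96")
    pts = st.sample_uniform_in_mask(nuclear, 3000, rng)
    base = st.mask_density_ratio(st.PointPattern("n1", "c", pts), s96, nuclear)

    side = nuclear.grid.shape[0] * nuclear.pixel_size
    rot_pts = np.column_stack([side - pts[:, 1], pts[:, 0]])  # 90 deg CCW
    rot = lambda m, role: st.MaskRaster(np.rot90(m.grid, k=-1).copy(),
                                        m.pixel_size, role)
    rotated = st.mask_density_ratio(
        st.PointPattern("n1", "c", rot_pts), rot(s96, "s96"), rot(nuclear, "nuclear")
    )
    assert rotated.ratio == pytest.approx(base.ratio, rel=1e-9)


def test_nucleus_sim_mask_assignment_rule():
    """Planted assignment: P(inside) = m f / (m f + (1 - f))."""
    config = sim.SimConfig(seed=9, mask_enrichment=2.0, mask_fraction=0.25,
                           n_localizations=20_000)
    nucleus = sim.gen_nucleus(config)
    f = nucleus.truth["mask_fraction_achieved"]
    expected = 2 * f / (2 * f + (1 - f))
    observed = nucleus.truth["n_inside"] / config.n_localizations
    assert observed == pytest.approx(expected, abs=3 * 0.5 / np.sqrt(20_000))
    assert nucleus.truth["p_inside"] == pytest.approx(expected)


def test_nucleus_sim_single_cluster_and_determinism():
    config = sim.SimConfig(seed=13, n_clusters=1, n_localizations=500)
    a = sim.gen_nucleus(config)
    b = sim.gen_nucleus(config)
    assert len(a.centroids) == 1
    np.testing.assert_array_equal(a.mask_points.points, b.mask_points.points)
    np.testing.assert_array_equal(a.s96_mask.grid, b.s96_mask.grid)
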