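"""Synthetic data generators with planted, known ground truth.

Every input class the toolkit consumes can be generated here without
downloads: score-annotated Hi-C contact lists with planted contact
hotspots over a distance-decay background; nuclei with cluster centroids,
localization patterns and signal masks; differential-abundance interactome
tables with planted high-confidence positives; proteomes with planted
motif instances; cassette-exon junction counts at a chosen true PSI; and
replicate/treated signal-track sets with planted peaks.

Each generator draws from its own pseudo-random stream split from the
master seed, so adding a generator call never perturbs the others, and
returns a ground-truth ledger alongside the data; recovery tests compare
against that ledger only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .seqfeatures import FYXF_PATTERN, MotifHit, MotifPattern
from .storm import ClusterSet, MaskRaster, PointPattern, disc_mask

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """All generator settings; ``seed`` fixes every output bit-for-bit."""

    seed: int = 0
    # Hi-C contacts
    chrom_length: float = 50e6
    n_background_contacts: int = 100_000
    background_score_sd: float = 20.0
    hotspot_specs: tuple = ()  # (centre1 bp, centre2 bp, n_contacts, sigma bp)
    # STORM nuclei
    nucleus_radius: float = 5.0  # um
    n_clusters: int = 100
    n_localizations: int = 10_000
    locs_per_cluster: int = 20
    loc_sigma: float = 30.0  # nm
    mask_fraction: float = 0.25
    mask_enrichment: float = 1.0
    mask_pixel_size: float = 20.0  # nm
    # interactome
    n_proteins: int = 500
    planted_positive_ids: tuple = ()
    # proteome
    n_sequences: int = 50
    sequence_length: int = 200
    motif_insertions: tuple = ()  # (sequence index, position)
    # junctions
    true_psi: float = 50.0
    junction_depth: int = 10_000
    # tracks
    track_n_bins: int = 10_000
    track_bin_size: int = 500
    peak_specs: tuple = ()  # (start bin, end bin, height)
    peak_retention: float = 0.5
    track_noise_sd: float = 0.1

    def __post_init__(self):
        if not 0 < self.mask_fraction < 1:
            raise ValueError("mask_fraction must lie strictly between 0 and 1")
        if not 0 <= self.true_psi <= 100:
            raise ValueError("true_psi must lie in [0, 100]")
        for c1, c2, _n, _sigma in self.hotspot_specs:
            if not (0 <= c1 <= self.chrom_length and 0 <= c2 <= self.chrom_length):
                raise ValueError(f"hotspot centre ({c1}, {c2}) outside chromosome")
        for start, end, _h in self.peak_specs:
            if not 0 <= start < end <= self.track_n_bins:
                raise ValueError(f"peak bins [{start}, {end}) outside track")


_STREAMS = ("contacts", "nucleus", "interactome", "proteome", "junctions", "tracks")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """One child stream per generator, split from the master seed."""
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


# ---------------------------------------------------------------------------
# Hi-C contacts


def gen_contacts(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Score-annotated contact list with planted hotspots.

    Background separations follow a 1/d density on [10 kb, chrom_length/2]
    (log-uniform) with Normal(0, background_score_sd) scores truncated to
    (-100, 100); each hotspot spec scatters n contacts as an isotropic 2D
    Gaussian around its centre with scores uniform on [60, 100].
    """
    rng = _rng(config, "contacts")
    L = config.chrom_length
    rows = []

    n_bg = config.n_background_contacts
    sep = np.exp(rng.uniform(np.log(1e4), np.log(L / 2), size=n_bg))
    p1 = rng.uniform(0, L - sep)
    sd = config.background_score_sd
    scores = truncnorm.rvs(-100 / sd, 100 / sd, scale=sd, size=n_bg, random_state=rng)
    bg = pd.DataFrame(
        {"chrom": "chrSim", "pos1": p1, "pos2": p1 + sep, "score": scores}
    )
    rows.append(bg)

    truth_hotspots = []
    for c1, c2, n, sigma in config.hotspot_specs:
        pts = rng.normal(loc=[c1, c2], scale=sigma, size=(int(n), 2))
        pts = np.clip(pts, 0, L)
        lo, hi = pts.min(axis=1), pts.max(axis=1)
        hs = pd.DataFrame(
            {
                "chrom": "chrSim",
                "pos1": lo,
                "pos2": hi,
                "score": rng.uniform(60, 100, size=int(n)),
            }
        )
        rows.append(hs)
        truth_hotspots.append(
            {"centre1": float(c1), "centre2": float(c2),
             "n_contacts": int(n), "sigma": float(sigma)}
        )

    contacts = pd.concat(rows, ignore_index=True)
    member_of = np.repeat(
        np.arange(-1, len(config.hotspot_specs)),
        [n_bg] + [int(n) for _, _, n, _ in config.hotspot_specs],
    )
    order = np.lexsort((contacts["pos2"].to_numpy(), contacts["pos1"].to_numpy()))
    contacts = contacts.iloc[order].reset_index(drop=True)
    truth = {
        "hotspots": truth_hotspots,
        "n_background": n_bg,
        "member_of": member_of[order].tolist(),  # -1 = background
    }
    return contacts, truth


# ---------------------------------------------------------------------------
# STORM nuclei


@dataclass
class NucleusSim:
    nuclear_mask: MaskRaster
    s96_mask: MaskRaster
    centroids: ClusterSet
    cluster_points: PointPattern
    mask_points: PointPattern
    truth: dict = field(default_factory=dict)


def _blob_mask(nuclear: MaskRaster, target_fraction: float,
               rng: np.random.Generator) -> MaskRaster:
    """Union of random discs inside the nuclear mask covering approximately
    ``target_fraction`` of its area (the achieved fraction is recorded by
    the caller)."""
    rows, cols = np.nonzero(nuclear.grid)
    n_target = target_fraction * nuclear.grid.sum()
    if n_target < 1:
        raise ValueError("mask_fraction times nuclear area is below one pixel")
    blob = np.zeros_like(nuclear.grid)
    r_px = max(3, int(np.sqrt(nuclear.grid.sum()) / 12))
    yy, xx = np.mgrid[0 : nuclear.grid.shape[0], 0 : nuclear.grid.shape[1]]
    while blob.sum() < n_target:
        pick = rng.integers(0, len(rows))
        cy, cx = rows[pick], cols[pick]
        blob |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        blob &= nuclear.grid
    return MaskRaster(blob, nuclear.pixel_size, role="s96")


def gen_nucleus(config: SimConfig, nucleus_id: str = "n1") -> NucleusSim:
    """One synthetic nucleus.

    The nuclear mask is a disc of ``nucleus_radius``; cluster centroids are
    CSR-uniform in the disc; ``cluster_points`` are Gaussian blobs of
    localizations attached to the centroids; ``mask_points`` are assigned
    inside the signal mask with probability m*f / (m*f + (1-f)) where m =
    mask_enrichment and f = the achieved mask area fraction, and placed
    uniformly within their region.
    """
    if config.n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = _rng(config, "nucleus")
    from .storm import sample_uniform_in_mask

    nuclear = disc_mask(config.nucleus_radius * 1000.0, config.mask_pixel_size)
    s96 = _blob_mask(nuclear, config.mask_fraction, rng)
    outside = nuclear.difference(s96)

    centroids = sample_uniform_in_mask(nuclear, config.n_clusters, rng)
    cluster_set = ClusterSet(nucleus_id, "sim", centroids,
                             np.full(config.n_clusters, config.locs_per_cluster))

    locs = rng.normal(
        np.repeat(centroids, config.locs_per_cluster, axis=0), config.loc_sigma
    )
    cluster_points = PointPattern(nucleus_id, "sim", locs)

    f = s96.area_um2 / nuclear.area_um2
    m = config.mask_enrichment
    p_in = m * f / (m * f + (1 - f))
    inside = rng.random(config.n_localizations) < p_in
    n_in = int(inside.sum())
    pts = np.empty((config.n_localizations, 2))
    pts[inside] = sample_uniform_in_mask(s96, n_in, rng)
    pts[~inside] = sample_uniform_in_mask(outside, config.n_localizations - n_in, rng)
    mask_points = PointPattern(nucleus_id, "sim", pts)

    truth = {
        "mask_fraction_achieved": f,
        "p_inside": p_in,
        "n_inside": n_in,
        "centroids": centroids.tolist(),
    }
    return NucleusSim(nuclear, s96, cluster_set, cluster_points, mask_points, truth)


# ---------------------------------------------------------------------------
# Interactome tables


def gen_interactome_table(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Differential-abundance table with planted high-confidence positives.

    Planted positives satisfy every high-confidence rule (|log2FC| > 0.58,
    p < 0.1, no IgG detection, knockdown log2FC <= -0.58); every other
    record is constructed to violate exactly one rule, recorded as ground
    truth in canonical test order (igg, fold_change, p_value, sirna).
    """
    rng = _rng(config, "interactome")
    ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    planted = set(config.planted_positive_ids)
    unknown = planted - set(ids)
    if unknown:
        raise ValueError(f"planted ids not in protein id space: {sorted(unknown)[:5]}")

    rows, reasons = [], {}
    violations = ("igg", "fold_change", "p_value", "sirna")
    for pid in ids:
        sign = rng.choice([-1.0, 1.0])
        good = {
            "protein_id": pid,
            "log2fc": sign * rng.uniform(0.8, 3.0),
            "p_value": rng.uniform(0.0, 0.099),
            "detected_in_igg": False,
            "sirna_log2fc": rng.uniform(-3.0, -0.8),
        }
        if pid in planted:
            reasons[pid] = ""
        else:
            reason = violations[rng.integers(0, len(violations))]
            if reason == "igg":
                good["detected_in_igg"] = True
            elif reason == "fold_change":
                good["log2fc"] = sign * rng.uniform(0.0, 0.58)
            elif reason == "p_value":
                good["p_value"] = rng.uniform(0.1, 1.0)
            else:
                good["sirna_log2fc"] = (
                    np.nan if rng.random() < 0.5 else rng.uniform(-0.5, 1.0)
                )
            reasons[pid] = reason
        rows.append(good)
    table = pd.DataFrame(rows)
    truth = {"positives": sorted(planted), "reasons": reasons}
    return table, truth


# ---------------------------------------------------------------------------
# Proteome with planted motifs


def _draw_motif_instance(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for pos in pattern.positions:
        if pos.optional and rng.random() < 0.5:
            continue
        choices = sorted(pos.allowed) if pos.allowed is not None else list(AA)
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def gen_proteome(config: SimConfig, pattern: MotifPattern = FYXF_PATTERN,
                 ) -> tuple[dict[str, str], list[MotifHit]]:
    """Random protein sequences with motif instances spliced in at recorded
    positions.

    Returns (id -> sequence, planted MotifHit ledger). The ledger lists the
    planted instances only; chance matches arising from the random
    background are legitimate scanner hits, so recovery tests assert that
    planted hits are a subset of scanner output.
    """
    rng = _rng(config, "proteome")
    seqs = {
        f"seq{i:04d}": "".join(
            rng.choice(list(AA), size=config.sequence_length)
        )
        for i in range(config.n_sequences)
    }
    planted = []
    for seq_idx, position in config.motif_insertions:
        sid = f"seq{seq_idx:04d}"
        instance = _draw_motif_instance(pattern, rng)
        if position + len(instance) > config.sequence_length:
            raise ValueError(
                f"insertion at {position} leaves no room for {len(instance)} residues"
            )
        s = seqs[sid]
        seqs[sid] = s[:position] + instance + s[position + len(instance):]
        planted.append(MotifHit(sid, position, len(instance), instance))
    return seqs, planted


# ---------------------------------------------------------------------------
# Junction counts


def gen_junction_counts(config: SimConfig) -> tuple[dict, dict]:
    """Cassette-exon junction read counts at a chosen true PSI.

    Each of ``junction_depth`` junction-supporting reads is an inclusion
    read with probability w = 2p/(1+p) (p = true_psi/100), the weight that
    makes the expectation of the junction-normalised PSI equal true_psi;
    inclusion reads split across the two inclusion junctions binomially.
    """
    rng = _rng(config, "junctions")
    p = config.true_psi / 100.0
    w = 2 * p / (1 + p) if p > 0 else 0.0
    n_inc = int(rng.binomial(config.junction_depth, w))
    n_exc = config.junction_depth - n_inc
    inc1 = int(rng.binomial(n_inc, 0.5))
    counts = {
        "inclusion_counts": (inc1, n_inc - inc1),
        "exclusion_count": n_exc,
    }
    truth = {"true_psi": config.true_psi, "depth": config.junction_depth}
    return counts, truth


# ---------------------------------------------------------------------------
# Signal tracks


def gen_tracks(config: SimConfig) -> tuple[dict, dict]:
    """Replicate track pair plus a treated track with planted peaks.

    Replicates share peak positions and heights with independent noise
    (half-normal, scale track_noise_sd); the treated track multiplies every
    peak height by ``peak_retention``.
    """
    from .tracks import SignalTrack

    rng = _rng(config, "tracks")

    def noise():
        return np.abs(rng.normal(0.0, config.track_noise_sd, size=config.track_n_bins))

    def with_peaks(retention: float, base: np.ndarray) -> np.ndarray:
        values = base.copy()
        for start, end, height in config.peak_specs:
            values[int(start):int(end)] += float(height) * retention
        return values

    tracks = {
        "rep1": SignalTrack("chrSim", config.track_bin_size, with_peaks(1.0, noise())),
        "rep2": SignalTrack("chrSim", config.track_bin_size, with_peaks(1.0, noise())),
        "treated": SignalTrack(
            "chrSim", config.track_bin_size, with_peaks(config.peak_retention, noise())
        ),
    }
    truth = {
        "peak_specs": [list(p) for p in config.peak_specs],
        "retention": config.peak_retention,
    }
    return tracks, truth


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
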