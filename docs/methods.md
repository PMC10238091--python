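# Methods

`stagkit` re-implements, as one tested package, the bespoke computational
procedures used to characterise cohesin-independent STAG (SA) protein
biology: Hi-C contact-hotspot detection with aggregate enrichment grids,
STORM nearest-neighbour and mask statistics against simulated random nulls,
high-confidence interactor filtering with hypergeometric interactome
enrichment, F/YXF-class motif scanning, percent-spliced-in (PSI) from
junction reads, and exon-peptide isoelectric-point reconstruction. Every
stage is exercisable on synthetic data with planted ground truth; no
downloads are required.

## Hi-C contact hotspots (`stagkit.hotspots`)

A contact is a coordinate pair (pos1 <= pos2) on one chromosome with a
dimensionless enrichment score in (-100, 100). The caller:

1. subsets to high-scoring contacts (score >= 60, inclusive) with
   separation in the 10 kb - 70 Mb band (inclusive boundaries);
2. links each retained contact to its k = 250 nearest neighbours by
   Euclidean distance in the (pos1, pos2) plane; the self-match at distance
   zero is discarded *by index*, so genuine zero distances between distinct
   duplicate contacts still form edges;
3. takes connected components of the undirected union of those edges and
   drops components with fewer than 100 members.

Each hotspot is summarised by its score-weighted centre (the weighting is a
package choice; the source procedure does not define one) and the member
bounding box.

Open design points and how they are resolved (each is a constructor flag):
neighbour search runs within the already-filtered high-scoring set
(`search_all` searches the whole band and subsets neighbours afterwards);
edges are the *union* of directed kNN lists (`mutual` requires both
directions); component size counts member contacts (`count_mode="fends"`
counts distinct fragment-end coordinates); no maximum neighbour distance is
applied by default, but `d_max` caps it — in sparse synthetic regimes a cap
of ~250 kb prevents isolated background contacts, whose k nearest
neighbours can be megabases away, from attaching to planted clusters.

Aggregate grids pool windows around all unordered pairs of hotspot-centre
axis projections whose separation falls in a requested band (e.g. 100 kb -
1 Mb). Each window spans +/- 250 kb around the pair and is split into 1 kb
bins (500 x 500 with defaults); windows without any score >= 60 contact are
discarded. The observed grid sums binned contact counts over retained
windows. The expected model is the package's own: the empirical
distance-decay separation histogram of all supplied contacts, evaluated at
each bin's separation and normalised per window to the window's observed
total, so enrichment log2((obs+1)/(exp+1)) measures concentration relative
to the genome-wide decay shape. Coordinates are 0-based bp, bins half-open.

## STORM spatial statistics (`stagkit.storm`)

Localizations are (x, y) nm points per nucleus and channel. Cluster
identification is density-based spatial clustering (DBSCAN; eps = 50 nm,
min_pts = 10 by default, both recorded in output metadata) — the imaging
study cited an earlier protocol whose parameters are not reproduced, so a
standard density-based algorithm with configurable parameters stands in.
Centroids are unweighted member means.

Nearest-neighbour distances (NND) are computed per query centroid, either
within one channel (self mode, self-match excluded by index) or against a
second channel (cross mode, exact coordinate matches kept; query defaults
to the SA-like channel). Histograms run 0-500 nm in 5 nm steps (100 bins);
distances beyond 500 nm are excluded from normalisation and reported as an
overflow count. The random null places the observed number of centroids
uniformly inside the nuclear mask (uniform pixel choice plus in-pixel
offset, i.e. rejection sampling at raster resolution), per nucleus, with 10
replicates by default, and averages replicate histograms. The difference
curve is experimental minus null frequency per bin.

Mask enrichment divides the localization density (count / area, area =
pixel count x pixel area) inside the S9.6 signal mask by the density over
the rest of the nucleus; a ratio above 1 is enrichment. A zero outside
density is flagged (inf / NaN) rather than raised.

Numerical note: in a bounded region the CSR mean NND exceeds the unbounded
closed form 1/(2 sqrt(lambda)) by a boundary term (about +5 nm at 400
points in a 10 x 10 um field); the calibration tests therefore compare
within Monte-Carlo error rather than exactly.

## Interactome statistics (`stagkit.interactome`)

A differential-abundance record carries a log2 fold change (acute
degradation vs untreated), an unadjusted p-value, an IgG-detection flag and
a knockdown (siRNA) log2 fold change. High-confidence interactors must
pass, in order: not IgG-detected; |log2FC| > 0.58 (log2 of 1.5, strict);
p < 0.1 (strict); knockdown-sensitive. "Sensitive" has no published numeric
rule; the default here is sirna_log2fc <= -0.58, records missing the field
fail, and the rule is configurable. Every exclusion is annotated with the
first failing rule in that fixed order so filter ledgers are reproducible.

Overlap enrichment against a reference interactome is the upper-tail
hypergeometric probability P(X >= k) with k the observed overlap, computed
exactly; the background set is always user-supplied, never assumed.
Families of tests are corrected by Benjamini-Hochberg step-up.

## Genome tracks (`stagkit.tracks`)

Signal tracks are per-bin values (500 bp bins by default). Peaks are
maximal runs of bins *strictly* above the track's empirical 0.995 quantile
(linear-interpolation quantile, genome-wide per track); the strict
inequality keeps zero-inflated tracks from calling the whole chromosome.
Replicate consensus retains replicate-1 peaks with >= 1 bp overlap in
replicate 2. R-loop peaks are classified against SA peaks as overlap
(>= 1 bp shared), adjacent (edge-to-edge gap <= 2 kb) or distal. Mean
profiles expand each region by a 2 kb flank, resample to a fixed bin count
by bin-centre lookup, and treat off-track positions as zero. Percent signal
change is 100 x (mean_treated - mean_control)/mean_control over
region-covered bins; treatment-sensitive sites are peaks whose mean signal
drops by a fraction >= tau (default 0.5 — the published site selection
gives no numeric rule). All intervals are 0-based half-open; strand is
ignored.

## Sequence features (`stagkit.seqfeatures`)

The F/YXF-class motif `[PFCAVIYL][FY][GDEN]F.{0,1}[DANE].{0,1}[DE]`
predicts binding to the SA conserved essential surface. Matching expands
the two optional positions explicitly into fixed-length patterns (window
lengths 6-8) rather than delegating to a regex engine, so every reported
span is exact and auditable; overlapping hits and multiple lengths per
start are all reported.

PSI for a cassette exon is 100 x inc/(inc + exc), where inc averages the
two inclusion junctions and exc is the single skipping junction — the
junction-count normalisation reflects the cassette geometry. PSI is
undefined (not an error) with zero reads; an event is "supported" when
inclusion plus exclusion reads total at least 50.

Exon peptides are reconstructed from the two printed esiRNA target
sequences (SA1 exon 31, SA2 exon 32) by translating both at the unique
reading offset that is internal-stop-free for every sequence in the set —
the only frame rule that needs no external annotation. For the printed
pair this forces offset 1 (the SA2 sequence has stops in its other two
frames) and yields two 36-residue peptides.

The isoelectric point is the unique root of the Henderson-Hasselbalch net
charge Z(pH) = sum over positive groups 1/(1+10^(pH-pKa)) minus sum over
negative groups 1/(1+10^(pKa-pH)), over side chains (K, R, H positive; D,
E, C, Y negative) and free termini, found by bisection on [0, 14] to 1e-4.
Z is strictly decreasing in pH, so the root is unique. The default pKa set
is Bjellqvist's: D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0;
residue-specific N-terminal values (A 7.59, M 7.0, S 6.93, P 8.36, T 6.82,
V 7.44, E 7.7; 7.5 otherwise) and C-terminal 3.55 with the D/E corrections
4.55/4.75. The table is injectable and recorded in output.

## Synthetic data (`stagkit.simulate`)

One pseudo-random stream per generator, split from the master seed, so
adding a generator call never perturbs the others; identical seeds are
bit-identical. Every generator returns a ground-truth ledger, and recovery
tests compare against that ledger only.

* **Contacts.** Background separations are log-uniform (density
  proportional to 1/d) on [10 kb, L/2] — enough to make kNN locality
  meaningful, not a claim about real distance decay — with scores
  Normal(0, sd = 20) truncated to (-100, 100), putting ~0.135% of the
  background above the score-60 cut. Each planted hotspot scatters its
  contacts as an isotropic 2D Gaussian (default sigma 20 kb) with scores
  uniform on [60, 100]. Off-chromosome centres reject the config.
* **Nuclei.** The nuclear mask is a disc (radius 5 um) rasterized at 20
  nm/pixel; area is pixel count x pixel area. The S9.6-like mask is a
  union of random discs grown to the requested area fraction (the achieved
  fraction is recorded and used downstream). Cluster centroids are
  CSR-uniform in the disc; cluster localizations are Gaussian blobs around
  them; mask-calibration points are assigned inside the mask with
  probability m f/(m f + (1-f)) for enrichment m and achieved fraction f,
  and uniformly within their region.
* **Interactome.** Planted positives satisfy every high-confidence rule;
  each other record is built to violate exactly one rule, recorded as the
  ground-truth exclusion reason.
* **Proteome.** Random sequences over the 20 amino acids with motif
  instances drawn from the pattern language spliced in at recorded
  positions. The background is left untouched, so chance matches are
  legitimate hits: the ledger lists planted instances only and recovery
  asserts planted ⊆ found.
* **Junctions.** Each of `junction_depth` reads is an inclusion read with
  probability w = 2p/(1+p) (p = true PSI/100) — the weight under which the
  expectation of the junction-normalised PSI equals the true PSI —
  splitting 50/50 across the two inclusion junctions.
* **Tracks.** Two replicates share planted peak positions and heights with
  independent half-normal noise; the treated track multiplies peak heights
  by a retention factor (default 0.5).

What the generators do **not** emulate: Hi-C matrix balancing and
realistic decay exponents, STORM photophysics/PSF and drift, peptide-level
MS spectra, read-level RNA-seq. Passing recovery tests therefore
demonstrates correctness of the algorithms under their stated statistical
assumptions, not performance on real instrument output.

## Problem sizes used in the packaged checks

The packaged calibration and recovery checks run at desk scale, chosen so
each completes in seconds: hotspot recovery uses one 50 Mb chromosome with
200,000 background contacts and 20 planted clusters of 120-200 contacts
(k = 25 scaled to the synthetic high-scorer density, d_max = 250 kb);
CSR calibration uses 400 centroids in a 10 x 10 um field; mask-ratio
calibration uses 10,000 localizations per nucleus; the motif oracle
comparison covers 1,000 random length-200 sequences; the filter-ledger
check covers 200 seeded configurations. The published genome-scale counts
(thousands of hotspots, tens of thousands of R-loop sites) depend on
deposited experimental datasets and are out of scope here; the two
published exon-peptide pI values are reproduced exactly as printed inputs.

## Known limitations

* The hotspot caller's behaviour depends on k relative to point density;
  k = 250 is appropriate at genome-scale contact counts and must be scaled
  down (with `d_max` if the background is sparse) on small instances.
* DBSCAN border points can change cluster assignment under point
  reordering; partitions are stable only for well-separated clusters.
* The aggregate-grid expected model is a package choice (see above), not a
  reproduction of the original visualisation package's internal model.
* Published mean NNDs may pool per-nucleus means or pool all distances;
  both reducers are available and the choice matters for unbalanced
  nuclei.
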