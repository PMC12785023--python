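# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `msimargin`, in the order the pipeline applies them.

## Data model

An MSI acquisition is held as an `MSIDataCube`: a possibly non-rectangular
set of integer pixel positions (0-based, x rightward, y downward — the
imzML top-left convention), a shared strictly increasing m/z axis of bin
centers, and an `n_pixels × n_bins` nonnegative intensity matrix. The
at-rest intensity dtype is float32 (ample for TOF dynamic range at half
the memory); operations whose contracts require exact arithmetic — TIC
normalization in particular — return float64, and the container preserves
it. Every transforming operation appends to a free-text provenance log and
never truncates it.

imzML 1.1 files are read and written with `pyimzml`. Continuous-mode axes
are adopted as-is; processed-mode peak lists are resampled by fixed-width
binning (below). Writing always produces continuous mode with a float32
intensity payload, so write → read is exact at float32 resolution.

## Preprocessing

**TIC normalization.** Each pixel spectrum is rescaled so its intensity
sum equals a common target. The default target is the grand mean of the
raw per-pixel TICs rather than 1.0: it keeps intensities on the
instrument's scale, and any positive constant gives the same clustering
under Euclidean distance (uniform scaling). Pixels with zero TIC cannot be
rescaled; by default they are kept as zeros and flagged in provenance
(`drop_pixel` is available). Normalization is exact to relative 1e−9 and
idempotent.

**Windowing.** The axis is partitioned into 200–400, 400–600, 600–800,
and 800–1000 Da with half-open `[low, high)` semantics; the terminal
window closes at 1000 so the partition covers the full range. The pipeline
always normalizes on the full recorded range first and windows second, so
per-window spectra keep their weights from the full spectrum; whether
normalization should instead be repeated inside each window is not
determined by the protocol this package follows, so both are reachable
through the API, with global normalization the default.

**Binning.** Processed-mode peak lists and phantom spectra are placed on a
fixed 0.1 Da grid anchored at the range start, centers at
`low + (i + 0.5)·width`, half-open bin intervals (a peak exactly on an
edge joins the upper bin). Bin width 0.1 Da matches the annotation
tolerance scale. Binning replaces the proprietary vendor centroiding used
on the original instruments; it is reproducible and conserves total
intensity up to out-of-range exclusions, which are counted in provenance.

## Segmentation

Pixels are clustered by agglomerative HCA with Euclidean distance and
single linkage, the standard MSI segmentation recipe, and the hierarchy is
cut at k = 2 (binary; margin depiction) or k = 10 (denary; heterogeneity).
No feature selection precedes clustering: distances use all bins of the
active window.

The cut is computed exactly through the MST equivalence: the
single-linkage partition into k clusters equals the connected components
after removing the k−1 largest edges of the minimum spanning tree of the
complete distance graph. Implementation details that matter:

- Distances are `scipy.spatial.distance.pdist` on float64; the MST comes
  from `scipy.sparse.csgraph` on the dense distance matrix, with all
  weights shifted by +1 beforehand so duplicate pixels (distance zero)
  keep their edges (a monotone shift leaves the MST unchanged). This holds
  the full condensed distance matrix, O(n²) memory — exactness and simple,
  provable tie handling were preferred over an O(n) memory streaming MST;
  the intended grids (up to a few thousand pixels) fit comfortably.
- **Ties.** When tied merge distances straddle the cut, components are
  first formed from all edges strictly below the tie value, then tied
  edges — drawn from *all* pixel pairs at that distance, not only the MST —
  are admitted in lexicographic (pixel-index pair) order until exactly k
  components remain. This reproduces naive agglomeration with the same
  tie-break, verified exactly against an independent O(n³) oracle.
- **Labels** are re-indexed by descending cluster size, ties broken by the
  smallest member pixel in row-major order, so cluster identities and
  colors are stable across reruns. There is no randomness anywhere; two
  runs are identical through the rendered PNG bytes.
- Requesting more clusters than there are distinct spectra is an error
  reporting the achievable maximum (splitting identical spectra would be
  arbitrary).
- Binary and denary cuts of the same cube share one distance/MST
  computation (`hca_segment_multi`).

Per-cluster arithmetic mean spectra and sizes accompany every result; the
dominant m/z of a mean spectrum is the center of its tallest bin, ties to
the lowest mass.

## Margin statistic and inference

Four ROIs per case — two tumor, two peritumor, supplied as JSON polygons
or run-length masks. The tumor's reference cluster is the *modal* label
over the union of the two tumor ROIs (ties to the smaller label): the
simplest estimator consistent with two tumor ROIs. The match percentage is
the fraction of peritumor-ROI pixels (both ROIs pooled; per-ROI available)
carrying that label, off-tissue positions excluded from both counts. The
margin is recognized when the match is *strictly* below the 10 %
threshold. For k = 10 the same statistic is computed but flagged advisory:
with ten classes label matching is unreliable, and the denary result is
instead summarized by a heterogeneity index (distinct labels inside the
tumor ROIs).

Collection-level agreement with the histology call is tested with the
exact one-sided binomial upper tail under p₀ = ½, computed in integer
arithmetic (`Σᵢ≥ₛ C(n,i)/2ⁿ`); 9 successes in 10 trials give 11/1024 ≈
0.011. One-sided is the appropriate direction for "better than chance
agreement"; chance probability ½ encodes a random binary call. A case
counts as recognized in a (window, k) cell if either ionization mode
recognized it; per-mode counts are recoverable from the per-case rows.

## Information content

The information content of a segmentation is the byte size of its label
image compressed losslessly as PNG. Because a file size is the statistic,
the encoder is pinned: 8-bit truecolor RGB, one image pixel per raster
position, maximum-effort deflate, no interlace, no ancillary chunks;
identical inputs give identical bytes, and the encoder identity (Pillow
version) is recorded. A fixed palette of ten maximally distinct colors
plus a background color for off-tissue positions keeps images comparable.
Sizes are reported in raw bytes and in KiB (bytes/1024); "kB" is ambiguous
between 1000 and 1024, so raw bytes are always preserved.

Trends of size across the four windows are tested by OLS of KiB on window
index 1–4 (the windows are categorical, equally spaced; the m/z midpoint
regressor is available), pooled over cases within a mode: per-mode slope
with a one-sided t-test for a decrease, and a two-sided t-test on the
interaction term of a joint two-mode regression for the slope difference.
Perfectly collinear inputs degenerate the t statistic; they are reported
as the machine-limit verdict (p = 0 for a nonzero slope in the tested
direction, p = 1 otherwise), never NaN.

## Annotation

Discriminant masses are matched against a local TSV table (name, formula,
class; ~34 curated entries: nucleotides including dCTP, common
glycerophospholipids and sphingolipids, triacylglycerols, sugars, fatty
acids). Monoisotopic masses are computed from IUPAC/CODATA atomic masses;
adduct m/z uses electron-adjusted shifts (+1.007276 for [M+H]⁺, etc.).
All (entry, adduct) pairs of polarity matching the ionization mode within
the ±0.1 Da tolerance are returned, nearest first. Every output is marked
*tentative*: MS1 mass matching cannot identify a species. The 885.75 Da
margin mass frequently attributed to the triglyceride class has no settled
formula; the shipped table deliberately asserts no entry for it.

## Phantom generator

The phantom emulates the tissue structure this analysis is designed for: a
peritumor background, an elliptical tumor with a second core subregion
(heterogeneity), a 2-pixel margin band around the tumor, and optionally a
fat disk (`complex` preset). Default raster 40 × 40 pixels at the nominal
30 µm pitch — a deliberately scaled-down stand-in for cm-scale sections
chosen so that full studies run in minutes; all statistics are
resolution-agnostic rates and indices.

Spectra are sums of Gaussian peaks (σ = 0.05 Da) on the 0.1 Da grid. Each
region's panel contains: two fixed common peaks plus 14 per-case random
common peaks (shared by all regions — inter-case variability without
contrast); fixed discriminant anchors at the literature masses (tumor:
465.94, 864.15, 885.75, 212.10, 699.40 Da; peritumor: 281.25, 480.31,
722.51, 834.53 Da) plus two per-case random discriminants per window. All
differential peaks are scaled by a per-window `contrast_by_window`
multiplier, so zero contrast makes regions chemically identical in that
window. The margin band carries the half/half tumor–peritumor mixture,
plus (in the `distinct_margin` preset) its own 465.94 Da peak so the
margin is a spectral class of its own; `gradient_margin` omits it. Mean
amplitudes are O(100), per-pixel amplitude CV 0.1 (lognormal), a
multiplicative per-pixel TIC drift of CV 0.15 (removed by normalization),
and folded-Gaussian additive noise on every bin: σ = 1 in negative mode,
σ = 5 in positive mode, encoding the observation that positive-mode images
are noisier at low mass. These values are the generator's definition of a
realistic high-SNR acquisition, chosen once.

Collections default to contrast confined to the lipid windows
(0/0/0.3/1.0 across the four windows): the study condition in which only
high-mass chemistry delineates the margin. Canonical ROIs are auto-placed
as radius-2 disks around deep interior points of the tumor and peritumor
regions (distance-transform maxima, eroded two pixels from any boundary),
so ROIs never touch the margin band. A master seed fans out to per-case
and per-mode substreams (`numpy.random.SeedSequence`); the two modes of a
case share panel and geometry draws and differ in noise.

**Scoring against truth.** Binary segmentations are scored by the adjusted
Rand index against tumor-versus-rest ground truth with the margin band
excluded: the band is a transition zone whose binary assignment is
genuinely ambiguous (single linkage may attach it to either side), and
excluding boundary pixels from segmentation scoring is standard practice.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: physically realistic TOF peak shapes and isotope
envelopes, matrix cluster ions and ion suppression, spatially correlated
noise, mass-calibration drift, irregular tissue outlines, and any claim
that the anchor masses behave in real tissue as they do here. Phantom
results validate the *pipeline*, not the biology. In particular the
decreasing positive-mode information-content trend reported for real
acquisitions is a property of real noise structure; the default phantom
study does not reproduce it, and the trend machinery is validated instead
by a Monte-Carlo power check (slopes −20 vs 0 KiB/window, noise σ = 2 KiB,
10 cases: the interaction test detects the difference at p < 0.005 in
≥ 90 % of replicates).

## Problem sizes and runtime

Defaults used by the test suite and the acceptance script: 40 × 40 rasters
(1600 pixels, 8000 bins), 10-case collections, 20-seed recovery batteries.
A full 10-case study (2 modes × 4 windows × k ∈ {2, 10}) runs in ~2–3
minutes on one CPU; the dominant cost is the Euclidean distance matrix per
windowed cube. Exact clustering with the dense-matrix MST is practical to
roughly 10⁴ pixels (~0.5 GiB for the distance matrix).

## Known limitations

- Single linkage chains: one noisy pixel bridging two tissues can merge
  them, which is faithful to the method under study, not a defect of the
  implementation. High SNR is assumed.
- k is fixed at 2/10 by design; no automatic model selection.
- Margin recognition for k = 10 is advisory only.
- The annotation step is MS1-only and polarity-filtered; it shortlists, it
  does not identify.
- imzML files embed a fresh UUID on every write, so fixture integrity is
  verified by content checksums (coordinates, axis, intensities), not file
  hashes.
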