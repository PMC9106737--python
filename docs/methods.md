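# Methods

This note documents the models, conventions and numerical choices behind
`rcpdecode`, and what the synthetic benchmarks do and do not demonstrate.

## Conventions

Pixel coordinates are 0-based `(y, x)` with the origin at the top-left of
the stitched canvas; tile rectangles are half-open.  Images are 16-bit
unsigned (8-bit input is upcast without rescaling).  Tiles are numbered
row-major on the stage grid and overlap by a configurable fraction of the
tile dimension (default 0.10); z-stacks carry a configurable number of
planes and are collapsed by per-pixel maximum before any 2-D processing.

## Registration

Stitching is translation-only, in the spirit of grid stitchers such as
MIST: for every grid-adjacent tile pair the integer residual around the
nominal offset is found by maximizing the Pearson correlation of the
overlap strips over a small search window (default ±5 px), with the peak
correlation serving as an edge confidence in [−1, 1].  Global positions
anchor tile 0 and propagate along the maximum-confidence spanning tree;
edges below a confidence floor (default 0.3) fall back to their nominal
offset and are excluded from influencing the tree where a better path
exists.  Overlap pixels blend by per-pixel maximum, which preserves the
peak of an RCP straddling a seam (averaging would dim it).  Rounds are
aligned to round 0 by the same correlation search on the nuclear channel,
which is the only channel guaranteed stable across hybridization cycles.
Offsets are integer pixels throughout; sub-pixel registration is deferred
because the barcode linker tolerates ≤1 px residuals through its distance
penalty.

Degenerate (constant) overlap content yields confidence 0; with unrelated
content the confidence is near zero and the stitcher's fallback keeps the
nominal geometry.

## Spot calling and quality

Background removal is a white top-hat with a disk structuring element
(default radius 3 px).  Spots are 8-connected components above a manual
per-channel intensity threshold, gated by component area
(`size_min_px`–`size_max_px`); the centroid is intensity-weighted and the
reported intensity is the component maximum.  Thresholds are deliberately
manual configuration values — channel gains differ between experiments and
rigs — and the defaults are calibrated to the simulator's default
amplitudes (threshold at 30% of the default spot amplitude admits no false
components ≥4 px on pure-noise canvases while keeping full recall).

When spot amplitude is only a few noise standard deviations, per-pixel
thresholding cannot reach both high recall and high precision: the top-hat
of pure noise has a heavy, spatially correlated positive tail.  For that
regime the filter stage offers a matched Gaussian pre-smoothing
(`detect_smooth_sigma_px`, default 0 = off, applied to the raw canvas
before the top-hat) — the standard spot-calling lever.  The low-SNR
benchmark (amplitude = 5× noise sd) enables it with σ = 1.2 px and reaches
recall = precision = 1.0 with ~0.2 px centroid error.

Each spot's channel purity is `q = I_det / max(Σ I_other, ε)`, measured at
the spot's centroid pixel on the top-hat canvases of its round, over all
non-nuclear channels.  The measurement support (centroid pixel rather than
component mean) is a locality choice; `q` uses the peak reading because the
filtered peak is the quantity the detector thresholds.  The floor ε
(default 1 intensity unit) guards perfectly pure spots whose other channels
are exactly zero; away from the floor `q` is scale-invariant.

Per-spot SNR is `(peak − median)/1.4826·MAD` over an annulus (inner radius
2×, outer 4× the structuring radius) excluding detected-spot pixels, capped
at 10⁴ when the background has zero spread.  Under the simulator's noise
model (constant background + additive Gaussian, single in-focus plane) the
analytic SNR is `spot_amplitude / gaussian_noise_sd`, which the measurement
reproduces within ~25%.

## Barcode decoding

Sequential readout is a direct (round, channel) → gene lookup; spots at
unassigned slots are labelled `unassigned` and retained.

Combinatorial readout chains each first-cycle spot to its nearest
second-cycle spot within `link_radius_px` (default 5), extending greedily
from the previous member for further cycles; linking is one-directional
(anchored at cycle 1), and at this stage a later-cycle spot may be claimed
by several chains.  The chain's confidence is

    Q = ∏_{i=1}^{n−1} ( q_i q_{i+1} − k d_{i(i+1)} ),

which for the two-cycle case reduces to `q₁q₂ − k·d₁₂`.  The product is
taken over the full bracketed term — the only reading that reduces to the
two-cycle form while remaining well-defined for n > 2.  `k` (default 0.2
per pixel) sets how fast confidence decays with link distance: with typical
q ≈ 1 it drives Q below zero near d ≈ 5 px, matching the default search
radius.  Only Q > 0 barcodes survive; shared spots are resolved by Q rank
(ties: smaller total distance, then input order); barcodes absent from the
codebook are counted as `invalid_barcode` and excluded from the expression
path.  Decoding is fully deterministic.

## Cells and quantification

Nuclei: DAPI threshold → hole filling → minimum-size gate → watershed on
the negated distance transform, seeded at maxima of the lightly smoothed
(σ = 1 px) distance map separated by at least `nucleus_peak_min_distance_px`
(default 6; the smoothing stops ragged mask edges from seeding spurious
maxima and over-splitting).  Territories: nuclei expanded outward up to
`max_expansion_px` (default 15 at the 20X scale — uncapped expansion would
tile the whole canvas, which real tissue geometry never does), meeting at
equidistant ridges.  Spots are assigned by the label under their rounded
centroid; label 0 is background — kept in the table, excluded from the
matrix.

Density mode (low magnification) defines a gene's signal in a cell as the
fraction of the cell's pixels whose top-hat signal clears a density
threshold — the minimal operational reading of "density-based, not
spot-based" quantification with cell-size adjustment; the
`CellQuantification.mode` flag guarantees the area division is applied
exactly once whether the matrix arrives as fractions or raw foreground
counts.

## Expression analysis

Filtering removes cells below a minimum total count first, then genes
expressed in too few of the surviving cells (cell-then-gene order).
Normalization scales each cell to a common total — the median of per-cell
totals by default — followed by log1p.  Density matrices skip count
normalization: the area division is their size adjustment.  Clustering
builds a symmetrized kNN graph (Euclidean, default 15 neighbours, after an
optional PCA to min(20, genes−1, cells−1) components — standard practice
for wider panels) and partitions it with Leiden (RB-configuration
modularity) at a configurable resolution; fixed seeds give identical
labels.

## The simulator

The generator emulates exactly the structure the pipeline assumes: cells
are disks (nucleus ⊂ cytoplasm), placed without nucleus overlap; per cell
and gene a Poisson number of RCPs (rate = `spots_per_cell_per_gene` ×
`efficiency_scale` × optional per-gene abundance factor × optional
log-normal per-cell expression scale) is drawn uniformly in the cytoplasm
disk; RCPs render as isotropic Gaussians (default σ = 1.2 px, ≈1 µm at a
20X/0.32 µm-per-pixel scale) into the channels the codebook dictates, at
the same stitched position every cycle; optional crosstalk mixes a fraction
of each signal channel into the others; the canvas is cut into overlapping
tiles with integer stage jitter, expanded into z-stacks whose central plane
holds the signal, and degraded with constant background plus per-plane
additive Gaussian noise, clipped to uint16.  Same config ⇒ bit-identical
output.

Deliberate simplifications: no tissue autofluorescence or illumination
gradients, Gaussian rather than Airy spots, no Poisson shot noise
(amplitude-dominated regime; keeps SNR analytic), integer-only jitter (so
stitch recovery can be asserted exactly), no z-dependent PSF.
Consequently, passing benchmarks demonstrates the correctness and
calibration of the algorithms under the stated signal model — not
robustness to autofluorescence, optical aberrations or segmentation of
densely packed tissue.

Paired-condition fixtures reuse one seed so nucleus placement and per-cell
expression scales (drawn before any spot) are identical across conditions;
only the rate scale differs, making the generative per-gene rate ratio
exact.

## Benchmark conditions and problem sizes

The canonical fixtures (in `rcpdecode.fixtures`) fix the study conditions
once: detection at amplitude/noise = 5 on a 256² tile with ~40 spots ≥8 px
apart; stitching on a 3×3 grid of 128² tiles with 10% overlap and ±3 px
jitter; combinatorial decoding with 2 cycles × 8 genes at low density and
5% crosstalk; segmentation/assignment on a 512² field with 30 cells;
spot-vs-density on an 800² field with 45 cells whose expression varies
log-normally (σ = 0.6); cluster recovery on planted marker-block mixtures
of 100 cells per population.

The efficiency comparison uses three paired 2000² ROIs, 800 cells each,
four genes at staggered abundances (expected low-condition totals
~200–1200 per ROI and gene) and a generative rate ratio of 5.13.  Rates
deliberately sit in the sparse regime: a count-based efficiency comparison
assumes resolvable spots, so crowding must stay mild.  Even so the denser
condition loses a few percent more spots to merging, biasing the recovered
slope ~4–6% low — an inherent property of count-based comparisons, reported
as such rather than corrected.

## Known limitations

Integer-pixel registration only; greedy (not globally optimal) cross-cycle
linking, one-directional as defined; no error-correcting barcodes or
crowding deconvolution; watershed segmentation assumes roughly convex,
DAPI-bright nuclei; density quantification depends on a manual threshold
with no auto-calibration.
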