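# rcpdecode

Image analysis for targeted in situ sequencing (ISS) experiments read out by
hybridization: spot calling, quality-scored combinatorial barcode decoding,
tile stitching, DAPI-based cell segmentation and cell-by-gene
quantification — plus a synthetic-experiment simulator that provides ground
truth for every stage, so the whole pipeline is testable without microscopy
data.

In ISS, padlock probes circularize on their target transcripts and are
amplified by rolling circle amplification into rolling circle products
(RCPs): bright, diffraction-limited fluorescent spots, imaged over one or
more hybridization cycles on a conventional widefield microscope.  The
analysis problem is to turn a grid of overlapping, multi-round,
multi-channel z-stacks into a per-cell expression matrix:

1. **Projection & stitching** — maximum-intensity projection per tile, then
   translation-only stitching of the tile grid (normalized cross-correlation
   on the nominal overlap strips, assembled along a maximum-confidence
   spanning tree) and per-round alignment on the nuclear channel.
2. **Spot calling** — white top-hat background removal (disk structuring
   element), manual per-channel intensity and size thresholds, 8-connected
   components, intensity-weighted centroids.  Each spot gets a
   channel-purity quality
   `q = I_detected / Σ_{c ≠ detected, c ≠ DAPI} I_c`.
3. **Decoding** — *sequential* mode: one gene per (round, channel), direct
   lookup.  *Combinatorial* mode: each first-cycle spot is linked to its
   nearest next-cycle spot within a search radius, and the chained barcode
   is scored

       Q = ∏_{i=1}^{n−1} ( q_i · q_{i+1} − k · d_{i(i+1)} )

   with `d` the inter-cycle distance in pixels and `k` a tunable penalty;
   only barcodes with `Q > 0` are called, and a spot claimed by several
   chains goes to the highest-Q one.
4. **Cells** — nuclei by DAPI threshold + watershed split, expanded into
   capped cell territories; spots are assigned to the territory containing
   their centroid.  A low-magnification (10X) mode quantifies each gene as
   the thresholded-signal fraction of every cell's area instead of counting
   spots.
5. **Expression analysis** — cell/gene filtering, median-total
   normalization, log1p, and Leiden clustering on a kNN graph (after an
   optional PCA), in the style of the standard single-cell workflow.

The `simulate` module generates the matching synthetic experiments — disk
cells, Gaussian RCPs, codebook-driven channel assignment, channel
crosstalk, tile jitter, focal z-stacks, Gaussian noise — with full ground
truth (spot lists, cell masks, tile offsets, count tables), and
`rcpdecode.fixtures` bundles the canonical benchmark conditions used by the
tests and examples.

## Worked example

`examples/03_combinatorial_decoding.py` simulates a 2-cycle, 8-gene
combinatorial experiment (95 RCPs, 5% channel crosstalk), detects spots in
both cycles, links them and applies the Q filter:

```
planted 95 barcoded RCPs; linked 95 candidates; called 95
correct-gene rate: 1.000; invalid barcodes: 0; dropped by Q<=0: 0
Q of called barcodes: median 9.79
```

Every planted RCP is recovered with its correct gene: the channel-purity
qualities are high (clean spots), the link distances are sub-pixel, so all
Q values clear zero.  The other examples cover detection at low SNR,
stitching with stage jitter (`9/9 offsets exact`), segmentation +
clustering (`planted 2 populations … label agreement 1.00`) and the 10X
density mode (`median per-gene r = 0.961` against 20X spot counts).  Each
example is a short, self-contained script that prints what it computes.

A thin CLI wraps the same stages for shell use:

```bash
rcpdecode run-all --sim sim.yaml --codebook codebook.yaml \
    --config run.yaml --out out/ --seed 1
```

writing tiles, stitched canvases, spot tables (CSV), the decoded table, the
label masks and the MatrixMarket expression matrix, plus a `manifest.json`
recording the stages run.

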