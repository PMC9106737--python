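"""Low-magnification density quantification versus spot counting.

Emulates imaging the same field at half the resolution (2x block-mean
downsampling), quantifies each gene as the thresholded-signal fraction of
every cell's area, and correlates those densities with the 20X spot counts
per gene.  High correlation means the faster low-magnification readout
preserves per-cell expression ranking.
"""

from rcpdecode import fixtures

corr, info = fixtures.run_density_comparison(seed=3)
print(f"{info['n_shared_cells']} cells quantified in both modes")
for row in corr.itertuples(index=False):
    print(f"  {row.gene}: Pearson r = {row.r:.3f}")
print(f"median per-gene r = {corr['r'].median():.3f}")
# r >~ 0.9 per gene: density maps are a faithful (if coarser) proxy for
# spot counts, enabling ~4x faster imaging.
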