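"""Simulate a small sequential experiment, call spots and assign genes.

Builds a single-tile, 4-gene experiment (one gene per fluorescence channel
in one round), runs projection, background filtering, spot calling and the
sequential gene lookup, and compares calls against the simulator's ground
truth.
"""

import rcpdecode as rd
from rcpdecode import fixtures, pipeline

sim, codebook, cfg = fixtures.segmentation_fixture(seed=2)
tileset, truth = rd.simulate.simulate_experiment(sim, codebook)
canvases, _ = pipeline.project_and_stitch(tileset, cfg)
filtered = pipeline.filter_canvases(canvases, sim.layout, cfg)
detected = pipeline.detect_all(filtered, sim.layout, cfg)
called = pipeline.decode_sequential(detected, codebook)

print(f"simulated {len(truth.spots)} RCPs in {len(truth.cells)} cells")
print(f"detected  {len(detected)} spots "
      f"(median quality q = {detected['quality'].median():.2f})")
for gene in codebook.genes:
    t = (truth.spots["gene"] == gene).sum()
    c = (called["gene"] == gene).sum()
    print(f"  {gene}: {c} called / {t} true")
# Counts track the ground truth to within a few percent: the shortfall is
# spots merging when two RCPs of the same gene land closer than the
# detector can resolve.
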