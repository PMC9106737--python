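"""Machine twin of a chemistry detection-efficiency comparison.

Simulates three paired ROIs whose second condition has a 5.13-fold higher
per-gene RCP rate (sharing the cell geometry, as consecutive tissue
sections would), runs the full detection pipeline on all six experiments,
and fits the through-origin regression of high-condition on low-condition
(ROI, gene) totals.  Takes about a minute.
"""

from rcpdecode import fixtures

ratio = 5.13
slope, r, a, b = fixtures.run_slope_recovery(ratio, seed=1)
print(f"low-condition totals per (ROI, gene):\n{a}")
print(f"high-condition totals per (ROI, gene):\n{b}")
print(f"recovered slope {slope:.2f} (true rate ratio {ratio}), "
      f"Pearson r = {r:.4f}")
# The slope lands a few percent below the true ratio: the denser
# high-efficiency condition loses slightly more spots to optical crowding,
# a bias inherent to count-based efficiency comparisons.
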