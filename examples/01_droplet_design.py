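"""Droplet-experiment design arithmetic.

Computes the occupancy probabilities and throughput numbers for a
standard run: 10% of droplets carry a cell, 35 um droplets generated
from 4 ul/min of aqueous phase, and 20,000 barcode beads fused at 7%
bead occupancy and 132 droplets per second.
"""

from dropmet import droplet_stats as ds

lam = ds.calibrate_lambda(0.10)
print(f"cell loading rate lambda        {lam:.6f}")
print(f"P(single cell in droplet)       {ds.poisson_occupancy(lam, 'exactly_k', 1):.4f}")
print(f"P(two cells in droplet)         {ds.poisson_occupancy(lam, 'exactly_k', 2):.6f}")
print(f"droplets in 10 min at 4 ul/min  {ds.droplet_count(4, 10, 35):,.0f}")
print(f"generation rate (droplets/s)    {ds.generation_rate(4, 35):,.0f}")
print(f"fusion device runtime (min)     {ds.fusion_runtime(20_000, 0.07, 132):.1f}")
print(f"expected barcoded cells         "
      f"{ds.expected_barcoded_cells(285_714, 0.10, 0.07, 0.8):,.0f}")

# The double-occupancy probability stays below 0.5% at this dilution --
# the price of the ~10x dilution is that ~90% of droplets are empty.
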