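"""Compute and reuse lαβ reference statistics.

A reference NBI frame is summarized by six numbers (per-axis mean and
standard deviation in lαβ). The JSON form lets a conversion run without
shipping the reference image itself — useful when the reference is
clinical data that cannot be redistributed.
"""

import numpy as np

from nbisim import colorspace, fixtures, transfer

# stand-in for a real NBI reference frame
_, nbi_reference = fixtures.generate_pair(fixtures.SyntheticSpec(seed=7))

stats = transfer.compute_stats(colorspace.rgb_to_lab(nbi_reference))
print("reference statistics as JSON:")
print(stats.to_json())

# a conversion driven by the JSON stats is identical to one driven by
# the reference frame itself
wli, _ = fixtures.generate_pair(fixtures.SyntheticSpec(seed=8))
from_stats = transfer.simulate_nbi(wli, transfer.ChannelStats.from_json(stats.to_json()))
from_frame = transfer.simulate_nbi(wli, nbi_reference)
print("max pixel difference (stats file vs frame):",
      f"{np.abs(from_stats.simulated - from_frame.simulated).max():.2e}")

# several reference frames can be pooled pixel-wise into one summary
refs = [fixtures.generate_pair(fixtures.SyntheticSpec(seed=s))[1] for s in (7, 17, 27)]
pooled = transfer.pooled_stats([colorspace.rgb_to_lab(r) for r in refs])
print(f"pooled over {len(refs)} frames: n_pixels = {pooled.n_pixels}")
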