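"""Run circular binary segmentation on a synthetic Z-score chromosome.

The vector has two true breakpoints (bins 40 and 70). CBS recursively
splits wherever the permutation p of the maximal circular t statistic
falls below alpha = 0.05; the recovered boundaries should land on the
true ones, and seg_mean recovers each level.
"""

import numpy as np

from plasmacin import CbsParams, cbs_segment

rng = np.random.default_rng(0)
z = rng.normal(size=100)
z[40:70] += 3.0   # a gained region at bin Z ~ +3

segments = cbs_segment(z, CbsParams(alpha=0.05, n_perm=2000, seed=1))

print(f"{'start':>6} {'end':>6} {'n_bins':>6} {'seg_mean':>9} "
      f"{'Z':>8} {'logP':>8}")
for s in segments:
    print(f"{s.start:6d} {s.end:6d} {s.n_bins:6d} {s.seg_mean:9.3f} "
          f"{s.z:8.2f} {s.logP:8.2f}")
print("\nThe gain is recovered with breakpoints at (or within one bin of) "
      "40 and 70; at alpha = 0.05 an occasional extra split of the noise "
      "background is expected. logP is the log10 permutation p-value of "
      "the split that created each segment.")
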