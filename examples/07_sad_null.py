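"""The SAD-only null: apparent dynamics from finite sequencing depth.

A static community (no colonization or extinction at all) is observed
through multinomial read sampling.  Rare taxa drop in and out of
detection, creating apparent events; this script estimates 'rates' from
those artefacts and fits the log-log regression, showing what sampling
noise alone produces.
"""

import numpy as np

from colext.simstudies import sad_null_slopes
from colext.synthetic import SyntheticSpec, simulate_sad_detection

spec = SyntheticSpec(n_taxa=300, times=tuple(float(t) for t in range(24)),
                     dynamics=False, depth=2000, seed=0)
series, truth = simulate_sad_detection(spec)
det = series.sites["site1"].detections[:, :, 0]
events = int((det[:, :-1] != det[:, 1:]).sum())
print(f"static community, depth 2000: {events} apparent events "
      f"across {det.shape[0]} taxa x {det.shape[1]} samples")

fits = sad_null_slopes(seeds=range(3))
for f in fits:
    print(f"  null slope {f.slope:+.3f} (n={f.n})")
print("\nsampling artefacts alone yield slopes well away from the -1 trade-off;")
print("estimation noise does create a spurious negative relation, so the slope")
print("value itself -- not merely its sign -- carries the evidence")
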