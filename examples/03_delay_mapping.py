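"""Voxelwise coupling strength and BOLD response delay on a toy brain.

Builds a 3-region volume whose voxels respond to the CO2 reference with
delays of 0, 3 and 6 s, then maps coupling r and delay voxelwise and
summarizes per region.
"""

import numpy as np

from cvrpipe import ParadigmSpec, build_paradigm, map_cvr
from cvrpipe.synthetic import region_regressor

spec = ParadigmSpec()
par = build_paradigm(spec, 100.0, seed=0)
tr = 1.25
times = 12 * tr + np.arange(468) * tr
reference = region_regressor(par, times, 0.0)

rng = np.random.default_rng(0)
labels = np.zeros((6, 3, 1), dtype=int)
labels[0:2], labels[2:4], labels[4:6] = 1, 2, 3
data = np.zeros((6, 3, 1, reference.size))
for lab, delay in ((1, 0.0), (2, 3.0), (3, 6.0)):
    sig = region_regressor(par, times, delay)
    sel = labels == lab
    noise = 0.3 * np.std(sig) * rng.standard_normal((sel.sum(), sig.size))
    data[sel] = sig + noise

cvr = map_cvr(data, reference, labels > 0, fs=1 / tr,
              f0=spec.fundamental_frequency)
for lab, delay in ((1, 0.0), (2, 3.0), (3, 6.0)):
    sel = labels == lab
    print(f"region {lab}: true delay {delay:.1f} s -> median estimate "
          f"{np.median(cvr.delay[sel]):.2f} s, median r "
          f"{np.median(cvr.r[sel]):.2f}")
# Delays are recovered within a fraction of the 1.25 s TR; r reflects the
# in-band signal-to-noise of each voxel.
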