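"""From raw gas/flow traces to a breath-resolved end-tidal CO2 series.

Generates one synthetic subject's capnography (with a 2 s analyzer
delay), removes the technical delay by cross-correlation against the
respiratory flow, segments breaths, and reads the end-tidal values.
"""

import numpy as np

from cvrpipe import (ParadigmSpec, build_paradigm, correct_technical_delay,
                     detect_breaths, extract_end_tidal)
from cvrpipe.paradigm import epoch_plateau_means
from cvrpipe.synthetic import make_cohort, make_physio

par = build_paradigm(ParadigmSpec(), 100.0, seed=0)
cohort, _ = make_cohort(seed=0)
truth = cohort[0]
truth.technical_delay = 2.0

pco2, po2, flow = make_physio(truth, par, rate=100.0)
corrected, lag = correct_technical_delay(pco2, flow, max_lag=5.0)
breaths = detect_breaths(corrected, flow)
et_co2, et_o2 = extract_end_tidal(corrected, po2, breaths)
means = epoch_plateau_means(et_co2.times, et_co2.values, par)

print(f"technical delay recovered : {lag:.2f} s (true 2.00 s)")
print(f"breaths detected          : {len(breaths)}")
print(f"resting P_ET_CO2          : {means[0.0]:.1f} mmHg "
      f"(true {truth.resting_petco2:.1f})")
print(f"+4 mmHg epoch increment   : {means[4.0] - means[0.0]:.2f} mmHg")
print(f"+8 mmHg epoch increment   : {means[8.0] - means[0.0]:.2f} mmHg")
# The increments recover the programmed steps within a fraction of a mmHg
# despite 0.5 mmHg analyzer noise, because each value is an expiratory
# plateau read at the breath's end-expiration point.
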