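"""Build the CO2 challenge block design and inspect its structure.

The default protocol alternates normocapnia (70 s) with 30 s epochs of
mild hypercapnia targeting +4 or +8 mmHg over the resting end-tidal CO2,
six cycles in all — ten minutes of scanning.
"""

from cvrpipe import ParadigmSpec, build_paradigm

spec = ParadigmSpec()
par = build_paradigm(spec, rate=100.0, seed=0)

print(f"total duration      : {par.duration:.0f} s")
print(f"hypercapnic epochs  : {par.n_hypercapnic_epochs}")
print(f"fundamental frequency: {spec.fundamental_frequency:.3f} Hz")
print(f"target range        : {par.target.min():.0f}-{par.target.max():.0f} mmHg")
print()
print(par.epochs.to_string(index=False))
# The epochs table drives both the synthetic gas traces and the frequency
# band used by the coupling analysis (fundamental = 1 / cycle duration).
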