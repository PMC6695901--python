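"""QCM-D: segment a five-step deposition protocol and apply Sauerbrey.

Builds a synthetic multi-overtone trace following the standard mucin
deposition protocol (buffer baseline, mucin adsorption, rinse, polymer
injection, final rinse), segments it at the injection times, and
converts each step's frequency shift into areal mass and thickness.
"""

from mucofilm.qcmd import rigidity_check, segment_trace, step_sauerbrey
from mucofilm.synthetic import make_qcmd_trace

trace, events = make_qcmd_trace(seed=7)
print(f"trace: {len(trace.time)} samples, overtones {trace.overtones}")

for step in segment_trace(trace, events):
    sb = step_sauerbrey(step, rho=1.05)
    rigid = "rigid" if rigidity_check(step) else "SOFT (Sauerbrey unreliable)"
    print(f"  {step.label:9s} df/n = {step.delta_f_per_overtone[3] / 3:6.2f} Hz  "
          f"mass = {sb.mass_areal:7.2f} ng/cm^2  d = {sb.thickness:5.2f} A  [{rigid}]")

print()
print("The mucin step deposits ~55 ng/cm^2 with dD well below 0.5e-6, so the")
print("rigid-film Sauerbrey estimate applies; the final rinse shows a negative")
print("mass (desorption) as polymer/mucin complexes are flushed away.")
print("Note the Sauerbrey thickness (~5 A at 1.05 g/cm^3) is a dry-mass")
print("equivalent; reflectometry, which sees the hydrated layer, gives ~22 A.")
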