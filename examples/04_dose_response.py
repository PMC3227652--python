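"""Dose-response saturation of the peak output.

The peak nuclear heterodimer concentration grows with the ligand dose
until it plateaus; the curve is summarised by the exponential fit
Opeak(x) = max(Opeak) * (1 - exp(-x/eta)), where eta is the dose scale at
which the response saturates.
"""

import smadscreen as ss
from smadscreen.experiments import DEFAULT_DOSES_PM

params = ss.make_parameter_fixtures()["sustained"]
fit = ss.dose_response(params, doses_pM=DEFAULT_DOSES_PM)

print("dose (pM)   Opeak (pM)")
for x, y in zip(fit.doses_pM, fit.opeaks_pM):
    print(f"{x:8.1f}   {y:10.2f}")
print(f"\nfit: max(Opeak) = {fit.max_opeak_pM:.1f} pM, eta = {fit.eta_pM:.1f} pM")
print("eta is the ligand concentration scale at which the response saturates;")
print("sustained responders tend to saturate at lower doses than transient ones.")
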