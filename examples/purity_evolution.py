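"""Radionuclidic purity of 47Sc after the end of bombardment.

Starts from the packaged per-scenario EOB activity sets (24 h, 1 uA)
and propagates radioactive decay, including the 44mSc -> 44gSc isomeric
transition (Bateman feeding). The purity is the 47Sc share of the total
scandium activity: it rises while the short-lived 43Sc/44Sc impurities
die away, and for entry energies of 35 MeV and above it peaks and then
falls because the long-lived 46Sc outlives 47Sc. Below 30 MeV no 46Sc
is made and the 99% purity level is eventually reached.
"""

import math

from foilyield import decay_activities, default_registry, max_rnp, rnp, time_to_rnp
from foilyield.io import activity_set_from_yields, load_yield_fixture

registry = default_registry()
yields = load_yield_fixture()

for e_entry in (30.0, 35.0, 40.0):
    a0 = activity_set_from_yields(yields, 24.0, e_entry)
    print(f"\nscenario: 24 h irradiation, protons below {e_entry:.0f} MeV")
    print(f"  EOB activities (MBq/uA): {a0.activities}")
    for t in (0.0, 100.0, 300.0, 1000.0):
        p = rnp(decay_activities(a0, t, registry))
        print(f"  RNP at {t:6.0f} h: {p:6.1%}")
    peak = max_rnp(a0, registry)
    if peak.at_horizon:
        print(f"  purity still rising at the {peak.t_h:.0f} h horizon ({peak.rnp:.1%})")
    else:
        print(f"  maximum RNP {peak.rnp:.1%} at {peak.t_h:.0f} h, then 46Sc takes over")
    t99 = time_to_rnp(a0, 0.99, registry)
    print("  time to 99% purity:", "never (46Sc floor)" if math.isinf(t99) else f"{t99:.0f} h")
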