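"""Energy bookkeeping through a stacked target.

Loads the packaged example stack (Kapton vacuum window, 12 cm air gap,
eight groups of Ti-48 target / Ni monitor / Al catcher / Al degrader),
sends a 70 MeV proton beam through it and prints the mid-foil energy and
combined uncertainty for every layer. The mid-foil energy is the energy
assigned to a cross-section point measured with that foil; the
uncertainty combines the +/-500 keV cyclotron extraction spread with
Bohr straggling accumulated in quadrature layer by layer.
"""

from foilyield import BeamState, propagate_stack
from foilyield.io import data_path, load_stack_json

layers = load_stack_json(data_path("example_stack.json"))
points = propagate_stack(BeamState(70.0, energy_unc_kev=500.0), layers)

print(f"{'layer':16s} {'role':9s} {'E_mid (MeV)':>12s} {'unc (keV)':>10s}")
for p in points:
    print(
        f"{p.layer.name:16s} {p.layer.role:9s} "
        f"{p.mid.energy_mev:12.3f} {p.mid.energy_unc_kev:10.0f}"
    )

targets = [p for p in points if p.layer.role == "target"]
print(
    f"\n{len(targets)} target foils sample the beam from "
    f"{targets[0].mid.energy_mev:.1f} down to {targets[-1].mid.energy_mev:.1f} MeV; "
    f"the deepest foil's energy is known to +/-{targets[-1].mid.energy_unc_kev:.0f} keV."
)
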