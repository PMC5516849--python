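"""Single-dose levodopa kinetics in the fasted versus fed state.

Builds the 42-state whole-body ACAT model with default kinetics, gives a
100 mg oral dose under each prandial physiology and prints the plasma peak.
Food slows gastric emptying (3.96 -> 0.33 per h) and raises gastric pH,
which lowers the peak concentration and delays its time.
"""

from levogut import (
    DoseRegimen,
    KineticParameters,
    PhysiologyParameters,
    build_wb_acat,
    cmax_tmax,
    set_prandial_state,
    simulate,
)

regimen = DoseRegimen(events=((0.0, 100.0),), horizon=12.0)
kinetics = KineticParameters()

for state in ("fasted", "fed"):
    physiology = set_prandial_state(PhysiologyParameters(), state)
    model = build_wb_acat(physiology, kinetics)
    tc = simulate(model, regimen, 12.0)
    cmax, tmax = cmax_tmax(tc)
    print(f"{state:>6}: Cmax = {cmax:.3f} mg/l at Tmax = {tmax:.2f} h "
          f"(GER {physiology.ger} /h, gastric pH {physiology.gastric_ph})")

print("\nThe fed state shows the expected lower, later peak: slower gastric")
print("emptying delays delivery to the absorbing intestinal segments.")
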