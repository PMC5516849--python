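"""Sequential two-occasion identification of the food effect on gastric emptying.

Synthetic plasma observations are generated for a 200 mg dose: a fasted
occasion at the literature fasting gastric-emptying rate (3.96/h) and a fed
occasion that differs only in that rate (0.33/h).  Stage 1 fits the kinetic
parameters on the fasted data with the rate pinned; stage 2 freezes the
kinetics and estimates the gastric-emptying rate alone from the fed data.
"""

import numpy as np

from levogut import (
    DoseRegimen,
    KineticParameters,
    PhysiologyParameters,
    build_wb_acat,
    generate_observations,
    sequential_two_occasion_fit,
)

model = build_wb_acat(PhysiologyParameters(), KineticParameters())
regimen = DoseRegimen(events=((0.0, 200.0),), horizon=8.0)
schedule = np.arange(0.25, 8.25, 0.25)

fasted = generate_observations(model, {}, regimen, "none", seed=1,
                               schedule=schedule)
fed = generate_observations(model, {"physiology.ger": 0.33}, regimen, "none",
                            seed=1, schedule=schedule, prandial="fed")

result = sequential_two_occasion_fit(fasted, fed, model, n_starts=4, seed=0)
ger = result.params["physiology.ger"]
print(f"stage-2 fed gastric-emptying rate: {ger:.4f} /h (truth 0.33 /h)")
print(f"stage-1 kinetics: { {k: round(v, 3) for k, v in result.params.items()} }")
print("\nThe two-occasion design isolates the prandial delay in gastric")
print("emptying as the single parameter changed by food.")
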