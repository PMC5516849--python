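"""Amino-acid ranking for brain levodopa delivery on the sIEC* network.

The enterocyte model is extended with kidney and brain levodopa transport,
the luminal influx is fixed at 15 mmol/gDW/h, the fasting calibration is
applied (66% of the influx reaches the systemic circulation, 30% of the
absorbed flux is eliminated renally) and the blood-brain-barrier delivery
reaction is maximised under co-administration of each amino acid in turn.
"""

from levogut import rank_amino_acids
from levogut.scenarios import fasting_reference

ref = fasting_reference(influx=15.0)
print(f"fasting reference: systemic {ref.systemic_pct_of_influx:.1f}% of influx, "
      f"renal {ref.renal_pct_of_absorbed:.1f}% of absorbed, "
      f"brain flux {ref.brain:.2f} mmol/gDW/h\n")

ranking = rank_amino_acids(influx=15.0)
print(ranking.table[["brain_flux", "class"]].round(3).to_string())
print(f"\nimproving: {ranking.amino_acids_in_class('improving')}")
print("Non-competing antiporter substrates (serine, threonine, asparagine)")
print("spare levodopa from renal loss and trans-stimulate secretion, raising")
print("the flux delivered to the brain above the fasting reference.")
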