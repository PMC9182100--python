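"""Turn raw assay readings into criterion values.

Shows the three measurement formulas: gravimetric rehydration capacity,
standard-curve inversion for total phenolic and total flavonoid content,
and the fixed-dilution total-anthocyanin formula.
"""

import famrank as fr

cap = fr.rehydration_capacity(w1=30.0, w2=75.0)
print(f"rehydration capacity: 30 g dry -> 75 g rehydrated = {cap:.1f} %")

tpc = fr.concentration_from_absorbance(0.4564, fr.TPC_CURVE)
print(f"TPC: absorbance 0.4564 at 725 nm -> {tpc:.3f} (gallic-acid equivalent units)")

tfc = fr.concentration_from_absorbance(0.4040, fr.TFC_CURVE)
print(f"TFC: absorbance 0.4040 at 420 nm -> {tfc:.3f} (quercetin equivalent units)")

tac = fr.total_anthocyanin(a535=0.1964, extract_volume=10.0, sample_mass=100.0)
print(f"TAC: A535=0.1964, 10 mL extract from 100 mg sample -> {tac:.3f} mg/10 mL")

print("\nthese values feed the ranking pipeline as the tpc/tfc/tac and")
print("rehydration criteria; the standard-curve slopes and intercepts are the")
print("published calibration coefficients, inverted exactly.")
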