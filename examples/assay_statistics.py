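"""Worked assay statistics: binding rate, viability, percent inhibition.

The three formulas the package provides for summarising the accompanying
cell-based readouts, evaluated on published group means.
"""

from nptraj.assay import (BindingAssay, GroupSummary, binding_rate,
                          percent_inhibition, viability)

# ELISA: 40 ng/mL total growth factor, 27.6 ng/mL left unbound
rate = binding_rate(BindingAssay(total=40.0, unbound=27.6))
print(f"ELISA binding rate: {rate * 100:.0f}% of the growth factor is "
      "nanoparticle-bound")

# MTT-style viability normalisation
v = viability(od_sample=0.66, od_blank=0.10, od_nc=0.80)
print(f"viability: {v:.0f}% of the negative-control signal")

# transwell migration (cells/field) and tube formation (um total length)
pairs = [
    ("WT migration", GroupSummary("WT", 583, 32), GroupSummary("WT+NP", 282, 30)),
    ("5A migration", GroupSummary("5A", 505, 55), GroupSummary("5A+NP", 312, 15)),
    ("WT tube length", GroupSummary("WT", 13804, 2488),
     GroupSummary("WT+NP", 5706, 295)),
]
for label, control, treated in pairs:
    pct = percent_inhibition(treated, control)
    print(f"{label}: {control.mean:g} -> {treated.mean:g} = "
          f"{pct:.0f}% inhibition")

print("\nPercent inhibition is the relative reduction of the treated group "
      "mean vs control, rounded to the nearest integer (halves away from "
      "zero); stronger inhibition of the wild type than of the mutant is "
      "the motif-dependence signal.")
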