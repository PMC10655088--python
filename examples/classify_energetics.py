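"""Classify contact energetics from decomposition components.

Samples a balanced synthetic suite of energy-decomposition records
(neutral stacks, a Hunter-Sanders-like class, ion-pi and ion-ion
pairs), places each on the signed ternary composition, and prints the
aggregate report.
"""

from picontact import classify, summarize, ternary_coordinates
from picontact.synthetic import sample_mixed_suite

suite = sample_mixed_suite(n_per_class=60, seed=5)
report = summarize(suite)
print(report.to_text())

example = suite[0]
point = ternary_coordinates(example.components_gas, variant="frz")
label = classify(example).label
print(
    f"\nexample record {example.dimer_id}: "
    f"r_disp={point.r_disp:+.2f} r_orb={point.r_orb:+.2f} "
    f"r_frz={point.r_signed:+.2f} -> {label}"
)
print(
    "\nThe three ratios are each term's signed share of the total "
    "composition (absolute values sum to 1).  A neutral stack with "
    "attractive electrostatics but a repulsive frozen energy is typed "
    "vdw_cfh: dispersion-vs-Pauli, not quadrupole repulsion, governs it."
)
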