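"""Quantum-yield competition for the four benchmark Ag_N-DNA emitters.

Loads the packaged descriptors (guanine and inosine variants of the Ag16 and
Ag10 cluster emitters), assembles the three S1 decay channels and prints the
yield table.  QYF is the percentage of excitations that leave as fluorescence
photons; the rest branch into the dark triplet (phi_ISC) or heat (phi_IC).
"""

from agphot import load_table1_fixtures, yield_table

table = yield_table(load_table1_fixtures())
cols = ["name", "k_r", "k_isc", "k_ic", "qyf_percent", "lifetime_s"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    "\nInosine-substituted emitters have weaker spin-orbit coupling, slower "
    "intersystem crossing, and therefore the higher fluorescence quantum yield."
)
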