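"""Summary statistics over the packaged experimental interaction table.

Loads the published double-mutant-cycle energies for GB3 and D+PHS and
summarizes the methyl-aromatic (C-H...pi) and amide-aromatic (N-H...pi)
interactions separately.
"""

from xhpi import summarize_interactions
from xhpi import io as xio

for kind, name in (("CH_pi", "C-H...pi"), ("NH_pi", "N-H...pi")):
    cycles = xio.reference_cycles(kind)
    s = summarize_interactions(cycles, kind)
    print(f"{name}: {s.count} pairs, {s.n_favorable} favorable (ddG < 0), "
          f"range [{s.min:+.2f}, {s.max:+.2f}] kcal/mol, mean {s.mean:+.3f}")
# Negative ddG marks a stabilizing interaction; the few small positive
# values reflect residual secondary interactions of the non-alanine
# mutations, a known caveat of the cycle construction.
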