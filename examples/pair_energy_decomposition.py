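"""Nonbonded pair energies and the mutant-box energy decomposition.

Computes the Coulomb/eps + Lennard-Jones interaction between a methyl donor
and an aromatic ring across a range of separations (toy parameter set,
eps = 4), then demonstrates the box algebra: ddE cancellation, the
eight-variant dddE identity, and the percentagewise cooperativity.
"""

from xhpi import (EnsembleSpec, dddE, dde, generate_xhpi_ensemble,
                  pair_energy, percent_cooperativity)
from xhpi import io as xio

params = xio.load_toy_params()

print("distance scan (methyl vs ring, omega = 160 deg):")
energies = {}
for d in (0.40, 0.45, 0.50, 0.55, 0.60):
    spec = EnsembleSpec(d_target=d, omega_target=160.0, jitter_sd=0.0)
    ens = generate_xhpi_ensemble(spec)
    pe = pair_energy(ens, ens[0].res_id == 1, ens[0].res_id == 2, params,
                     epsilon_eff=4.0, pair_label=f"d={d:.2f}")
    energies[d] = pe
    print(f"  d = {d:.2f} nm: E = {pe.e_total:+.3f} kcal/mol "
          f"(coul {pe.e_coul:+.3f}, LJ {pe.e_lj:+.3f})")
# The interaction weakens monotonically as the contact lengthens over the
# 0.4-0.6 nm range where folded-protein XH...pi pairs cluster.

# Alanine-truncation cycle: removing either partner zeroes its energies,
# so ddE collapses to the intact-pair energy.
intact = energies[0.45]
cycle = dde(intact, None, None, None, pair_label="donor-ring")
print(f"\nddE with truncated partners = {cycle.dde:+.3f} kcal/mol "
      f"(equals the intact pair energy)")

# Planted three-body term: eight variant energies whose box combination
# isolates the planted +0.10 kcal/mol.
vals = {k: -1.0 for k in ("xyz", "x'yz", "xy'z", "x'y'z",
                          "xyz'", "x'yz'", "xy'z'", "x'y'z'")}
vals["xyz"] += 0.10
box = dddE(vals, triple_label="toy", interactions=(-0.45, -0.55))
print(f"dddE = {box.ddde:+.3f} kcal/mol, percentagewise = "
      f"{100 * box.percentagewise:+.0f}% of the mean pair interaction")
print(f"(independent check: {percent_cooperativity(0.10, -0.45, -0.55):+.2%})")
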