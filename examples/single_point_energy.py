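"""Single-point AMBER energy of a small synthetic molecule.

Builds a 10-atom bonded chain from the canonical parameter palette and
evaluates every term class of the Hamiltonian.  The printed numbers are
kcal/mol; their sum is the unpartitioned total energy E_system.
"""

from energysplit import FixtureSpec, make_fixture, total_energy

system = make_fixture(FixtureSpec("chain", 10))
totals = total_energy(system)

print(f"atoms: {system.n_atoms}, bonds: {len(system.terms.bonds)}, "
      f"angles: {len(system.terms.angles)}, torsions: {len(system.terms.torsions)}")
for name, value in totals.as_dict().items():
    print(f"{name:>12s}: {value:12.6f} kcal/mol")
print(f"{'E_system':>12s}: {totals.total:12.6f} kcal/mol")
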