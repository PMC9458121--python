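"""Partition a 30-atom system into two fragments plus the remainder.

Atoms 1-10 form fragment "0" and atoms 15-25 fragment "1"; everything else
(atoms 0, 11-14, 26-29) falls into the automatic remainder fragment "X".
Each bucket below is either a fragment self-energy (all atoms of the term
inside one fragment) or an interaction energy between fragments; the sum
of all buckets reconstructs E_system exactly.
"""

from energysplit import (
    FixtureSpec,
    assign_fragments,
    make_fixture,
    partitioned_energy,
    total_energy,
    write_report,
)

system = make_fixture(FixtureSpec("random", 30, seed=5))
scheme = assign_fragments({"0": range(1, 11), "1": range(15, 26)}, system.n_atoms)
report = partitioned_energy(system, scheme)

print(write_report(report, "text"))
residual = abs(total_energy(system).total - report.total_energy)
print(f"reconstruction residual |E_system - sum of buckets| = {residual:.2e} kcal/mol")
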