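"""Simulate a melon-sized half-diallel trial with known genetic truth.

Eight parents crossed without reciprocals (28 F1 hybrids), selfed parents
included, three blocks, six environments.  The generator draws GCA, SCA,
G x E and plot-error effects from the requested variance components, so
every downstream estimate can be compared against the truth it came from.
"""

from diallelkit import SimulationSpec, default_design, simulate_diallel

design = default_design(method="method2")
spec = SimulationSpec(design=design, delta_self=-1.5, seed=42)
records, truth = simulate_diallel(spec)

print(f"records: {len(records)} plots "
      f"({design.n_entries} entries x {design.n_reps} blocks x "
      f"{len(design.environments)} environments)")
print("\ntrue GCA effects (kg/plant, sum to zero):")
print(truth.g.round(3).to_string())
print(f"\nself penalty delta = {truth.delta_self} kg/plant "
      "(negative -> inbreeding depression -> hybrids outyield parents)")
print("\nfirst plots:")
print(records.head(6).to_string(index=False))
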