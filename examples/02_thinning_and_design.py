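"""Spatial rarefaction and the presence/background design table.

Occurrence records closer than 10 km are greedily thinned (reducing spatial
autocorrelation from uneven collection effort); the survivors are paired
with a uniform background sample of up to 10,000 cells to form the
presence/background design that the maximum-entropy model consumes.
"""

from qregions import OccurrenceSet, assemble_design, rarefy
from qregions.synth import SyntheticScenario, generate_bundle

bundle = generate_bundle(SyntheticScenario(seed=1))
occ = OccurrenceSet(bundle.presences)

thinned = rarefy(occ, radius_km=10.0)
print(f"thinning: {len(occ)} records -> {len(thinned)} "
      f"(every pair now >= 10 km apart)")

design = assemble_design(thinned, bundle.env, background_n=10000, seed=7)
print(f"design table: {len(design.presence)} presence rows, "
      f"{design.background_n} background rows, "
      f"{len(design.variables)} variables")
print(f"dropped during extraction: {design.n_dropped_presence} presences")
# The background defines the model's 'universe': raw maxent output is a
# probability distribution over exactly these cells.
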