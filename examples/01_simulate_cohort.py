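"""Generate a synthetic circRNA cohort with planted ground truth.

Writes a toy genome, refFlat gene models, per-sample chimeric junction files
(total-RNA and polyA+ libraries) and a truth sidecar into ./example_run/sim.
"""

from circsieve import SimulationConfig, simulate
from circsieve.simulate import read_truth

config = SimulationConfig(seed=7)
paths = simulate(config, "example_run/sim")

circ, artifacts = read_truth(paths["truth"])
print(f"samples: {len(config.samples)} "
      f"({len(config.total_samples)} total-RNA, {len(config.polya_samples)} polyA+)")
print(f"planted circles: {len(circ)} "
      f"({sum(p.circ_type == 'exonic' for p in circ)} exonic, "
      f"{sum(p.circ_type == 'ciRNA' for p in circ)} ciRNA lariats)")
print(f"planted polyA+ artifacts: {len(artifacts)}")
print(f"annotation: {paths['annotation']}")
# The planted circles are what a correct caller + filter chain must recover;
# the artifacts are back-splice-shaped junctions that only the polyA+
# subtraction can remove.
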