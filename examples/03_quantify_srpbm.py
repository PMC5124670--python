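"""Normalise junction support to SRPBM and assemble the expression matrix.

SRPBM = raw junction reads / total mapped reads x 1e9. NA cells mark a
junction never observed in that sample (distinct from a read count of 0).
"""

from pathlib import Path

from circsieve import RunConfig, SimulationConfig, simulate, srpbm
from circsieve.pipeline import detect, filter_candidates, quantify

print(f"srpbm(3 reads, 15M mapped) = {srpbm(3, 1.5e7):.0f}")

paths = simulate(SimulationConfig(seed=7), "example_run/sim")
config = RunConfig(sample_sheet=paths["sample_sheet"],
                   annotation=paths["annotation"],
                   outdir=Path("example_run/out"), tolerance=0)
matrix = quantify(filter_candidates(detect(config), config), config)

print(f"matrix: {matrix.values.shape[0]} junctions x "
      f"{matrix.values.shape[1]} samples ({matrix.unit})")
print(matrix.values.iloc[:4, :3].round(1).to_string())
# Each cell is that sample's depth-normalised read support for the junction;
# comparable across samples of different sequencing depth.
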