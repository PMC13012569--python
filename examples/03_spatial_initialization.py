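"""Initialize agent positions from an annotated spot table.

Generates a synthetic spot table (hexagonal lattice with a tumor core,
fibroblast collar, ECM column, and inert scaffold — the structure of an
annotated spatial-transcriptomics section), maps it into a simulation domain
with an aspect-ratio-preserving affine transform, and rasterizes the ECM.
"""

import numpy as np

from cellgrammar import FixtureGenerator, generate_fixture, map_spatial_table
from cellgrammar.initialization import rasterize_ecm
from cellgrammar.microenv import Domain

table = generate_fixture(FixtureGenerator("spot_table", seed=7,
                                          params=dict(n_spots=400)))
print("spot table:", len(table), "spots;",
      table["cell_type"].value_counts().to_dict())

domain = Domain(-500, 500, -500, 500, voxel_size=20.0)
positions, labels, ecm = map_spatial_table(table, domain)
print(f"mapped into domain: x in [{positions[:, 0].min():.0f}, "
      f"{positions[:, 0].max():.0f}] um, y in [{positions[:, 1].min():.0f}, "
      f"{positions[:, 1].max():.0f}] um (aspect ratio preserved)")

ecm_grid = rasterize_ecm(positions, ecm, domain)
print(f"ECM field: {ecm_grid.shape[0]}x{ecm_grid.shape[1]} voxels, "
      f"density {ecm_grid.min():.2f}..{ecm_grid.max():.2f} "
      f"(densest around the fibroblast collar)")
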