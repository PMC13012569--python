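"""The two calibration procedures on synthetic data.

(1) Biphasic combined-Hill fit: migration speed versus ECM density rises
    then falls; the same density feeds one increasing and one decreasing
    Hill term and bounded least squares recovers the generating parameters.
(2) Layer-thickness calibration: a grid search over the stem-cell cycling
    rate of the layered-growth model minimizes the residual sum of squares
    of per-layer thicknesses against a reference column.
"""

import numpy as np

from cellgrammar import (
    FixtureGenerator,
    build_scenario,
    calibrate_layers,
    fit_biphasic_hill,
    generate_fixture,
    layer_thickness,
)
from cellgrammar.scenarios import CORTICAL_LAYERS

# -- biphasic Hill fit -------------------------------------------------------
data = generate_fixture(FixtureGenerator("motility_dataset", seed=11,
                                         params=dict(noise=0.02)))
fit = fit_biphasic_hill(data["density"], data["speed"])
print("biphasic fit (truth: bM=0.8, up 0.3^2.0, down 1.2^4.0):")
print(f"  bM={fit['max_value']:.3f}  up {fit['up_half_max']:.3f}^{fit['up_power']:.2f}"
      f"  down {fit['down_half_max']:.3f}^{fit['down_power']:.2f}"
      f"  rss={fit['rss']:.2e}")

# -- layer calibration --------------------------------------------------------
reference = generate_fixture(FixtureGenerator("layer_reference", seed=0))
print("\nreference thicknesses (um):",
      {k.replace(" neuron", ""): v for k, v in reference.items()})


def runner(params, seed):
    sc = build_scenario("cortex", stem_cycle_rate=params["rate"])
    snaps, _ = sc.build(seed=seed).run()
    final = snaps[-1]
    th, _ = layer_thickness(final.positions, final.cell_types, CORTICAL_LAYERS, axis=1)
    return th


best, rss, table = calibrate_layers(runner, reference,
                                    {"rate": [0.01, 0.02, 0.04]}, replicates=2)
for row in table:
    print(f"  rate {row['rate']:.3f}: mean RSS {row['rss']:9.1f} um^2")
print(f"best stem cycling rate: {best['rate']} (RSS {rss:.1f})")
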