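# cellgrammar

Plain-language hypotheses about cell behavior — "In tumor cells, oxygen
decreases necrosis" — compiled into executable mathematics and run as an
off-lattice multicellular agent-based simulation coupled to a
reaction–diffusion microenvironment.

The package is for systems biologists and modelers who want to encode
cell-scale hypotheses (from literature, expert knowledge, or annotated
single-cell / spatial data) as one-line rules, simulate the resulting
multicellular dynamics, and quantify, perturb, and calibrate the model
without writing simulation code.

## The model

Each rule modulates one behavioral parameter *b* of one cell type as a
function of a signal *s* through a saturating response R(s) ∈ [0, 1):

> b(s) = b₀ + (b_M − b₀) · R(s),  with Hill response R(s) = (s/s*)ᵖ / (1 + (s/s*)ᵖ)

where b₀ is the base value, b_M the saturation value, s* the half-max, and
p the Hill power. When several rules target the same behavior, up- and
down-regulating signals pool into multivariate Hill responses

> U = Σᵢ(uᵢ/uᵢ*)^pᵢ / (1 + Σᵢ(uᵢ/uᵢ*)^pᵢ),  D likewise over the dⱼ,

combined bilinearly:

> b(u, d) = (1 − D)·[(1 − U)·b₀ + U·b_M] + D·b_m.

With a single up rule this reduces exactly to the Hill curve above; adding or
removing rules never requires changing the others. Rules live in an 8-column
CSV (cell type, signal, direction, behavior, saturation, half-max, Hill
power, applies-to-dead) validated against signal/behavior dictionaries that
auto-register entries for every substrate and cell type in the model.

Cell agents carry phenotype parameters (cycling, death, motility, secretion,
uptake, attack, phagocytosis, transformation, asymmetric division), read
signals from their surroundings (substrate concentrations and gradients,
mechanical pressure, cell–cell contact, damage, time), and re-evaluate their
behaviors through the compiled rules each phenotype step. Diffusible
substrates evolve by an unconditionally stable implicit operator-split
solver with per-cell secretion and uptake.

Seven bundled scenarios reproduce classic tumor-ecosystem models at desk
scale: hypoxia-driven migration, fibroblast/ECM-driven EMT in pancreatic
cancer, two tumor–immune models with plastic macrophage polarization and
CD8 exhaustion, macrophage-EGF-driven invasion, a virtual immunotherapy
trial over PD-1/PD-L1/CD137-stratified compositions, and cortical layer
formation by asymmetric stem-cell division. Metrics (population AUC, radial
distributions and their Wasserstein distance, invasive-projection counts,
layer thickness), multiplicative-perturbation sensitivity sweeps, and two
calibration procedures (biphasic combined-Hill fit; layer-thickness RSS
grid search) complete the toolkit.

## Worked example

```python
from cellgrammar import Vocabulary, compile_ruleset, parse_rules_csv
from cellgrammar.responses import evaluate_behavior

vocab = Vocabulary(substrates=["oxygen"], cell_types=["tumor"])
rules = parse_rules_csv("tumor,oxygen,increases,cycle entry,0.0005,5.0,4,0", vocab)
resp = compile_ruleset(rules, {"tumor": {"cycle entry": 0.0}})["tumor"]["cycle entry"]
for oxygen in (0.0, 5.0, 38.0):
    print(oxygen, evaluate_behavior(resp, {"oxygen": oxygen}))
```

prints

```
0.0 0.0
5.0 0.00025
38.0 0.0004998290319305278
```

— the cycle-entry rate rises from 0 through half the saturation (0.00025
1/min) at the 5.0 mmHg half-max toward the 0.0005 1/min saturation at
physioxia. Running the hypoxia scenario end to end
(`python examples/02_run_hypoxia.py`) prints population curves ending, at
seed 1, with 309 live non-motile and 146 live motile tumor cells, a
necrotic core of 37 agents, an interior oxygen minimum of 6.8 mmHg, and a
55 µm Wasserstein distance between the motile and non-motile radial
distributions — the motile phenotype concentrated around the hypoxic
interior where it is induced.

The `examples/` directory holds one short script per capability (rule
parsing, scenario runs, data-driven initialization, sensitivity,
calibration, the virtual trial). A thin CLI mirrors the common entry
points: `cellgrammar run|validate|render|sweep --help`.

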