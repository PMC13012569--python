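"""From a plain-language hypothesis row to an executable dose response.

Parses one rule written in the 8-column CSV dialect, renders it back as an
English sentence, and evaluates the compiled behavior response at a few
signal levels.
"""

from cellgrammar import Vocabulary, compile_ruleset, parse_rules_csv, render_rule_english
from cellgrammar.responses import evaluate_behavior

ROW = "tumor,oxygen,increases,cycle entry,0.0005,5.0,4,0"

vocab = Vocabulary(substrates=["oxygen"], cell_types=["tumor"])
rules = parse_rules_csv(ROW, vocab)
print("hypothesis :", render_rule_english(rules.rules[0], "verbose"))

compiled = compile_ruleset(rules, {"tumor": {"cycle entry": 0.0}})
response = compiled["tumor"]["cycle entry"]

for oxygen in (0.0, 2.5, 5.0, 10.0, 38.0, 5000.0):
    rate = evaluate_behavior(response, {"oxygen": oxygen})
    print(f"oxygen {oxygen:7.1f} mmHg -> cycle entry {rate:.6f} 1/min")

# The rate rises sigmoidally from the base value 0: half the printed
# saturation (0.00025) at the half-max 5.0 mmHg, and saturating at the
# printed 0.0005 1/min for large oxygen.
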