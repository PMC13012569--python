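"""Hypothesis-rule grammar: parse, validate, render, export, and compile.

A rule is one plain-language hypothesis, "In T, S increases/decreases B",
stored as one CSV row with eight fields::

    cell type, signal, response, behavior, saturation value, half-max,
    Hill power, applies to dead?

Rules are validated against signal and behavior dictionaries generated from
the model's substrates and cell types, and compiled into per-(cell type,
behavior) :class:`~cellgrammar.responses.BehaviorResponse` objects.
"""

from __future__ import annotations

import enum
import html as _html
import io
from dataclasses import dataclass, field, replace

from .responses import BehaviorResponse, RuleTerm

__all__ = [
    "Direction",
    "Rule",
    "RuleSet",
    "Vocabulary",
    "parse_rules_csv",
    "render_rule_english",
    "export_rules",
    "compile_ruleset",
    "RuleParseError",
    "RuleValidationError",
]


class RuleParseError(ValueError):
    pass


class RuleValidationError(ValueError):
    pass


class Direction(str, enum.Enum):
    INCREASES = "increases"
    DECREASES = "decreases"


# behaviors every cell type has regardless of the model's substrates
CORE_BEHAVIORS = {
    "cycle entry": "1/min",
    "apoptosis": "1/min",
    "necrosis": "1/min",
    "migration speed": "um/min",
    "migration bias": "dimensionless",
    "migration persistence time": "min",
    "damage rate": "1/min",
    "phagocytose dead cell": "1/min",
    "cell-cell adhesion strength": "um/min",
    "cell-cell repulsion strength": "um/min",
}

CORE_SIGNALS = {
    "pressure": "dimensionless",
    "volume": "um^3",
    "damage": "a.u.",
    "time": "min",
    "dead": "boolean",
    "contact with dead cell": "count",
}


def _norm(s: str) -> str:
    """Whitespace normalization: strip and collapse internal runs."""
    return " ".join(str(s).split())


@dataclass(frozen=True)
class Rule:
    """One parsed hypothesis row."""

    cell_type: str
    signal: str
    direction: Direction
    behavior: str
    saturation_value: float
    half_max: float
    hill_power: float
    applies_to_dead: bool = False
    source_row: int | None = None

    def __post_init__(self):
        if self.half_max <= 0:
            raise RuleParseError(f"half_max must be positive, got {self.half_max}")
        if self.hill_power <= 0:
            raise RuleParseError(f"hill_power must be positive, got {self.hill_power}")


class Vocabulary:
    """Signal and behavior dictionaries for a model.

    Built from the model's substrate names and cell-type names: every
    substrate registers signals "<substrate>" and "<substrate> gradient" and
    behaviors "<substrate> secretion" and "<substrate> uptake"; every cell
    type registers the signal "contact with <type>" and the behaviors
    "transform to <type>", "attack <type>", and "phagocytose <type>".
    """

    def __init__(self, substrates=(), cell_types=()):
        self.substrates = [_norm(s) for s in substrates]
        self.cell_types = [_norm(c) for c in cell_types]
        self.signals: dict[str, str] = dict(CORE_SIGNALS)
        self.behaviors: dict[str, str] = dict(CORE_BEHAVIORS)
        for s in self.substrates:
            self.signals[s] = "substrate concentration"
            self.signals[f"{s} gradient"] = "substrate units/um"
            self.behaviors[f"{s} secretion"] = "1/min"
            self.behaviors[f"{s} uptake"] = "1/min"
        for c in self.cell_types:
            self.signals[f"contact with {c}"] = "count"
            self.behaviors[f"transform to {c}"] = "1/min"
            self.behaviors[f"attack {c}"] = "1/min"
            self.behaviors[f"phagocytose {c}"] = "1/min"

    def canonical_behavior(self, name: str) -> str | None:
        """Resolve a behavior name, accepting 'transition to X' as a synonym
        of 'transform to X'.  Returns the canonical identifier or None."""
        name = _norm(name)
        if name in self.behaviors:
            return name
        if name.startswith("transition to "):
            alt = "transform to " + name[len("transition to "):]
            if alt in self.behaviors:
                return alt
        return None

    def has_signal(self, name: str) -> bool:
        return _norm(name) in self.signals

    def has_cell_type(self, name: str) -> bool:
        return _norm(name) in self.cell_types


@dataclass
class RuleSet:
    """An ordered collection of rules with parse provenance."""

    rules: list[Rule] = field(default_factory=list)
    source: str | None = None

    def __len__(self):
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def __eq__(self, other):
        if not isinstance(other, RuleSet):
            return NotImplemented
        strip = lambda rs: [replace(r, source_row=None) for r in rs.rules]
        return strip(self) == strip(other)

    def for_cell_type(self, cell_type: str) -> list[Rule]:
        cell_type = _norm(cell_type)
        return [r for r in self.rules if r.cell_type == cell_type]

    def to_csv(self) -> str:
        """Serialize back to the 8-column CSV dialect (no header)."""
        out = io.StringIO()
        for r in self.rules:
            out.write(
                f"{r.cell_type},{r.signal},{r.direction.value},{r.behavior},"
                f"{r.saturation_value:g},{r.half_max:g},{r.hill_power:g},"
                f"{int(r.applies_to_dead)}\n"
            )
        return out.getvalue()


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def parse_rules_csv(path_or_text, vocabulary: Vocabulary | None = None) -> RuleSet:
    """Parse a rules CSV (path, file object, or literal text) into a RuleSet.

    Each data row must have exactly eight comma-separated fields.  A header
    row is auto-detected by a non-numeric fifth field.  When a vocabulary is
    given, unknown cell types, signals, and behaviors are collected and
    reported in a single validation error.
    """
    source = None
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        s = str(path_or_text)
        if "," in s or "\n" in s or not s.strip():
            text = s
        else:
            source = s
            with open(s, encoding="utf-8") as fh:
                text = fh.read()

    rules: list[Rule] = []
    problems: list[str] = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [_norm(f) for f in line.split(",")]
        if len(fields) != 8:
            raise RuleParseError(f"row {i}: expected 8 columns, got {len(fields)}")
        if i == 1 and not _is_number(fields[4]):
            continue  # header row
        ct, sig, resp, beh, sat, hfm, hp, dead = fields
        try:
            direction = Direction(resp)
        except ValueError:
            problems.append(f"row {i}: unknown response {resp!r} (use increases/decreases)")
            continue
        if vocabulary is not None:
            if not vocabulary.has_cell_type(ct):
                problems.append(
                    f"row {i}: unknown cell type {ct!r}; known: {sorted(vocabulary.cell_types)}"
                )
            if not vocabulary.has_signal(sig):
                problems.append(
                    f"row {i}: unknown signal {sig!r}; known: {sorted(vocabulary.signals)}"
                )
            canon = vocabulary.canonical_behavior(beh)
            if canon is None:
                problems.append(
                    f"row {i}: unknown behavior {beh!r}; known: {sorted(vocabulary.behaviors)}"
                )
            else:
                beh = canon
        try:
            rule = Rule(
                cell_type=ct,
                signal=sig,
                direction=direction,
                behavior=beh,
                saturation_value=float(sat),
                half_max=float(hfm),
                hill_power=float(hp),
                applies_to_dead=bool(int(float(dead))),
                source_row=i,
            )
        except (ValueError, RuleParseError) as exc:
            raise RuleParseError(f"row {i}: {exc}") from None
        rules.append(rule)
    if problems:
        raise RuleValidationError("; ".join(problems))
    return RuleSet(rules=rules, source=source)


def render_rule_english(rule: Rule, verbosity: str = "terse") -> str:
    """Render a rule as its plain-language hypothesis sentence."""
    base = f"In {rule.cell_type}, {rule.signal} {rule.direction.value} {rule.behavior}"
    if verbosity == "terse":
        return base
    return (
        f"{base} with half-max {rule.half_max:g} and Hill power {rule.hill_power:g}"
        f" (saturation {rule.saturation_value:g}"
        + (", applies to dead cells)" if rule.applies_to_dead else ")")
    )


def export_rules(rs: RuleSet, format: str = "text") -> str:
    """Deterministic full description of a rule set, grouped by cell type."""
    by_type: dict[str, list[Rule]] = {}
    for r in rs.rules:
        by_type.setdefault(r.cell_type, []).append(r)
    if format == "text":
        lines = [f"Rule set ({len(rs.rules)} rules)", ""]
        for ct in sorted(by_type):
            lines.append(f"{ct}:")
            for r in by_type[ct]:
                lines.append("  - " + render_rule_english(r, "verbose"))
            lines.append("")
        return "\n".join(lines)
    if format == "html":
        parts = [
            "<!DOCTYPE html>",
            "<html><head><title>Cell hypothesis rules</title></head><body>",
            f"<h1>Rule set ({len(rs.rules)} rules)</h1>",
        ]
        for ct in sorted(by_type):
            parts.append(f"<h2>{_html.escape(ct)}</h2><ul>")
            for r in by_type[ct]:
                parts.append("<li>" + _html.escape(render_rule_english(r, "verbose")) + "</li>")
            parts.append("</ul>")
        parts.append("</body></html>")
        return "\n".join(parts)
    raise ValueError(f"unknown export format {format!r} (use 'text' or 'html')")


def compile_ruleset(rs: RuleSet, model_phenotypes) -> dict[str, dict[str, BehaviorResponse]]:
    """Compile rules into BehaviorResponse objects keyed by cell type then
    behavior.

    ``model_phenotypes`` maps cell type -> {behavior -> base value b0}.  The
    saturation of a pooled response is the maximum over increase-rule
    saturations (bM) and the minimum over decrease-rule saturations (bm).
    """
    compiled: dict[str, dict[str, BehaviorResponse]] = {}
    grouped: dict[tuple[str, str], list[Rule]] = {}
    for r in rs.rules:
        grouped.setdefault((r.cell_type, r.behavior), []).append(r)
    for (ct, beh), rules in grouped.items():
        if ct not in model_phenotypes:
            raise RuleValidationError(f"rule targets undefined cell type {ct!r}")
        pheno = model_phenotypes[ct]
        if beh not in pheno:
            raise RuleValidationError(
                f"cell type {ct!r} has no base value for behavior {beh!r}"
            )
        b0 = float(pheno[beh])
        ups = [r for r in rules if r.direction is Direction.INCREASES]
        downs = [r for r in rules if r.direction is Direction.DECREASES]
        resp = BehaviorResponse(
            behavior=beh,
            base_value=b0,
            max_value=max(r.saturation_value for r in ups) if ups else None,
            min_value=min(r.saturation_value for r in downs) if downs else None,
            up_terms=[
                RuleTerm(r.signal, r.half_max, r.hill_power, r.applies_to_dead) for r in ups
            ],
            down_terms=[
                RuleTerm(r.signal, r.half_max, r.hill_power, r.applies_to_dead) for r in downs
            ],
            sources=[r.source_row for r in ups + downs],
        )
        compiled.setdefault(ct, {})[beh] = resp
    return compiled
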