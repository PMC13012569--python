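"""Rule parsing, validation, English rendering, export, and compilation."""

import pytest

from cellgrammar.grammar import (
    Direction,
    Rule,
    RuleParseError,
    RuleValidationError,
    Vocabulary,
    compile_ruleset,
    export_rules,
    parse_rules_csv,
    render_rule_english,
)

EXAMPLE_ROW = "tumor,oxygen,increases,cycle entry,0.0005,5.0,4,0"


@pytest.fixture
def vocab():
    return Vocabulary(substrates=["oxygen"], cell_types=["tumor", "motile tumor"])


class TestParse:
    def test_worked_example_row(self, vocab):
        rs = parse_rules_csv(EXAMPLE_ROW, vocab)
        (rule,) = rs.rules
        assert rule.cell_type == "tumor"
        assert rule.signal == "oxygen"
        assert rule.direction is Direction.INCREASES
        assert rule.behavior == "cycle entry"
        assert rule.saturation_value == 0.0005
        assert rule.half_max == 5.0
        assert rule.hill_power == 4.0
        assert rule.applies_to_dead is False

    def test_empty_input_gives_empty_ruleset(self, vocab):
        assert len(parse_rules_csv("", vocab)) == 0

    def test_header_autodetected_by_nonnumeric_fifth_field(self, vocab):
        text = ("cell type,signal,response,behavior,saturation,half-max,power,dead\n"
                + EXAMPLE_ROW + "\n")
        assert len(parse_rules_csv(text, vocab)) == 1

    def test_unknown_signal_is_named(self, vocab):
        with pytest.raises(RuleValidationError, match="unknown_factor"):
            parse_rules_csv("tumor,unknown_factor,increases,cycle entry,1,1,1,0", vocab)

    def test_unknown_cell_type_and_behavior_reported(self, vocab):
        with pytest.raises(RuleValidationError, match="martian"):
            parse_rules_csv("martian,oxygen,increases,cycle entry,1,1,1,0", vocab)
        with pytest.raises(RuleValidationError, match="levitation"):
            parse_rules_csv("tumor,oxygen,increases,levitation,1,1,1,0", vocab)

    def test_wrong_column_count_reports_row(self, vocab):
        with pytest.raises(RuleParseError, match="row 1"):
            parse_rules_csv("tumor,oxygen,increases,cycle entry,0.0005", vocab)

    def test_nonpositive_parameters_rejected(self, vocab):
        with pytest.raises(RuleParseError):
            parse_rules_csv("tumor,oxygen,increases,cycle entry,1,-5,4,0", vocab)
        with pytest.raises(RuleParseError):
            parse_rules_csv("tumor,oxygen,increases,cycle entry,1,5,0,0", vocab)

    def test_transition_synonym_canonicalized(self, vocab):
        rs = parse_rules_csv(
            "tumor,oxygen,decreases,transition to motile tumor,0,5,4,0", vocab)
        assert rs.rules[0].behavior == "transform to motile tumor"

    def test_roundtrip_through_csv(self, vocab):
        text = (EXAMPLE_ROW + "\n"
                "motile tumor,oxygen,decreases,necrosis,0.001,3.75,8,1\n")
        rs = parse_rules_csv(text, vocab)
        again = parse_rules_csv(rs.to_csv(), vocab)
        assert again == rs


class TestRender:
    @pytest.mark.parametrize(
        "cell,signal,direction,behavior,expected",
        [
            ("naïve T cells", "IL-10", "decreases", "transition to CD8 T cells",
             "In naïve T cells, IL-10 decreases transition to CD8 T cells"),
            ("MCF-7 breast cancer cells", "cisplatin", "increases", "apoptosis",
             "In MCF-7 breast cancer cells, cisplatin increases apoptosis"),
        ],
    )
    def test_plain_language_sentences(self, cell, signal, direction, behavior, expected):
        rule = Rule(cell, signal, Direction(direction), behavior, 1.0, 1.0, 1.0)
        assert render_rule_english(rule) == expected

    def test_verbose_appends_optional_arguments(self):
        rule = Rule("tumor", "oxygen", Direction.INCREASES, "cycle entry",
                    0.0005, 5.0, 4.0)
        verbose = render_rule_english(rule, "verbose")
        assert "half-max 5" in verbose and "Hill power 4" in verbose

    def test_render_parse_roundtrip_of_qualitative_fields(self, vocab):
        rs = parse_rules_csv(EXAMPLE_ROW, vocab)
        sentence = render_rule_english(rs.rules[0])
        # "In <ct>, <sig> <dir> <behavior>" carries the qualitative fields
        assert sentence == "In tumor, oxygen increases cycle entry"


class TestExport:
    def test_empty_ruleset_document(self, vocab):
        rs = parse_rules_csv("", vocab)
        doc = export_rules(rs, "text")
        assert "0 rules" in doc

    def test_text_contains_sentence_and_parameters(self, vocab):
        rs = parse_rules_csv(EXAMPLE_ROW, vocab)
        doc = export_rules(rs, "text")
        assert "In tumor, oxygen increases cycle entry" in doc
        for token in ("0.0005", "5", "4"):
            assert token in doc

    def test_exports_deterministic(self, vocab):
        rs = parse_rules_csv(EXAMPLE_ROW + "\ntumor,oxygen,decreases,necrosis,0,4,8,0",
                             vocab)
        assert export_rules(rs, "text") == export_rules(rs, "text")
        assert export_rules(rs, "html") == export_rules(rs, "html")

    def test_html_well_formed(self, vocab):
        import xml.etree.ElementTree as ET

        rs = parse_rules_csv(EXAMPLE_ROW, vocab)
        html = export_rules(rs, "html")
        body = html.split("\n", 1)[1]  # drop doctype
        ET.fromstring(body)  # raises if not well-formed


class TestCompile:
    def test_max_of_increase_saturations(self, vocab):
        text = ("tumor,oxygen,increases,cycle entry,0.1,5,4,0\n"
                "tumor,oxygen gradient,increases,cycle entry,0.2,1,2,0\n")
        for flipped in (False, True):
            rows = text.strip().split("\n")
            rs = parse_rules_csv("\n".join(rows[::-1] if flipped else rows), vocab)
            compiled = compile_ruleset(rs, {"tumor": {"cycle entry": 0.01}})
            resp = compiled["tumor"]["cycle entry"]
            assert resp.max_value == 0.2
            assert len(resp.up_terms) == 2

    def test_min_of_decrease_saturations_and_mixed(self, vocab):
        text = ("tumor,oxygen,decreases,necrosis,0.002,5,4,0\n"
                "tumor,pressure,decreases,necrosis,0.001,1,2,0\n"
                "tumor,damage,increases,necrosis,0.05,10,2,0\n")
        rs = parse_rules_csv(text, vocab)
        compiled = compile_ruleset(rs, {"tumor": {"necrosis": 0.01}})
        resp = compiled["tumor"]["necrosis"]
        assert resp.min_value == 0.001
        assert resp.max_value == 0.05
        assert len(resp.up_terms) == 1 and len(resp.down_terms) == 2

    def test_missing_phenotype_is_a_compile_error(self, vocab):
        rs = parse_rules_csv(EXAMPLE_ROW, vocab)
        with pytest.raises(RuleValidationError, match="cycle entry"):
            compile_ruleset(rs, {"tumor": {}})
        with pytest.raises(RuleValidationError, match="tumor"):
            compile_ruleset(rs, {})

    def test_provenance_rows_recorded(self, vocab):
        text = EXAMPLE_ROW + "\ntumor,oxygen,decreases,cycle entry,0,4,8,0\n"
        rs = parse_rules_csv(text, vocab)
        compiled = compile_ruleset(rs, {"tumor": {"cycle entry": 0.0}})
        assert compiled["tumor"]["cycle entry"].sources == [1, 2]


def test_vocabulary_autoregistration():
    v = Vocabulary(substrates=["IL-10"], cell_types=["macrophage"])
    assert "IL-10" in v.signals and "IL-10 gradient" in v.signals
    assert "IL-10 secretion" in v.behaviors and "IL-10 uptake" in v.behaviors
    assert "contact with macrophage" in v.signals
    for beh in ("transform to macrophage", "attack macrophage", "phagocytose macrophage"):
        assert beh in v.behaviors
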