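"""Structured-text rule parsing, evaluation, and transpilation."""

from __future__ import annotations

import itertools
import re

import pytest

from traitscreen import (
    BlockMode,
    Condition,
    RuleBlock,
    RuleSet,
    evaluate_ruleset,
    parse_genotype_literal,
    parse_rule_text,
    parse_script,
    render_rule_text,
    ruleset_to_script,
)
from traitscreen.ruledsl import RuleTextError
from traitscreen.script_engine import evaluate

from conftest import FRUCTOSE_TEXT, FRUCTOSE_TEXT_CURLY, make_store


def lit(text):
    return parse_genotype_literal(text)


class TestParseRuleText:
    @pytest.mark.parametrize("text", [FRUCTOSE_TEXT, FRUCTOSE_TEXT_CURLY])
    def test_fructose_ruleset_shape(self, text):
        rules = parse_rule_text(text)
        assert len(rules.blocks) == 2
        assert all(b.mode is BlockMode.ANY for b in rules.blocks)
        assert [len(b.conditions) for b in rules.blocks] == [3, 3]
        keys = {c.key for b in rules.blocks for c in b.conditions}
        assert keys == {"rs1800546", "rs76917243", "rs78340951"}
        assert [b.trait for b in rules.blocks] == [
            "Fructose Intolerant", "Variant Carrier"]
        assert rules.else_trait == "Tolerant to Fructose"

    def test_minimal_all_block(self):
        rules = parse_rule_text('All:\nrs1 \'AA\'\nrs2 \'GG\'\n== "X"')
        (block,) = rules.blocks
        assert block.mode is BlockMode.ALL
        assert len(block.conditions) == 2
        assert block.trait == "X"
        assert rules.else_trait is None

    def test_keywords_case_insensitive(self):
        for kw in ("any", "ANY", "Any :", "aNy:"):
            rules = parse_rule_text(f'{kw}\nrs1 \'AA\'\n== "T"')
            assert rules.blocks[0].mode is BlockMode.ANY

    def test_comments_and_blank_lines_ignored(self):
        rules = parse_rule_text(
            "# header\n\nAll\n# inside\nrs1 'AA'\n\n== \"T\"\n")
        assert len(rules.blocks[0].conditions) == 1

    def test_condition_outside_block(self):
        with pytest.raises(RuleTextError, match="line 1.*outside"):
            parse_rule_text("rs1 'AA'")

    def test_unclosed_block_at_eof(self):
        with pytest.raises(RuleTextError, match="never closed"):
            parse_rule_text("Any\nrs1 'AA'\n")

    def test_bad_literal_reports_line(self):
        with pytest.raises(RuleTextError, match="line 2"):
            parse_rule_text("Any\nrs1 'TGAT'\n== \"T\"")

    def test_duplicate_else(self):
        with pytest.raises(RuleTextError, match="duplicate"):
            parse_rule_text('else "A"\nelse "B"')

    def test_duplicate_condition_warns_but_keeps(self, caplog):
        with caplog.at_level("WARNING"):
            rules = parse_rule_text('Any\nrs1 \'AA\'\nrs1 \'AA\'\n== "T"')
        assert len(rules.blocks[0].conditions) == 2
        assert any("duplicate condition" in r.message for r in caplog.records)

    def test_risk_extension_syntax(self):
        rules = parse_rule_text('Any\nrs1 \'AA\'\n== "T" risk 0.8')
        assert rules.blocks[0].risk == 0.8
        assert rules.blocks[0].trait == "T"

    def test_else_only_ruleset(self):
        rules = parse_rule_text('else "fine"')
        assert rules.blocks == ()
        assert rules.else_trait == "fine"


class TestEvaluateRuleset:
    @pytest.fixture
    def fructose(self):
        return parse_rule_text(FRUCTOSE_TEXT)

    @pytest.mark.parametrize("genotypes, expected", [
        # homozygous causal at one site
        ({"rs1800546": "G/G", "rs76917243": "G/G", "rs78340951": "G/G"},
         "Fructose Intolerant"),
        # heterozygous carrier
        ({"rs1800546": "C/C", "rs76917243": "G/T", "rs78340951": "G/G"},
         "Variant Carrier"),
        # all homozygous reference
        ({"rs1800546": "C/C", "rs76917243": "G/G", "rs78340951": "G/G"},
         "Tolerant to Fructose"),
    ])
    def test_fructose_outcomes(self, fructose, genotypes, expected):
        result = evaluate_ruleset(fructose, make_store(genotypes))
        assert result.comment == expected
        assert result.risk == 0.0

    def test_first_match_wins_exhaustively(self):
        """Two-block rulesets agree with a hand-rolled sequential oracle
        over every assignment of match/mismatch to four conditions."""
        keys = ["rs1", "rs2", "rs3", "rs4"]
        for modes in itertools.product([BlockMode.ANY, BlockMode.ALL],
                                       repeat=2):
            rules = RuleSet(blocks=(
                RuleBlock(mode=modes[0], trait="first", risk=0.9,
                          conditions=(Condition("rs1", lit("AA")),
                                      Condition("rs2", lit("AA")))),
                RuleBlock(mode=modes[1], trait="second", risk=0.2,
                          conditions=(Condition("rs3", lit("AA")),
                                      Condition("rs4", lit("AA")))),
            ), else_trait="neither")
            for bits in itertools.product([True, False], repeat=4):
                store = make_store({k: ("A/A" if b else "C/C")
                                    for k, b in zip(keys, bits)})
                # independent oracle: explicit sequential first-match walk
                expected = "neither"
                for blk, (x, y) in zip(("first", "second"),
                                       (bits[:2], bits[2:])):
                    mode = modes[0] if blk == "first" else modes[1]
                    fired = (x or y) if mode is BlockMode.ANY else (x and y)
                    if fired:
                        expected = blk
                        break
                assert evaluate_ruleset(rules, store).comment == expected

    def test_pure_and_order_of_dead_blocks_irrelevant(self):
        never = RuleBlock(mode=BlockMode.ALL, trait="dead",
                          conditions=(Condition("rs99", lit("TT")),))
        fires = RuleBlock(mode=BlockMode.ANY, trait="live",
                          conditions=(Condition("rs1", lit("AA")),))
        store = make_store({"rs1": "A/A"})
        a = RuleSet(blocks=(never, fires), else_trait="no")
        b = RuleSet(blocks=(fires, never), else_trait="no")
        assert (evaluate_ruleset(a, store) == evaluate_ruleset(b, store)
                == evaluate_ruleset(a, store))

    def test_no_else_gives_none_comment(self):
        rules = parse_rule_text('Any\nrs1 \'AA\'\n== "T"')
        result = evaluate_ruleset(rules, make_store({"rs1": "C/C"}))
        assert result.comment == "none" and result.risk == 0.0


class TestTranspile:
    def test_fructose_structure(self):
        script = ruleset_to_script(parse_rule_text(FRUCTOSE_TEXT))
        units = re.findall(r"\bif\b", script)
        assert len(units) == 6
        assert len(re.findall(r"\breturn risk, comment\b", script)) == 6
        # trailing default-comment assignment comes after every if-unit
        assert script.rstrip().endswith('comment = "Tolerant to Fructose"')
        # conditions are emitted in slash form
        assert 'rs1800546 == "G/G"' in script
        assert 'rs78340951 == "C/G"' in script

    def test_all_block_single_unit_with_and(self):
        rules = parse_rule_text('All\nrs1 \'AA\'\nrs2 \'GG\'\n== "X"')
        script = ruleset_to_script(rules)
        assert script.count("if ") == 1
        assert script.count(" and ") == 1

    def test_else_only_is_bare_assignment(self):
        script = ruleset_to_script(RuleSet(else_trait="X"))
        assert script.strip() == 'comment = "X"'

    def test_positional_keys_sanitized_in_output(self):
        rules = parse_rule_text('Any\nchr1:16949 \'AC\'\n== "T"')
        script = ruleset_to_script(rules)
        assert 'chr1_16949 == "A/C"' in script
        assert ":" not in script.split("==")[0]

    def test_emitted_script_parses(self):
        rules = parse_rule_text(FRUCTOSE_TEXT)
        program = parse_script(ruleset_to_script(rules))
        assert len(program.statements) == 7  # 6 if-units + comment assignment

    def test_risk_value_carried_through(self):
        rules = parse_rule_text('Any\nrs1 \'AA\'\n== "T" risk 0.8')
        program = parse_script(ruleset_to_script(rules))
        result = evaluate(program, make_store({"rs1": "A/A"}))
        assert result.risk == 0.8 and result.comment == "T"


class TestRender:
    def test_round_trip_identity(self):
        rules = parse_rule_text(FRUCTOSE_TEXT)
        assert parse_rule_text(render_rule_text(rules)) == rules

    def test_round_trip_with_risk_extension(self):
        rules = parse_rule_text('All\nrs1 \'AA\'\n== "T" risk 0.5')
        assert parse_rule_text(render_rule_text(rules)) == rules
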