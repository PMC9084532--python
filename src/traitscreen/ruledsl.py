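"""The structured-text rule dialect: Any/All blocks with an else label.

This is the entry format for users who do not want to write script
code.  A rule file is a sequence of blocks; each block opens with the
keyword ``Any`` or ``All`` (case-insensitive, optional colon), lists
one condition per line (``KEY LITERAL``, e.g. ``rs1800546 'GG'``), and
closes with ``== "Trait label"``.  An optional ``else "Label"`` line
gives the no-match label.  Example::

    Any
    rs1800546 'GG'
    rs76917243 'TT'
    rs78340951 'CC'
    == "Fructose Intolerant"

    Any:
    rs1800546 'C/G'
    rs76917243 'G/T'
    rs78340951 C/G
    == "Variant Carrier"

    else "Tolerant to Fructose"

Blocks are tested in order and the first block whose conditions hold
determines the result (first-match semantics): an ``Any`` block fires
when at least one condition matches, an ``All`` block when every
condition matches.  A :class:`RuleSet` can be evaluated directly
(:func:`evaluate_ruleset`) or transpiled to the script dialect
(:func:`ruleset_to_script`); the two routes are semantically
equivalent by construction.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from typing import Optional

from .genotypes import (
    GenotypeCall,
    GenotypeStore,
    genotype_match,
    parse_genotype_literal,
    sanitize_identifier,
)
from .script_engine import TraitResult

log = logging.getLogger(__name__)

__all__ = [
    "BlockMode", "Condition", "RuleBlock", "RuleSet",
    "parse_rule_text", "evaluate_ruleset", "ruleset_to_script",
    "render_rule_text", "RuleTextError",
]


class RuleTextError(ValueError):
    """A structured-text rule file could not be parsed."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class BlockMode(enum.Enum):
    ANY = "any"
    ALL = "all"


@dataclass(frozen=True)
class Condition:
    """One ``KEY LITERAL`` line: a variant key and the genotype to match."""

    key: str
    literal: GenotypeCall

    def __post_init__(self) -> None:
        sanitize_identifier(self.key)  # raises on malformed keys
        if self.literal.missing:
            raise ValueError("a condition literal cannot be a missing call")


@dataclass(frozen=True)
class RuleBlock:
    mode: BlockMode
    conditions: tuple[Condition, ...]
    trait: str
    risk: float = 0.0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a rule block needs at least one condition")


@dataclass(frozen=True)
class RuleSet:
    blocks: tuple[RuleBlock, ...] = ()
    else_trait: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.blocks and self.else_trait is None:
            raise ValueError("a ruleset needs blocks or an else label")


_KEYWORD_RE = re.compile(r"^(any|all)\s*:?$", re.IGNORECASE)
_ELSE_RE = re.compile(r"^else\s*:?\s+(.+)$", re.IGNORECASE)
_TRAIT_RE = re.compile(r'^==\s*(.+?)\s*$')
# optional extension: a risk value after the trait label
_TRAIT_RISK_RE = re.compile(
    r'^(?P<label>.+?)\s+risk\s+(?P<risk>\d+(?:\.\d+)?|\.\d+)$', re.IGNORECASE
)

_QUOTES = "\"“”"


def _strip_label_quotes(text: str, lineno: int) -> str:
    text = text.strip()
    if text and text[0] in _QUOTES:
        if len(text) < 2 or text[-1] not in _QUOTES:
            raise RuleTextError(f"unterminated quote in {text!r}", lineno)
        text = text[1:-1]
    return text.strip()


def parse_rule_text(text: str) -> RuleSet:
    """Parse a structured-text rule file into a :class:`RuleSet`.

    Blank lines and ``#`` comments are ignored.  Errors carry the line
    number: a condition outside a block, a block left open at the end
    of the file, an unparseable genotype literal, or a duplicate
    ``else`` line.
    """
    blocks: list[RuleBlock] = []
    else_trait: Optional[str] = None
    mode: Optional[BlockMode] = None
    conditions: list[Condition] = []
    block_line = 0

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue

        kw = _KEYWORD_RE.match(line)
        if kw:
            if mode is not None:
                raise RuleTextError(
                    f"block opened at line {block_line} not closed by a "
                    "'== \"Trait\"' line before a new block", lineno)
            mode = BlockMode[kw.group(1).upper()]
            block_line = lineno
            continue

        m = _TRAIT_RE.match(line)
        if m:
            if mode is None:
                raise RuleTextError("'==' trait line outside a block", lineno)
            label_text, risk = m.group(1), 0.0
            ext = _TRAIT_RISK_RE.match(label_text)
            if ext and ext.group("label").rstrip()[-1:] in _QUOTES + "'":
                label_text = ext.group("label")
                risk = float(ext.group("risk"))
            trait = _strip_label_quotes(label_text, lineno)
            if not conditions:
                raise RuleTextError(
                    f"block opened at line {block_line} has no conditions",
                    lineno)
            blocks.append(RuleBlock(
                mode=mode, conditions=tuple(conditions), trait=trait,
                risk=risk))
            mode, conditions = None, []
            continue

        m = _ELSE_RE.match(line)
        if m and mode is None:
            if else_trait is not None:
                raise RuleTextError("duplicate 'else' line", lineno)
            else_trait = _strip_label_quotes(m.group(1), lineno)
            continue

        # condition line: KEY LITERAL
        if mode is None:
            raise RuleTextError(
                f"condition {line!r} outside any Any/All block", lineno)
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise RuleTextError(
                f"expected 'KEY GENOTYPE', got {line!r}", lineno)
        key, literal_text = parts
        try:
            cond = Condition(key=key,
                             literal=parse_genotype_literal(literal_text))
        except ValueError as exc:
            raise RuleTextError(str(exc), lineno) from exc
        if cond in conditions:
            log.warning("line %d: duplicate condition %s %s in block",
                        lineno, key, literal_text)
        conditions.append(cond)

    if mode is not None:
        raise RuleTextError(
            f"block opened at line {block_line} never closed by a "
            "'== \"Trait\"' line", len(text.splitlines()) or 1)
    return RuleSet(blocks=tuple(blocks), else_trait=else_trait)


def evaluate_ruleset(rules: RuleSet, store: GenotypeStore) -> TraitResult:
    """First-match evaluation of a ruleset against a genotype store.

    Blocks are tested in order; the first firing block yields
    ``TraitResult(block.risk, block.trait)``.  If none fires the result
    is the else label (or ``"none"``) with risk 0.0.  Absent or missing
    variants make their condition false; evaluation never raises.
    """
    warned: set[str] = set()

    def holds(cond: Condition) -> bool:
        call = store.lookup(cond.key)
        if (call is None or call.missing) and cond.key not in warned:
            warned.add(cond.key)
            log.warning(
                "variant %s %s in genotype input; condition is false",
                cond.key,
                "is missing" if call is not None else "not found")
        return genotype_match(call, cond.literal)

    for block in rules.blocks:
        tests = (holds(c) for c in block.conditions)
        if any(tests) if block.mode is BlockMode.ANY else all(tests):
            return TraitResult(risk=block.risk, comment=block.trait)
    if rules.else_trait is not None:
        return TraitResult(risk=0.0, comment=rules.else_trait)
    return TraitResult()


def _condition_src(cond: Condition) -> str:
    return (f'{sanitize_identifier(cond.key)} == '
            f'"{"/".join(cond.literal.alleles)}"')


def _block_units(block: RuleBlock) -> list[str]:
    body = [f'comment = "{block.trait}"']
    if block.risk:
        body.insert(0, f"risk = {block.risk}")
    body.append("return risk, comment")
    inner = "\n".join(f"   {s}" for s in body)
    if block.mode is BlockMode.ALL:
        cond = " and ".join(_condition_src(c) for c in block.conditions)
        return [f"if {cond}\nthen\n{inner}\nend"]
    return [f"if {_condition_src(c)}\nthen\n{inner}\nend"
            for c in block.conditions]


def ruleset_to_script(rules: RuleSet) -> str:
    """Transpile a ruleset to script-dialect source.

    An ``Any`` block emits one ``if ... then ... return risk, comment
    end`` unit per condition, in order; an ``All`` block emits a single
    unit whose condition is the ``and``-chain of its conditions.  The
    immediate returns reproduce first-match semantics in the purely
    sequential script dialect.  A trailing ``comment = "<else>"``
    supplies the no-match label.
    """
    units: list[str] = []
    for block in rules.blocks:
        units.extend(_block_units(block))
    if rules.else_trait is not None:
        units.append(f'comment = "{rules.else_trait}"')
    return "\n\n".join(units) + "\n"


def render_rule_text(rules: RuleSet) -> str:
    """Deterministic canonical rendering; inverse of parse_rule_text."""
    out: list[str] = []
    for block in rules.blocks:
        out.append(block.mode.name.capitalize() + ":")
        for cond in block.conditions:
            out.append(f"{cond.key} '{'/'.join(cond.literal.alleles)}'")
        close = f'== "{block.trait}"'
        if block.risk:
            close += f" risk {block.risk}"
        out.append(close)
        out.append("")
    if rules.else_trait is not None:
        out.append(f'else "{rules.else_trait}"')
    return "\n".join(out).strip() + "\n"
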