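"""Parser and evaluator for the rule-script dialect.

The dialect is the small imperative language rule files are written in:
sequential statements, ``if <cond> then ... end`` blocks whose
conditions are genotype-variable equality tests combined with ``and`` /
``or`` (``and`` binds tighter), assignments to the two result variables
``risk`` (float) and ``comment`` (string), and an optional early
``return risk, comment``.  Variables name variant sites — rsIDs
(``rs553090414``) or sanitized positions (``chr1_16949``, also written
``chr1:16949``) — and are bound at evaluation time from a
:class:`~traitscreen.genotypes.GenotypeStore`.

The language is deliberately not Turing-complete: no loops, arithmetic,
or user functions.  A program is a decision list; evaluation always
terminates in one pass.

Grammar (EBNF, whitespace/newlines insignificant)::

    program   := [ "function" IDENT "(" ")" ] stmt* [ "end" ]
    stmt      := "if" expr "then" stmt* "end"
               | "risk" "=" NUMBER
               | "comment" "=" STRING
               | IDENT "=" STRING          # top level only; ignored
               | "return" "risk" "," "comment"
    expr      := term ( "or" term )*
    term      := atom ( "and" atom )*
    atom      := IDENT "==" STRING | "(" expr ")"

Top-level ``IDENT = "<genotype>"`` bindings are accepted and ignored
with a warning: they are machine-added scaffolding found in completed
rule functions, and the genotype store supersedes them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Union

from .genotypes import (
    GenotypeCall,
    GenotypeStore,
    desanitize_identifier,
    genotype_match,
    parse_genotype_literal,
    sanitize_identifier,
)

log = logging.getLogger(__name__)

__all__ = [
    "Eq", "And", "Or", "Expr",
    "AssignRisk", "AssignComment", "If", "Return", "Stmt",
    "RuleProgram", "TraitResult",
    "parse_script", "evaluate", "extract_variables",
    "ScriptSyntaxError",
]


class ScriptSyntaxError(ValueError):
    """Raised on any lexical or grammatical error, with line/column."""

    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"line {line}, column {col}: {message}")
        self.line = line
        self.col = col


# --- AST -------------------------------------------------------------------

@dataclass(frozen=True)
class Eq:
    var: str
    literal: GenotypeCall


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"


Expr = Union[Eq, And, Or]


@dataclass(frozen=True)
class AssignRisk:
    value: float


@dataclass(frozen=True)
class AssignComment:
    value: str


@dataclass(frozen=True)
class Return:
    pass


@dataclass(frozen=True)
class If:
    cond: Expr
    body: tuple["Stmt", ...]


Stmt = Union[AssignRisk, AssignComment, If, Return]


@dataclass(frozen=True)
class RuleProgram:
    statements: tuple[Stmt, ...]

    @property
    def referenced_vars(self) -> frozenset[str]:
        out: set[str] = set()

        def walk_expr(e: Expr) -> None:
            if isinstance(e, Eq):
                out.add(e.var)
            else:
                walk_expr(e.left)
                walk_expr(e.right)

        def walk(stmts) -> None:
            for s in stmts:
                if isinstance(s, If):
                    walk_expr(s.cond)
                    walk(s.body)

        walk(self.statements)
        return frozenset(out)


@dataclass(frozen=True)
class TraitResult:
    """Outcome of one rule program: a unitless risk score and a label."""

    risk: float = 0.0
    comment: str = "none"


# --- tokenizer -------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<comment>--[^\n]*)
  | (?P<string>"[^"\n]*"|“[^”\n]*”)
  | (?P<number>\d+\.\d+|\.\d+|\d+)
  | (?P<op>==|=|,|\(|\))
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*(?::\d+)?)
    """,
    re.VERBOSE,
)

_KEYWORDS = frozenset({"if", "then", "end", "and", "or", "return", "function"})


@dataclass(frozen=True)
class _Token:
    kind: str  # 'string' | 'number' | 'op' | 'ident' | 'keyword' | 'eof'
    text: str
    line: int
    col: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos, line, line_start = 0, 1, 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ScriptSyntaxError(
                f"unexpected character {text[pos]!r}", line, pos - line_start + 1
            )
        kind = m.lastgroup
        tok_text = m.group()
        col = pos - line_start + 1
        if kind not in ("ws", "comment"):
            if kind == "ident" and tok_text in _KEYWORDS:
                kind = "keyword"
            tokens.append(_Token(kind, tok_text, line, col))
        nl = tok_text.count("\n")
        if nl:
            line += nl
            line_start = pos + tok_text.rindex("\n") + 1
        pos = m.end()
    tokens.append(_Token("eof", "<end of input>", line, len(text) - line_start + 1))
    return tokens


# --- parser ----------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def error(self, msg: str) -> ScriptSyntaxError:
        t = self.cur
        return ScriptSyntaxError(f"{msg} (got {t.text!r})", t.line, t.col)

    def advance(self) -> _Token:
        t = self.cur
        self.i += 1
        return t

    def accept(self, kind: str, text: Optional[str] = None) -> Optional[_Token]:
        t = self.cur
        if t.kind == kind and (text is None or t.text == text):
            return self.advance()
        return None

    def expect(self, kind: str, text: Optional[str] = None) -> _Token:
        t = self.accept(kind, text)
        if t is None:
            raise self.error(f"expected {text or kind}")
        return t

    # program := [function wrapper] stmts
    def parse_program(self) -> RuleProgram:
        wrapped = False
        if self.accept("keyword", "function"):
            self.expect("ident")
            self.expect("op", "(")
            self.expect("op", ")")
            wrapped = True
        stmts = self.parse_statements(top_level=True)
        if wrapped:
            self.expect("keyword", "end")
        if self.cur.kind != "eof":
            raise self.error("unexpected trailing input")
        return RuleProgram(statements=tuple(stmts))

    def parse_statements(self, top_level: bool) -> list[Stmt]:
        stmts: list[Stmt] = []
        while True:
            t = self.cur
            if t.kind == "eof" or (t.kind == "keyword" and t.text == "end"):
                return stmts
            if stmts and isinstance(stmts[-1], Return):
                raise self.error("statements after 'return' are unreachable")
            stmts.append(self.parse_statement(top_level))

    def parse_statement(self, top_level: bool) -> Stmt:
        t = self.cur
        if t.kind == "keyword" and t.text == "if":
            return self.parse_if(top_level)
        if t.kind == "keyword" and t.text == "return":
            self.advance()
            self.expect("ident", "risk")
            self.expect("op", ",")
            self.expect("ident", "comment")
            return Return()
        if t.kind == "ident":
            return self.parse_assignment(top_level)
        raise self.error("expected a statement")

    def parse_if(self, top_level: bool) -> If:
        self.expect("keyword", "if")
        cond = self.parse_expr()
        self.expect("keyword", "then")
        body = self.parse_statements(top_level=False)
        self.expect("keyword", "end")
        return If(cond=cond, body=tuple(body))

    def parse_assignment(self, top_level: bool) -> Stmt:
        name_tok = self.expect("ident")
        name = name_tok.text
        if name == "risk":
            self.expect("op", "=")
            num = self.expect("number")
            return AssignRisk(value=float(num.text))
        if name == "comment":
            self.expect("op", "=")
            s = self.expect("string")
            return AssignComment(value=_string_value(s.text))
        # genotype-variable binding: machine-added scaffolding, ignored
        eq = self.advance()
        if eq.kind != "op" or eq.text not in ("=", "=="):
            raise self.error("expected '=' or '==' after identifier")
        if eq.text == "==" or not top_level:
            raise ScriptSyntaxError(
                f"only 'risk' and 'comment' may be assigned "
                f"(found {name!r})", name_tok.line, name_tok.col,
            )
        s = self.expect("string")
        log.warning(
            "ignoring top-level binding %s = %s: genotype variables are "
            "initialized from the genotype file", name, s.text,
        )
        return _Ignored()

    def parse_expr(self) -> Expr:
        left = self.parse_term()
        while self.accept("keyword", "or"):
            left = Or(left=left, right=self.parse_term())
        return left

    def parse_term(self) -> Expr:
        left = self.parse_atom()
        while self.accept("keyword", "and"):
            left = And(left=left, right=self.parse_atom())
        return left

    def parse_atom(self) -> Expr:
        if self.accept("op", "("):
            e = self.parse_expr()
            self.expect("op", ")")
            return e
        name_tok = self.cur
        if name_tok.kind != "ident":
            raise self.error("expected a variant identifier or '('")
        self.advance()
        # colon-form positions are sanitized to underscore variables;
        # other identifiers (rsIDs, chrN_POS, bare names) pass through
        if ":" in name_tok.text:
            try:
                var = sanitize_identifier(name_tok.text)
            except ValueError as exc:
                raise ScriptSyntaxError(
                    str(exc), name_tok.line, name_tok.col
                ) from exc
        else:
            var = name_tok.text
        self.expect("op", "==")
        s = self.expect("string")
        try:
            literal = parse_genotype_literal(_string_value(s.text))
        except ValueError as exc:
            raise ScriptSyntaxError(str(exc), s.line, s.col) from exc
        return Eq(var=var, literal=literal)


@dataclass(frozen=True)
class _Ignored:
    """Sentinel for discarded top-level genotype bindings."""


def _string_value(token_text: str) -> str:
    return token_text[1:-1]


def parse_script(text: str) -> RuleProgram:
    """Parse rule-script source into a :class:`RuleProgram`.

    Raises :class:`ScriptSyntaxError` with line/column on any malformed
    input, including assignment to a variable other than ``risk`` or
    ``comment`` and an ``if`` without a closing ``end``.
    """
    if not text.strip():
        raise ScriptSyntaxError("empty script", 1, 1)
    program = _Parser(_tokenize(text)).parse_program()
    stmts = tuple(s for s in program.statements if not isinstance(s, _Ignored))
    return RuleProgram(statements=stmts)


# --- evaluator -------------------------------------------------------------

def evaluate(program: RuleProgram, store: GenotypeStore) -> TraitResult:
    """Run a program against a genotype store.

    Starts from the defaults ``risk = 0.0``, ``comment = "none"``,
    executes statements in order, and returns the final pair.  An
    equality test on a variant that is absent from the store, or whose
    call is missing, is false (warned once per distinct key); a
    ``return`` halts execution immediately.
    """
    risk = 0.0
    comment = "none"
    warned: set[str] = set()

    def test(expr: Expr) -> bool:
        if isinstance(expr, Eq):
            key = desanitize_identifier(expr.var)
            call = store.lookup(key)
            if (call is None or call.missing) and key not in warned:
                warned.add(key)
                log.warning(
                    "variant %s %s in genotype input; condition is false",
                    key, "is missing" if call is not None else "not found",
                )
            return genotype_match(call, expr.literal)
        if isinstance(expr, And):
            return test(expr.left) and test(expr.right)
        return test(expr.left) or test(expr.right)

    def run(stmts) -> bool:
        """Execute statements; True means a return was hit."""
        nonlocal risk, comment
        for s in stmts:
            if isinstance(s, AssignRisk):
                risk = s.value
            elif isinstance(s, AssignComment):
                comment = s.value
            elif isinstance(s, Return):
                return True
            elif isinstance(s, If):
                if test(s.cond) and run(s.body):
                    return True
        return False

    run(program.statements)
    return TraitResult(risk=risk, comment=comment)


def extract_variables(program: RuleProgram) -> frozenset[str]:
    """Store-query keys for every variant a program references.

    Sanitized positional variables are translated back to colon form
    (``chr1_16949`` → ``chr1:16949``); rsIDs pass through.  Used for
    targeted scanning and absent-variant warnings.
    """
    return frozenset(desanitize_identifier(v) for v in program.referenced_vars)
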