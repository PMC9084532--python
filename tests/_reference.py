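"""Independent reference interpreter for the rule-script dialect.

Used only as a test oracle.  It shares no code with the package's
engine and uses a different algorithm throughout: a flat token stream
executed with an if-nesting stack (no AST), and shunting-yard
conversion to reverse Polish notation for condition expressions (the
engine uses recursive descent).  Genotypes are supplied as a plain
dict mapping variable names to 'A/G'-style strings (None = missing /
absent), compared as sorted allele multisets.
"""

from __future__ import annotations

import re
from typing import Mapping, Optional

_TOKEN = re.compile(
    r'"[^"\n]*"|==|=|,|\(|\)|[A-Za-z_][A-Za-z0-9_]*(?::\d+)?|\d+\.\d+|\.\d+|\d+'
)

_PREC = {"or": 1, "and": 2}


def _multiset(genotype: str) -> tuple:
    return tuple(sorted(a.upper() for a in genotype.split("/")))


def _atom(var: str, literal: str,
          genotypes: Mapping[str, Optional[str]]) -> bool:
    for k in (var, var.replace(":", "_"), var.replace("_", ":")):
        if k in genotypes:
            call = genotypes[k]
            return call is not None and _multiset(call) == _multiset(literal)
    return False


def _eval_condition(tokens: list[str],
                    genotypes: Mapping[str, Optional[str]]) -> bool:
    # infix -> RPN (shunting-yard), atoms reduced to booleans on the fly
    output: list[object] = []
    ops: list[str] = []
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if t in _PREC:
            while ops and ops[-1] in _PREC and _PREC[ops[-1]] >= _PREC[t]:
                output.append(ops.pop())
            ops.append(t)
        elif t == "(":
            ops.append(t)
        elif t == ")":
            while ops[-1] != "(":
                output.append(ops.pop())
            ops.pop()
        else:  # var == "literal"
            assert tokens[i + 1] == "==", tokens
            output.append(_atom(t, tokens[i + 2].strip('"'), genotypes))
            i += 2
        i += 1
    while ops:
        output.append(ops.pop())
    stack: list[bool] = []
    for item in output:
        if item == "and":
            b, a = stack.pop(), stack.pop()
            stack.append(a and b)
        elif item == "or":
            b, a = stack.pop(), stack.pop()
            stack.append(a or b)
        else:
            stack.append(bool(item))
    (result,) = stack
    return result


def reference_eval(source: str,
                   genotypes: Mapping[str, Optional[str]]) -> tuple[float, str]:
    """Execute a script and return (risk, comment)."""
    tokens = _TOKEN.findall(source)
    if tokens[:1] == ["function"]:
        assert tokens[1:4] == ["evaluate", "(", ")"] or tokens[2:4] == ["(", ")"]
        tokens = tokens[4:]
        assert tokens[-1] == "end"
        tokens = tokens[:-1]
    risk, comment = 0.0, "none"
    active: list[bool] = []  # truth of each enclosing if
    i = 0
    while i < len(tokens):
        t = tokens[i]
        executing = all(active)
        if t == "if":
            j = tokens.index("then", i)
            active.append(executing and _eval_condition(tokens[i + 1:j],
                                                        genotypes))
            i = j
        elif t == "end":
            active.pop()
        elif t == "return":
            assert tokens[i + 1:i + 4] == ["risk", ",", "comment"]
            if executing:
                return risk, comment
            i += 3
        elif t == "risk" and tokens[i + 1] == "=":
            if executing:
                risk = float(tokens[i + 2])
            i += 2
        elif t == "comment" and tokens[i + 1] == "=":
            if executing:
                comment = tokens[i + 2].strip('"')
            i += 2
        elif tokens[i + 1] == "=":  # auto-added genotype binding: ignore
            assert not active, "assignment to a genotype variable in a block"
            i += 2
        else:
            raise AssertionError(f"oracle cannot read token {t!r}")
        i += 1
    return risk, comment
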