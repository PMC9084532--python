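"""Convert a structured-text ruleset to script-dialect source.

An Any block becomes one if-unit per condition, each with an immediate
return (first match wins); an All block becomes a single if-unit with
an and-chain; the else label becomes a trailing default assignment.
"""

from traitscreen import parse_rule_text, ruleset_to_script

RULES = """\
All
rs4988235 'GG'
rs182549 'CC'
== "Lactose intolerant likely"

else "Lactase persistent"
"""

script = ruleset_to_script(parse_rule_text(RULES))
print(script)
# the single All block yields one if-unit whose condition is the
# and-chain of both genotype tests; when neither fires, the trailing
# assignment supplies the else label.
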