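"""Screen a synthetic individual for hereditary fructose intolerance.

Builds a small single-sample VCF in a temporary directory with a
homozygous causal genotype at rs1800546 (ALDOB), then evaluates the
Any/All rule file for fructose tolerance against it.
"""

import tempfile
from pathlib import Path

from traitscreen import evaluate_ruleset, parse_rule_text, read_vcf
from traitscreen.fixtures import FRUCTOSE_VARIANTS, FixtureSpec, generate_fixture

RULES = """\
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
"""

with tempfile.TemporaryDirectory() as tmp:
    spec = FixtureSpec(variants=FRUCTOSE_VARIANTS,
                       genotypes={"rs1800546": "1/1"})  # homozygous G/G
    vcf, _ = generate_fixture(spec, Path(tmp))
    store = read_vcf(vcf)
    result = evaluate_ruleset(parse_rule_text(RULES), store)

print(f"risk={result.risk:g}\tcomment={result.comment}")
# comment is the label of the first rule block whose conditions hold:
# the individual is homozygous G/G at rs1800546, so the first Any block
# fires and the screen reports "Fructose Intolerant".
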