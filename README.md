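# traitscreen

Rule-based screening of single-sample genotype data for mono- and
oligogenic traits.

Many clinically interesting phenotypes — hereditary fructose
intolerance (*ALDOB*), lactase persistence (*MCM6*), *APOE*-linked
Alzheimer's risk — are deterministic or near-deterministic functions of
genotypes at a handful of loci.  Screening a VCF for them needs no
statistics, just a clear way to write down genotype conditions and
evaluate them.  `traitscreen` is that: it loads one individual's
genotypes from a VCF or a simple rsid/chrom/pos/genotype table, and
evaluates user-written trait rules against them, returning a numeric
**risk** score and a text **comment**.  It is aimed at researchers and
clinicians who want to test variant–trait hypotheses without writing
VCF-processing code, in any species — the rule library is entirely
user-defined.

## The two rule dialects

**Script dialect** — a tiny imperative language: sequential statements,
`if <condition> then ... end` blocks, assignments to the two result
variables, and optional early returns.  Conditions test variant
genotypes by rsID or chromosomal position (`chr1:16949`), written as
unordered allele pairs (`"A/G"` matches a G/A call; phase is ignored):

```lua
if rs568149713 == "A/G" and rs557514207 == "G/G" then
   comment = "highrisk"
   risk = 0.8
end

if chr1:16949 == "A/C" or rs553090414 == "C/C" then
   comment = "mediumrisk"
   risk = 0.5
end
```

`and` binds tighter than `or`; parentheses override.  Evaluation starts
from `risk = 0`, `comment = "none"`, runs top to bottom, and a variant
absent from the genotype file simply makes its condition false.

**Structured text dialect** — for users who do not want to write code
at all: ordered `Any` / `All` blocks, each closed by a trait label,
with an optional `else` label.  The first block whose conditions hold
decides the result:

```
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
```

Genotype literals may be compact (`'GG'`) or slash-form (`C/G`, quotes
optional); the slash form is required for indel alleles (`'T/TGAT'`).
Text rules are mechanically transpiled to the script dialect
(`ruleset_to_script` / the `txt2script` command), and direct evaluation
of a ruleset is exactly equivalent to evaluating its transpilation — a
property the test suite fuzzes.

## Worked example

```sh
$ txt2script -i fructose.txt > fructose.lua
$ traitscreen -i person.vcf --rules fructose.txt
risk=0	comment=Fructose Intolerant
$ traitscreen -i person.tsv -lua fructose.lua --json
{"risk": 0.0, "comment": "Fructose Intolerant"}
```

Here `person.vcf` carries a homozygous G/G call at rs1800546, so the
first `Any` block fires: the comment names the matched trait, and the
risk is 0 because the text dialect assigns no risk values (an optional
`== "Trait" risk 0.8` extension does).  The same decision logic is
available from Python:

```python
from traitscreen import read_vcf, parse_rule_text, evaluate_ruleset
store = read_vcf("person.vcf")
result = evaluate_ruleset(parse_rule_text(open("fructose.txt").read()), store)
print(result.risk, result.comment)   # 0.0 Fructose Intolerant
```

The `examples/` directory has short narrative scripts for each
capability (screening, the script dialect, transpilation); each prints
the numbers it computes and says what they mean.

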