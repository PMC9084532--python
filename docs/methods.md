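# Methods and design notes

## The model of a trait rule

`traitscreen` treats a trait rule program as a *decision list* over
genotype predicates.  A predicate compares the genotype call at one
variant site — addressed by rsID or by 1-based chromosomal position —
to a literal allele pair.  The comparison is:

- **unordered**: the call's allele *multiset* must equal the literal's,
  so a literal `A/G` matches calls recorded as `A/G` or `G/A`.  Rule
  authors cannot know the arbitrary allele order a variant caller
  emitted, and making results depend on it would be a correctness trap;
- **phase-blind**: `|`-separated (phased) and `/`-separated (unphased)
  VCF genotypes are matched identically.  The rule dialects have no
  phase syntax, so *cis*/*trans* configurations of multi-site
  haplotypes cannot be distinguished — a real limitation for the few
  oligogenic traits where gametic phase matters;
- **total**: a site that is absent from the genotype file, or present
  with a missing call (`./.`), makes the predicate false.  Evaluation
  never aborts on incomplete data; each such site is warned once.

A program's result is a pair: a floating-point `risk` score (unitless,
default 0.0) and a string `comment` (default `"none"`).  The script
dialect executes sequentially — later assignments overwrite earlier
ones unless an early `return` intervenes — while the text dialect has
first-match semantics, which the transpiler encodes by giving every
emitted if-unit an immediate `return`.

## Dialects and the transpiler

The script dialect is deliberately not Turing-complete: if-blocks over
`and`/`or` combinations of genotype predicates, assignments to
`risk`/`comment`, and `return risk, comment`.  `and` binds tighter than
`or` and both are left-associative; parentheses are accepted.  The
parser is a hand-written tokenizer plus recursive descent — the grammar
has about ten productions, and this keeps error messages (line, column,
offending token) precise.  Two tolerated extras reflect how rule files
circulate in practice: an optional `function <name> () ... end` wrapper,
and top-level `variable = "genotype"` bindings, both of which appear in
machine-completed rule files; the bindings are ignored with a warning
because the genotype store is the source of truth.

The text dialect is line-oriented: `Any`/`All` keywords
(case-insensitive, optional colon), one `KEY LITERAL` condition per
line, `== "Trait label"` closing each block, optional `else "Label"`,
`#` comments.  Straight and typographic quotes are both accepted, since
rule text pasted from documents often carries curly quotes.  Trait
labels are preserved verbatim, including internal spaces.  The text
dialect carries no risk values by design; an extension suffix
(`== "Trait" risk 0.8`) is parsed when present.

Transpilation (`ruleset_to_script`) maps an `Any` block to one if-unit
per condition and an `All` block to a single if-unit with an
`and`-chain, each unit returning immediately; an `else` label becomes a
trailing `comment = ...` assignment that only executes when no unit
returned.  The central correctness property — direct ruleset evaluation
equals evaluation of the transpiled script, exactly, in both fields —
is enforced two ways: a seeded fuzz over 500 random ruleset/store pairs
in the acceptance tests plus 150 Hypothesis draws, and a brute-force
check that enumerates all programs from a small grammar (≤3 variables,
≤2 if-blocks) against an independently written flat-token reference
interpreter over every genotype assignment.

## Genotype ingestion

VCF input goes through `pysam`; plain and bgzipped files both work, and
the GT FORMAT field is required.  GT allele indices are mapped to REF/ALT
sequences (`0/1` with REF A, ALT G → `A/G`), preserving GT order and the
phase flag for reporting even though matching ignores both.  Only
single-sample processing is supported: a multi-sample file requires an
explicit sample name and errors otherwise, naming the available
samples.  Hemizygous GTs (`1`) yield one-allele calls that match only
one-allele literals; half-calls (`./1`) keep the known allele.  Records
whose GT cannot be interpreted become missing calls and are tallied in
a warning, not dropped silently.

Tabular input follows the layout of common consumer-genotype exports:
whitespace- or comma-delimited columns rsid, chromosome, position,
genotype, with `#` comments and `--`/`..`/`00` as no-call tokens.
Malformed rows are skipped with a per-row warning; a file with no valid
rows is an error.  Positional lookup strips a case-insensitive leading
`chr` from both store keys and queries, so `chr1:16949` finds records
whose CHROM column says `1` or `chr1`.  Alleles are uppercased on
ingest; case carries no meaning for nucleotide sequences.

## The synthetic-data generator

`traitscreen.fixtures` makes the whole system testable without any
external download.  `generate_fixture` writes a matched VCF/TSV pair
from a declarative spec (variants plus GT assignments, homozygous
reference by default), byte-deterministic so goldens are stable.  It
emulates a minimal but well-formed single-sample callset: sorted
biallelic-to-triallelic sites with GT-only FORMAT.  It does not emulate
real-data features that the matching semantics deliberately ignore or
that ingestion treats uniformly — quality fields, filters, multi-sample
columns, structural variants, or genome-build differences — so passing
tests demonstrate correctness of rule evaluation over calls, not
robustness to every VCF dialect in the wild.

`random_ruleset`/`random_store` drive the property tests.  Stores are
drawn adversarially around a ruleset: for each referenced variant,
roughly a quarter of draws omit it, a fifth make it a missing call, a
third copy a rule literal (with shuffled allele order, to exercise
unordered matching), and the rest draw a fresh random genotype.  These
rates were chosen once to make every code path (match, mismatch,
missing, absent, order-swap) common in a 500-draw run.

## Numerical and procedural choices

- Risk values are IEEE doubles parsed from integer or decimal literals;
  no arithmetic exists in the dialect, so comparisons in tests are
  exact equality.
- Coordinates are 1-based everywhere, matching VCF convention.
- Duplicate conditions inside a block are kept (harmless under Any/All
  semantics) with a warning; duplicate `else` lines are an error.
- `and`/`or` short-circuit, so absent-variant warnings are emitted only
  for predicates actually evaluated.
- The brute-force test sizes (6 expression shapes × 2 bodies × ≤2
  blocks, 4 genotype states per variable) and the 500-pair fuzz were
  chosen to cover the semantic space exhaustively at small scale while
  keeping the default test run under a minute apart from the I/O smoke
  test; the throughput smoke test uses a synthetic million-record VCF,
  which loads in well under a minute on one CPU.

## Known limitations

- No phasing, dosage, or probabilistic genotypes; no polygenic scores —
  the tool is for deterministic mono-/oligogenic screening only.
- One sample per run; batch screening means one invocation per sample.
- No liftover: rule positions must match the genome build of the input.
- The script dialect is a closed subset by design: no loops, arithmetic,
  numeric comparisons, or string operations.  Anything outside the
  grammar is a parse error, not silently ignored.
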