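"""Evaluate a hand-written rule script across three genotype profiles.

The script has two if-blocks: a high-risk AND pair and a medium-risk
OR pair.  With no early returns, a profile satisfying both blocks gets
the *second* block's values — assignments simply overwrite.
"""

from traitscreen import GenotypeCall, GenotypeStore, VariantRecord, evaluate, parse_script

SCRIPT = """
if rs568149713 == "A/G"
and rs557514207 == "G/G" then
   comment = "highrisk"
   risk = 0.8
end

if chr1:16949 == "A/C"
or rs553090414 == "C/C"
then
   comment = "mediumrisk"
   risk = 0.5
end
"""


def store_of(calls: dict[str, str]) -> GenotypeStore:
    store = GenotypeStore(sample_id="demo")
    for i, (key, gt) in enumerate(calls.items()):
        call = GenotypeCall(alleles=tuple(gt.split("/")), raw=gt)
        if ":" in key:
            chrom, _, pos = key.partition(":")
            store.add(VariantRecord(chrom, int(pos), "", "N", (), call))
        else:
            store.add(VariantRecord("1", 1000 + i, key, "N", (), call))
    return store


program = parse_script(SCRIPT)
profiles = {
    "high-risk pair": {"rs568149713": "A/G", "rs557514207": "G/G",
                       "chr1:16949": "T/T", "rs553090414": "C/T"},
    "medium-risk site": {"rs568149713": "G/G", "rs557514207": "A/G",
                         "chr1:16949": "T/T", "rs553090414": "C/C"},
    "both blocks fire": {"rs568149713": "A/G", "rs557514207": "G/G",
                         "chr1:16949": "A/C", "rs553090414": "C/C"},
}
for name, calls in profiles.items():
    result = evaluate(program, store_of(calls))
    print(f"{name:18s} -> risk={result.risk:g} comment={result.comment}")
# the first profile triggers only block 1 (risk 0.8); the second only
# block 2 (risk 0.5); the third triggers both, and block 2's
# assignments overwrite block 1's, so it also reports risk 0.5.
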