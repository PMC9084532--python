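from __future__ import annotations

from typing import Mapping, Optional

import pytest

from traitscreen import GenotypeCall, GenotypeStore, VariantRecord

# the two-block worked script: a high-risk AND pair, then a medium-risk OR pair
SNIPPET1 = """
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

# the same snippet completed into a function with auto-added genotype bindings
SNIPPET1_COMPLETED = """
function evaluate ()
   comment = "none"
   risk = 0
   rs568149713 = "A/G"
   rs557514207 = "G/G"
   chr1_16949 = "A/C"
   rs553090414 = "C/C"
   if rs568149713 == "A/G" and rs557514207 == "G/G"
then
      comment = "highrisk"
      risk = 0.8
   end
   if chr1_16949 == "A/C"
or rs553090414 == "C/C"
then
      comment = "mediumrisk"
      risk = 0.5
   end
   return risk, comment
end
"""

# hereditary fructose intolerance: three causal ALDOB variants
FRUCTOSE_TEXT = """Any
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

# same ruleset with typographic quotes, as pasted from typeset documents
FRUCTOSE_TEXT_CURLY = """Any
rs1800546 ‘GG’
rs76917243 ‘TT’
rs78340951 ‘CC’
== “Fructose Intolerant”

Any:
rs1800546 ‘C/G’
rs76917243 ‘G/T’
rs78340951 C/G
== “Variant Carrier”

else “Tolerant to Fructose”
"""


def make_store(calls: Mapping[str, Optional[str]],
               sample: str = "S") -> GenotypeStore:
    """Build a store from {key: 'A/G'} dicts; None means a missing call.

    Keys may be rsIDs or 'chrN:POS' positions.
    """
    store = GenotypeStore(sample_id=sample)
    pos = 1
    for key, gt in calls.items():
        call = (GenotypeCall(missing=True, raw="./.") if gt is None
                else GenotypeCall(alleles=tuple(gt.upper().split("/")), raw=gt))
        if ":" in key:
            chrom, _, p = key.partition(":")
            store.add(VariantRecord(chrom=chrom, pos=int(p), id="",
                                    ref="N", alts=(), call=call))
        else:
            pos += 10
            store.add(VariantRecord(chrom="1", pos=pos, id=key,
                                    ref="N", alts=(), call=call))
    return store


@pytest.fixture
def fructose_text() -> str:
    return FRUCTOSE_TEXT


@pytest.fixture
def snippet1() -> str:
    return SNIPPET1
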