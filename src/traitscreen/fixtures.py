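"""Synthetic genotype fixtures and random rule generators.

Everything here is deterministic given a seed, so test inputs are
reproducible and no external data is needed.  :func:`generate_fixture`
writes a matched single-sample VCF/TSV pair from a
:class:`FixtureSpec`; :func:`random_ruleset` and :func:`random_store`
draw rule programs and genotype stores for the transpilation-
equivalence property, biased so that matches, mismatches, missing
calls, and absent variants all occur with useful frequency.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from .genotypes import (
    GenotypeCall,
    GenotypeStore,
    VariantRecord,
    normalize_genotype,
)
from .ruledsl import BlockMode, Condition, RuleBlock, RuleSet

__all__ = [
    "FixtureSpec", "Variant", "generate_fixture", "spec_store",
    "random_ruleset", "random_store", "FRUCTOSE_VARIANTS",
]

_NUCS = "ACGT"


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int
    rsid: str
    ref: str
    alts: tuple[str, ...]


#: the three causal ALDOB sites used in the fructose-intolerance ruleset
FRUCTOSE_VARIANTS = (
    Variant("9", 104182860, "rs78340951", "G", ("C",)),
    Variant("9", 104184282, "rs76917243", "G", ("T",)),
    Variant("9", 104189856, "rs1800546", "C", ("G",)),
)


def variant_key(v: Variant) -> str:
    """The rsID where one exists, otherwise the ``chrom:pos`` position."""
    return v.rsid or f"{v.chrom}:{v.pos}"


@dataclass
class FixtureSpec:
    """A declarative description of one synthetic single-sample callset.

    ``genotypes`` maps variant key (rsID, or ``chrom:pos`` for id-less
    sites) → GT string in VCF index form, e.g. ``"0/1"``; variants
    without an entry default to homozygous reference ``0/0``.
    """

    variants: Sequence[Variant]
    genotypes: dict[str, str] = field(default_factory=dict)
    sample_id: str = "SAMPLE1"
    seed: int = 0

    def validate(self) -> None:
        seen: dict[str, int] = {}
        for v in self.variants:
            if v.pos < 1:
                raise ValueError(f"{variant_key(v)}: positions are 1-based")
            if v.chrom in seen and v.pos <= seen[v.chrom]:
                raise ValueError(
                    f"{variant_key(v)}: positions must be strictly "
                    f"increasing within chromosome {v.chrom}")
            seen[v.chrom] = v.pos
        known = {variant_key(v) for v in self.variants}
        for key in self.genotypes:
            if key not in known:
                raise ValueError(f"genotype given for unknown variant {key}")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=traitscreen-fixture
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def generate_fixture(
    spec: FixtureSpec, out_dir: Union[str, Path], stem: str = "fixture"
) -> tuple[Path, Path]:
    """Write the VCF and TSV files for a spec; returns their paths.

    Output is byte-deterministic for a given spec, and the two files
    describe the same calls, so stores read from either agree on every
    non-missing genotype.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{stem}.vcf"
    tsv_path = out_dir / f"{stem}.tsv"

    contigs = dict.fromkeys(v.chrom for v in spec.variants)
    with open(vcf_path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{spec.sample_id}\n")
        for v in spec.variants:
            gt = spec.genotypes.get(variant_key(v), "0/0")
            alt = ",".join(v.alts) if v.alts else "."
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{alt}"
                     f"\t.\t.\t.\tGT\t{gt}\n")

    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("# rsid\tchrom\tpos\tgenotype\n")
        for v in spec.variants:
            call = _spec_call(spec, v)
            gt = "--" if call.missing else "/".join(call.alleles)
            fh.write(f"{v.rsid or '.'}\t{v.chrom}\t{v.pos}\t{gt}\n")
    return vcf_path, tsv_path


def _spec_call(spec: FixtureSpec, v: Variant) -> GenotypeCall:
    return normalize_genotype(spec.genotypes.get(variant_key(v), "0/0"),
                              v.ref, v.alts)


def spec_store(spec: FixtureSpec) -> GenotypeStore:
    """Build the GenotypeStore a reader should produce, without I/O."""
    spec.validate()
    store = GenotypeStore(sample_id=spec.sample_id)
    for v in spec.variants:
        store.add(VariantRecord(
            chrom=v.chrom, pos=v.pos, id=v.rsid, ref=v.ref, alts=v.alts,
            call=_spec_call(spec, v)))
    return store


# ---------------------------------------------------------------------------
# random draws for property tests

def _random_call(rng: random.Random, indel_rate: float = 0.15) -> GenotypeCall:
    def allele() -> str:
        if rng.random() < indel_rate:
            return "".join(rng.choices(_NUCS, k=rng.randint(2, 4)))
        return rng.choice(_NUCS)

    return GenotypeCall(alleles=(allele(), allele()))


def _keys(n: int, rng: random.Random) -> list[str]:
    out = []
    for i in range(n):
        if rng.random() < 0.25:
            out.append(f"chr{rng.randint(1, 22)}:{rng.randint(1, 10**6)}")
        else:
            out.append(f"rs{rng.randint(10**3, 10**8)}")
    return out


def random_ruleset(rng: random.Random, max_blocks: int = 4,
                   max_conditions: int = 3) -> RuleSet:
    """Draw a well-formed ruleset over a small shared variant pool."""
    pool = _keys(rng.randint(1, 5), rng)
    n_blocks = rng.randint(0, max_blocks)
    blocks = []
    for _ in range(n_blocks):
        mode = rng.choice([BlockMode.ANY, BlockMode.ALL])
        conds = tuple(
            Condition(key=rng.choice(pool), literal=_random_call(rng))
            for _ in range(rng.randint(1, max_conditions)))
        trait = f"trait {rng.randint(0, 99)}"
        risk = rng.choice([0.0, 0.0, 0.1, 0.5, 0.8, 1.0])
        blocks.append(RuleBlock(mode=mode, conditions=conds, trait=trait,
                                risk=risk))
    else_trait = (f"default {rng.randint(0, 9)}"
                  if (blocks and rng.random() < 0.7) or not blocks else None)
    return RuleSet(blocks=tuple(blocks), else_trait=else_trait)


def random_store(rules: RuleSet, rng: random.Random) -> GenotypeStore:
    """Draw a store exercising the ruleset's variants.

    Each referenced variant is, with roughly equal probability, given a
    genotype copied from one of its rule literals (a match), a fresh
    random genotype (usually a mismatch), a missing call, or left out
    of the store entirely.
    """
    store = GenotypeStore(sample_id="RAND")
    by_key: dict[str, list[GenotypeCall]] = {}
    for block in rules.blocks:
        for cond in block.conditions:
            by_key.setdefault(cond.key, []).append(cond.literal)
    pos_counter = 1000
    for key, literals in by_key.items():
        u = rng.random()
        if u < 0.25:
            continue  # absent from the callset
        if u < 0.45:
            call = GenotypeCall(missing=True, raw="./.")
        elif u < 0.75:
            lit = rng.choice(literals)
            alleles = list(lit.alleles)
            rng.shuffle(alleles)  # order must not matter
            call = GenotypeCall(alleles=tuple(alleles))
        else:
            call = _random_call(rng)
        if key.startswith("rs"):
            pos_counter += rng.randint(1, 50)
            rec = VariantRecord(chrom="1", pos=pos_counter, id=key,
                                ref="N", alts=(), call=call)
        else:
            chrom, _, pos = key.partition(":")
            rec = VariantRecord(chrom=chrom, pos=int(pos), id="",
                                ref="N", alts=(), call=call)
        store.add(rec)
    return store
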