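"""Genotype calls, stores, and readers for single-sample VCF/TSV input.

A :class:`GenotypeStore` maps rsIDs and chromosomal positions to
:class:`GenotypeCall` values for one individual.  Rule conditions test
those calls with :func:`genotype_match`, which compares allele
*multisets*: heterozygous ``A/G`` equals ``G/A``, and phase (``|`` vs
``/`` in the VCF GT field) is deliberately ignored — rule authors cannot
know the arbitrary allele order a caller emitted, and the rule dialect
carries no phase information.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pysam

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "GenotypeStore",
    "read_vcf",
    "read_tsv",
    "write_tsv",
    "normalize_genotype",
    "parse_genotype_literal",
    "genotype_match",
    "sanitize_identifier",
    "GenotypeParseError",
    "KeyPatternError",
]

#: tokens meaning "no call" in TSV genotype columns
MISSING_TSV_TOKENS = frozenset({"--", "..", "00", ".", "-"})
#: the VCF missing-allele token
MISSING_ALLELE = "."

_ALLELE_RE = re.compile(r"^[ACGTN]+$")
_RSID_RE = re.compile(r"^rs\d+$")
_POSKEY_RE = re.compile(r"^(?:chr)?([A-Za-z0-9]+):(\d+)$", re.IGNORECASE)
_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class GenotypeParseError(ValueError):
    """A genotype literal or GT field could not be interpreted."""


class KeyPatternError(ValueError):
    """A variant key is neither an rsID nor a chrom:pos position."""


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid (or degenerate) genotype call.

    Parameters
    ----------
    alleles:
        Ordered allele sequences, uppercase, 0–2 entries.  Empty for a
        fully missing call.
    phased:
        True when the source encoded phase (``|`` separator).  Only
        meaningful for two-allele calls.
    missing:
        True when no usable call was present.
    raw:
        The source text the call was built from, kept for reporting.
    """

    alleles: tuple[str, ...] = ()
    phased: bool = field(default=False, compare=False)
    missing: bool = False
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.missing:
            if self.alleles:
                raise ValueError("missing call must carry no alleles")
        else:
            if not self.alleles:
                raise ValueError("non-missing call needs at least one allele")
            if len(self.alleles) > 2:
                raise ValueError("calls are diploid at most (2 alleles)")
            for a in self.alleles:
                if not _ALLELE_RE.match(a):
                    raise ValueError(f"invalid allele {a!r}")
        if self.phased and len(self.alleles) != 2:
            raise ValueError("phase flag requires exactly two alleles")

    def __str__(self) -> str:
        if self.missing:
            return "./."
        sep = "|" if self.phased else "/"
        return sep.join(self.alleles)


#: explicit missing call singleton used by readers
MISSING_CALL = GenotypeCall(missing=True, raw=".")


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with its genotype call for the loaded sample."""

    chrom: str
    pos: int
    id: str
    ref: str
    alts: tuple[str, ...]
    call: GenotypeCall

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")

    @property
    def chrom_normalized(self) -> str:
        return normalize_chrom(self.chrom)


def normalize_chrom(label: str) -> str:
    """Strip a case-insensitive leading ``chr`` so 'chr1' and '1' agree."""
    if label[:3].lower() == "chr":
        return label[3:]
    return label


@dataclass
class GenotypeStore:
    """rsID and positional lookup of genotype calls for one sample.

    Lookups of absent keys return ``None`` — rule evaluation treats an
    absent or missing variant as a condition that is simply false, it
    never aborts.
    """

    sample_id: str = ""
    by_rsid: dict[str, GenotypeCall] = field(default_factory=dict)
    by_pos: dict[tuple[str, int], GenotypeCall] = field(default_factory=dict)
    #: count of source lines whose genotype could not be parsed
    n_unparseable: int = 0

    def add(self, record: VariantRecord) -> None:
        if record.id:
            self.by_rsid[record.id] = record.call
        self.by_pos[(record.chrom_normalized, record.pos)] = record.call

    def lookup(self, key: str) -> Optional[GenotypeCall]:
        """Resolve an rsID or ``[chr]NAME:POS`` key; ``None`` if absent."""
        if _RSID_RE.match(key):
            return self.by_rsid.get(key)
        m = _POSKEY_RE.match(key)
        if m:
            return self.by_pos.get((normalize_chrom(m.group(1)), int(m.group(2))))
        return self.by_rsid.get(key)

    def __len__(self) -> int:
        return len(self.by_pos)

    def variants(self) -> Iterable[tuple[str, GenotypeCall]]:
        yield from self.by_rsid.items()


def parse_genotype_literal(text: str) -> GenotypeCall:
    """Parse a genotype literal as written in rule files.

    Two forms are accepted, optionally wrapped in single or double
    (straight or typographic) quotes: a slash form ``C/G`` and a compact
    two-letter form ``CG``.  The slash form is mandatory for indel
    alleles such as ``T/TGAT`` — a compact multi-character token is
    ambiguous and rejected.
    """
    stripped = text.strip().strip("'\"‘’“”")
    if not stripped:
        raise GenotypeParseError("empty genotype literal")
    if "/" in stripped:
        parts = [p.strip().upper() for p in stripped.split("/")]
        if any(not p for p in parts):
            raise GenotypeParseError(
                f"empty allele in genotype literal {text!r}"
            )
    else:
        if len(stripped) != 2:
            raise GenotypeParseError(
                f"genotype literal {text!r} has no '/' and is not two "
                "single-letter alleles; multi-base (indel) alleles must "
                "use the slash form, e.g. 'T/TGAT'"
            )
        parts = [stripped[0].upper(), stripped[1].upper()]
    try:
        return GenotypeCall(alleles=tuple(parts), raw=text.strip())
    except ValueError as exc:
        raise GenotypeParseError(f"bad genotype literal {text!r}: {exc}") from exc


def normalize_genotype(
    gt_field: str, ref: str, alts: Iterable[str]
) -> GenotypeCall:
    """Turn a VCF GT field into allele sequences.

    ``0`` maps to REF, ``i`` (>=1) to the i-th ALT.  ``|`` marks a
    phased call, ``/`` unphased; allele order is preserved as given.
    Missing tokens (``.``, ``./.``, ``.|.``) give a missing call; a GT
    with one missing and one called allele keeps the called allele
    (half-call → one-allele call).
    """
    gt_field = gt_field.strip()
    if not gt_field:
        return GenotypeCall(missing=True, raw=gt_field)
    phased = "|" in gt_field
    tokens = re.split(r"[/|]", gt_field)
    if len(tokens) > 2:
        raise GenotypeParseError(f"GT field {gt_field!r} has >2 alleles")
    allele_seqs = [ref.upper()] + [a.upper() for a in alts]
    out: list[str] = []
    for tok in tokens:
        tok = tok.strip()
        if tok == MISSING_ALLELE or tok == "":
            continue
        if not tok.isdigit():
            raise GenotypeParseError(f"bad GT allele index {tok!r} in {gt_field!r}")
        idx = int(tok)
        if idx >= len(allele_seqs):
            raise GenotypeParseError(
                f"GT index {idx} out of range for REF={ref} ALT={list(alts)}"
            )
        out.append(allele_seqs[idx])
    if not out:
        return GenotypeCall(missing=True, raw=gt_field)
    return GenotypeCall(
        alleles=tuple(out), phased=phased and len(out) == 2, raw=gt_field
    )


def genotype_match(call: Optional[GenotypeCall], literal: GenotypeCall) -> bool:
    """Unordered, phase-blind genotype equality.

    True iff ``call`` is present, non-missing, and its allele multiset
    equals the literal's.  A missing or absent call never matches.
    """
    if call is None or call.missing:
        return False
    return Counter(call.alleles) == Counter(literal.alleles)


def sanitize_identifier(key: str) -> str:
    """Map a variant key to a legal script variable name.

    rsIDs pass through unchanged; positional keys like ``chr1:16949``
    become ``chr1_16949``.  Anything else is rejected.
    """
    if _RSID_RE.match(key):
        return key
    m = _POSKEY_RE.match(key)
    if m:
        name = key.replace(":", "_")
        if not name.lower().startswith("chr"):
            name = "chr" + name
        if _IDENT_RE.match(name):
            return name
    raise KeyPatternError(
        f"variant key {key!r} is neither an rsID (rs123...) nor a "
        "position (chr1:6658743)"
    )


def desanitize_identifier(name: str) -> str:
    """Inverse of :func:`sanitize_identifier` for positional variables."""
    if _RSID_RE.match(name):
        return name
    if name.lower().startswith("chr") and "_" in name:
        label, _, pos = name.rpartition("_")
        if pos.isdigit():
            return f"{label}:{pos}"
    return name


# ---------------------------------------------------------------------------
# readers / writer

def read_vcf(path: Union[str, Path], sample: Optional[str] = None) -> GenotypeStore:
    """Load a single sample's genotypes from a VCF file.

    Plain-text and bgzipped VCFs are both accepted; the GT FORMAT field
    is required per record.  With a multi-sample file, ``sample`` must
    name the column to read.  Records whose GT cannot be interpreted
    become missing calls and are tallied in ``store.n_unparseable``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF file not found: {path}")
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"VCF {path} contains no sample columns")
        if sample is None:
            if len(samples) > 1:
                raise ValueError(
                    f"VCF {path} has {len(samples)} samples "
                    f"({', '.join(samples)}); pass an explicit sample name"
                )
            sample = samples[0]
        elif sample not in samples:
            raise ValueError(
                f"sample {sample!r} not in VCF {path} "
                f"(available: {', '.join(samples)})"
            )
        store = GenotypeStore(sample_id=sample)
        for rec in vcf:
            _ingest_vcf_record(rec, sample, store)
    if store.n_unparseable:
        log.warning(
            "%s: %d record(s) had unparseable GT fields; stored as missing",
            path, store.n_unparseable,
        )
    return store


def _ingest_vcf_record(rec, sample: str, store: GenotypeStore) -> None:
    sdata = rec.samples[sample]
    alts = tuple(a for a in (rec.alts or ()) if a)
    gt = sdata.get("GT")
    if gt is None:
        gt_str = ""
    else:
        sep = "|" if sdata.phased else "/"
        gt_str = sep.join("." if i is None else str(i) for i in gt)
    try:
        call = normalize_genotype(gt_str, rec.ref or "N", alts)
    except GenotypeParseError:
        store.n_unparseable += 1
        call = GenotypeCall(missing=True, raw=gt_str)
    rsid = rec.id or ""
    store.add(
        VariantRecord(
            chrom=rec.chrom, pos=rec.pos, id=rsid,
            ref=(rec.ref or "N").upper(), alts=alts, call=call,
        )
    )


def read_tsv(path: Union[str, Path]) -> GenotypeStore:
    """Load genotypes from a whitespace- or comma-delimited table.

    Expected columns: rsid, chromosome, position, genotype — the layout
    of common consumer-genotype exports.  ``#`` lines are comments;
    genotype tokens ``--``/``..``/``00`` mean no-call.  Malformed rows
    are skipped with a warning; a file with no valid rows is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TSV file not found: {path}")
    store = GenotypeStore(sample_id=path.stem)
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 4:
                log.warning("%s:%d: expected >=4 columns, got %d; row skipped",
                            path, lineno, len(fields))
                continue
            rsid, chrom, pos_s, gt = fields[:4]
            if rsid == ".":
                rsid = ""
            if not pos_s.isdigit():
                log.warning("%s:%d: non-numeric position %r; row skipped",
                            path, lineno, pos_s)
                continue
            if gt in MISSING_TSV_TOKENS:
                call = GenotypeCall(missing=True, raw=gt)
            else:
                try:
                    call = parse_genotype_literal(gt)
                except GenotypeParseError as exc:
                    log.warning("%s:%d: %s; row skipped", path, lineno, exc)
                    continue
            store.add(
                VariantRecord(
                    chrom=chrom, pos=int(pos_s), id=rsid,
                    ref="N", alts=(), call=call,
                )
            )
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"no valid genotype rows in {path}")
    return store


def write_tsv(store: GenotypeStore, path: Union[str, Path]) -> None:
    """Write a store back out in the four-column table layout.

    Only positionally-keyed entries can be written; rsIDs are recovered
    from the rsID map where the call object is shared.
    """
    call_to_rsid = {id(call): rsid for rsid, call in store.by_rsid.items()}
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("# rsid\tchrom\tpos\tgenotype\n")
        for (chrom, pos), call in sorted(store.by_pos.items()):
            rsid = call_to_rsid.get(id(call), ".")
            gt = "--" if call.missing else "/".join(call.alleles)
            fh.write(f"{rsid}\t{chrom}\t{pos}\t{gt}\n")
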