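"""HLA allele nomenclature: parsing, canonical rendering, genotypes.

Six loci are supported — the class I loci A, B, Cw and the class II loci
DRB1, DQB1, DPB1.  An allele name carries an allele *group* (first field)
and optionally a *protein* field; a name without a protein field is a
low-resolution (serology-level) designation.  Several dialects occur in
clinical typing reports and are all accepted:

    "A*02:01"   colon-delimited (canonical)
    "A*02: 01"  stray whitespace around the separator
    "A*0201"    concatenated 4-digit
    "A*02"      low-resolution (group only)
    "A*203"     legacy 3-digit name, kept verbatim as an opaque group

Canonical rendering is ``LOCUS*GG:PP`` (or ``LOCUS*GG`` at low resolution).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "LOCI",
    "CLASS_I_LOCI",
    "CLASS_II_LOCI",
    "Allele",
    "Genotype",
    "HLAParseError",
    "parse_allele",
    "parse_genotype",
    "read_genotypes",
]

#: Supported loci, in conventional report order.
LOCI = ("A", "B", "Cw", "DRB1", "DQB1", "DPB1")
CLASS_I_LOCI = frozenset({"A", "B", "Cw"})
CLASS_II_LOCI = frozenset({"DRB1", "DQB1", "DPB1"})


class HLAParseError(ValueError):
    """Raised when an HLA allele or genotype string cannot be interpreted."""


# Longest prefixes first so "DRB1" is not read as "D" + junk.
_LOCUS_ALTS = "|".join(sorted(LOCI, key=len, reverse=True))
_ALLELE_RE = re.compile(
    rf"^\s*(?:HLA-)?({_LOCUS_ALTS})\s*\*\s*(.+?)\s*$", re.IGNORECASE
)
# Case-normalisation table ("cw" -> "Cw", "drb1" -> "DRB1", ...).
_LOCUS_CANON = {locus.upper(): locus for locus in LOCI}


@dataclass(frozen=True, order=True)
class Allele:
    """One HLA allele at group or group:protein resolution.

    Equality and ordering are over ``(locus, group, protein)``; a
    low-resolution allele (``protein is None``) never equals a
    high-resolution one of the same group.
    """

    locus: str
    group: str
    protein: str | None = None
    legacy: bool = field(default=False, compare=False)

    @property
    def hla_class(self) -> str:
        """``"I"`` for A/B/Cw, ``"II"`` for DRB1/DQB1/DPB1."""
        return "I" if self.locus in CLASS_I_LOCI else "II"

    @property
    def low_resolution(self) -> bool:
        return self.protein is None

    def render(self) -> str:
        if self.protein is None:
            return f"{self.locus}*{self.group}"
        return f"{self.locus}*{self.group}:{self.protein}"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.render()


def parse_allele(text: str) -> Allele:
    """Parse one allele name in any supported dialect.

    Raises :class:`HLAParseError` naming the offending token on an unknown
    locus prefix or non-numeric fields.
    """
    if not text or not text.strip():
        raise HLAParseError("empty allele name")
    match = _ALLELE_RE.match(text)
    if match is None:
        # Distinguish "no star / unknown locus" for a clearer message.
        head = text.strip().split("*", 1)[0]
        raise HLAParseError(f"unknown HLA locus prefix {head!r} in {text!r}")
    locus = _LOCUS_CANON[match.group(1).upper()]
    fields_txt = match.group(2)

    if ":" in fields_txt:
        parts = [p.strip() for p in fields_txt.split(":")]
        if len(parts) > 2:
            # Keep only group:protein; synonymous/noncoding fields are out
            # of scope and their presence is an input error here.
            raise HLAParseError(f"too many fields in {text!r}")
        group, protein = parts
    else:
        digits = fields_txt.strip()
        if not digits.isdigit():
            raise HLAParseError(f"non-numeric allele fields {digits!r} in {text!r}")
        if len(digits) == 4:
            group, protein = digits[:2], digits[2:]
        elif len(digits) == 3:
            # Legacy name such as A*203: opaque group token, no protein.
            return Allele(locus, digits, None, legacy=True)
        else:
            group, protein = digits, None

    if not group.isdigit():
        raise HLAParseError(f"non-numeric allele group {group!r} in {text!r}")
    if protein is not None and not protein.isdigit():
        raise HLAParseError(f"non-numeric protein field {protein!r} in {text!r}")
    return Allele(locus, group, protein)


def _coerce(allele: "Allele | str") -> Allele:
    return allele if isinstance(allele, Allele) else parse_allele(allele)


@dataclass(frozen=True)
class Genotype:
    """Per-locus unordered allele pairs for one subject.

    Homozygosity is represented by the same allele twice.  Each locus slot
    holds alleles of that locus only.
    """

    subject_id: str
    alleles: Mapping[str, tuple[Allele, Allele]]

    def __post_init__(self) -> None:
        normalised: dict[str, tuple[Allele, Allele]] = {}
        for locus, pair in self.alleles.items():
            if locus not in LOCI:
                raise HLAParseError(f"unsupported locus {locus!r}")
            if len(pair) != 2:
                raise HLAParseError(
                    f"{self.subject_id}: locus {locus} needs exactly two alleles"
                )
            a, b = (_coerce(x) for x in pair)
            for allele in (a, b):
                if allele.locus != locus:
                    raise HLAParseError(
                        f"{self.subject_id}: allele {allele} listed under locus {locus}"
                    )
            normalised[locus] = tuple(sorted((a, b)))
        object.__setattr__(self, "alleles", normalised)

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(l for l in LOCI if l in self.alleles)

    def distinct(self, locus: str) -> tuple[Allele, ...]:
        """Distinct alleles at a locus (one entry if homozygous)."""
        pair = self.alleles[locus]
        return (pair[0],) if pair[0] == pair[1] else pair

    def is_homozygous(self, locus: str) -> bool:
        return len(self.distinct(locus)) == 1


def parse_genotype(
    record: Mapping[str, Iterable[str]], subject_id: str = ""
) -> Genotype:
    """Build a :class:`Genotype` from a mapping of locus -> two allele strings."""
    alleles = {locus: tuple(strings) for locus, strings in record.items()}
    return Genotype(subject_id, alleles)  # type: ignore[arg-type]


def _genotype_from_flat(row: Mapping[str, str], subject_id: str) -> Genotype:
    record: dict[str, tuple[str, str]] = {}
    for locus in LOCI:
        a1, a2 = row.get(f"{locus}_1"), row.get(f"{locus}_2")
        if a1 and a2:
            record[locus] = (a1, a2)
        elif a1 or a2:
            raise HLAParseError(f"{subject_id}: locus {locus} has only one allele")
    return Genotype(subject_id, record)  # type: ignore[arg-type]


def read_genotypes(path: str | Path) -> list[Genotype]:
    """Read genotypes from TSV (columns subject_id, A_1, A_2, ...) or JSON.

    The JSON form is a list of objects with the same keys as the TSV columns.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        import csv

        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    out = []
    for row in rows:
        sid = row.get("subject_id", "")
        if not sid:
            raise HLAParseError("genotype row without subject_id")
        out.append(_genotype_from_flat(row, sid))
    return out
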