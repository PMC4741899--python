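"""Pairwise RMSD records per locus: build, store, query, and the
acceptable-mismatch dictionary.

A record holds the coordinate and revised RMSD between two alleles of the
same locus plus optional annotations (number of mismatched amino acids,
peptide-binding-groove pockets A-F involved, peptide-binding / TCR-contact
flags).  A matrix is an order-insensitive map over unordered within-locus
allele pairs; querying an allele against itself yields an implicit zero
record.

A mismatch is *acceptable* when its revised RMSD is at or below the locus
class threshold: 0.2 Å for the class I loci (A/B/Cw), 0.1 Å for the class
II loci (DRB1/DQB1/DPB1).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .fixedpoint import format4
from .nomenclature import CLASS_I_LOCI, Allele, parse_allele
from .structure import (
    RegionSet,
    StructureModel,
    coordinate_rmsd,
    default_regions,
    revised_rmsd,
)

__all__ = [
    "ACCEPTABLE_THRESHOLDS",
    "RMSDRecord",
    "RMSDMatrix",
    "build_matrix",
    "classify_acceptable",
    "annotate_mismatches",
]

#: Revised-RMSD acceptability thresholds (Å) by HLA class.
ACCEPTABLE_THRESHOLDS = {"I": 0.2, "II": 0.1}

POCKETS = ("A", "B", "C", "D", "E", "F")


class MatrixLookupError(KeyError):
    """A queried allele pair is not in the matrix."""


def _ordered(a: Allele, b: Allele) -> tuple[Allele, Allele]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class RMSDRecord:
    """One unordered allele pair's structure-discrepancy record."""

    allele1: Allele
    allele2: Allele
    coordinate_rmsd: float
    revised_rmsd: float
    n_mismatch_aa: int | None = None
    pockets: frozenset[str] | None = None
    peptide_binding: bool | None = None
    tcr_contact: bool | None = None

    def __post_init__(self) -> None:
        if self.allele1.locus != self.allele2.locus:
            raise ValueError(
                f"cross-locus record {self.allele1}/{self.allele2}"
            )
        if self.allele1 > self.allele2:
            a1, a2 = self.allele2, self.allele1
            object.__setattr__(self, "allele1", a1)
            object.__setattr__(self, "allele2", a2)
        if self.coordinate_rmsd < 0 or self.revised_rmsd < 0:
            raise ValueError("RMSD values must be nonnegative")
        if self.pockets is not None:
            object.__setattr__(self, "pockets", frozenset(self.pockets))

    @property
    def locus(self) -> str:
        return self.allele1.locus


def classify_acceptable(
    record: RMSDRecord,
    thresholds: Mapping[str, float] = ACCEPTABLE_THRESHOLDS,
) -> bool:
    """True iff the pair's revised RMSD is within its locus-class threshold."""
    hla_class = "I" if record.locus in CLASS_I_LOCI else "II"
    return record.revised_rmsd <= thresholds[hla_class]


class RMSDMatrix:
    """Order-insensitive store of within-locus :class:`RMSDRecord` s."""

    def __init__(self, records: Iterable[RMSDRecord] = (), source: str = "computed"):
        self.source = source
        self._records: dict[tuple[Allele, Allele], RMSDRecord] = {}
        for record in records:
            self.add(record)

    def add(self, record: RMSDRecord, on_duplicate: str = "error") -> None:
        """Insert a record.  ``on_duplicate``: "error" rejects any second
        record for the pair; "identical" tolerates exact re-insertions
        (useful when pooling per-subject report records)."""
        key = (record.allele1, record.allele2)
        if key in self._records:
            if on_duplicate == "identical" and self._records[key] == record:
                return
            raise ValueError(
                f"duplicate record for pair {record.allele1}/{record.allele2}"
            )
        self._records[key] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def alleles(self, locus: str | None = None) -> list[Allele]:
        seen = set()
        for rec in self:
            for allele in (rec.allele1, rec.allele2):
                if locus is None or allele.locus == locus:
                    seen.add(allele)
        return sorted(seen)

    def __contains__(self, pair: tuple[Allele, Allele]) -> bool:
        a, b = pair
        return a == b or _ordered(a, b) in self._records

    def lookup(self, a: Allele | str, b: Allele | str) -> RMSDRecord:
        """Order-insensitive retrieval; ``a == b`` yields a zero record."""
        a = parse_allele(a) if isinstance(a, str) else a
        b = parse_allele(b) if isinstance(b, str) else b
        if a.locus != b.locus:
            raise MatrixLookupError(
                f"cross-locus query {a}/{b}: records exist only within a locus"
            )
        for allele in (a, b):
            if allele.low_resolution:
                raise MatrixLookupError(
                    f"{allele} is low-resolution; the matrix is keyed on "
                    "high-resolution (group:protein) names"
                )
        if a == b:
            return RMSDRecord(a, b, 0.0, 0.0, n_mismatch_aa=0)
        key = _ordered(a, b)
        try:
            return self._records[key]
        except KeyError:
            raise MatrixLookupError(
                f"pair {a}/{b} not in matrix (source: {self.source})"
            ) from None

    def acceptable_dictionary(
        self,
        allele: Allele | str,
        thresholds: Mapping[str, float] = ACCEPTABLE_THRESHOLDS,
    ) -> list[Allele]:
        """All acceptable-mismatch partners of ``allele``, canonically sorted.

        The query allele itself is excluded; an allele with no partner at
        or under the threshold yields an empty list.
        """
        allele = parse_allele(allele) if isinstance(allele, str) else allele
        partners = []
        found = False
        for rec in self:
            if allele not in (rec.allele1, rec.allele2):
                continue
            found = True
            other = rec.allele2 if rec.allele1 == allele else rec.allele1
            if other != allele and classify_acceptable(rec, thresholds):
                partners.append(other)
        if not found:
            raise MatrixLookupError(f"allele {allele} not in matrix")
        return sorted(partners)

    # -- TSV serialisation -------------------------------------------------

    _COLUMNS = (
        "locus",
        "allele1",
        "allele2",
        "coordinate_rmsd",
        "revised_rmsd",
        "n_mismatch_aa",
        "pockets",
        "peptide_binding",
        "tcr_contact",
    )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(self._COLUMNS)
            for rec in sorted(self, key=lambda r: (r.locus, r.allele1, r.allele2)):
                writer.writerow(
                    [
                        rec.locus,
                        rec.allele1.render(),
                        rec.allele2.render(),
                        format4(rec.coordinate_rmsd),
                        format4(rec.revised_rmsd),
                        "" if rec.n_mismatch_aa is None else rec.n_mismatch_aa,
                        "" if rec.pockets is None else ",".join(sorted(rec.pockets)),
                        _bool_out(rec.peptide_binding),
                        _bool_out(rec.tcr_contact),
                    ]
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RMSDMatrix":
        matrix = cls(source=str(path))
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                matrix.add(
                    RMSDRecord(
                        allele1=parse_allele(row["allele1"]),
                        allele2=parse_allele(row["allele2"]),
                        coordinate_rmsd=float(row["coordinate_rmsd"]),
                        revised_rmsd=float(row["revised_rmsd"]),
                        n_mismatch_aa=(
                            int(row["n_mismatch_aa"]) if row["n_mismatch_aa"] else None
                        ),
                        pockets=(
                            frozenset(row["pockets"].split(","))
                            if row["pockets"]
                            else None
                        ),
                        peptide_binding=_bool_in(row["peptide_binding"]),
                        tcr_contact=_bool_in(row["tcr_contact"]),
                    )
                )
        return matrix


def _bool_out(value: bool | None) -> str:
    return "" if value is None else ("yes" if value else "no")


def _bool_in(text: str) -> bool | None:
    return None if text == "" else text == "yes"


def build_matrix(
    models: Sequence[StructureModel],
    region_sets: Mapping[str, RegionSet] | None = None,
    fit: str = "region",
) -> RMSDMatrix:
    """Score every within-locus unordered pair of models.

    Cross-locus pairs are never computed.  Duplicate allele identities
    among the models are an error.
    """
    by_locus: dict[str, list[StructureModel]] = {}
    seen: set[Allele] = set()
    for model in models:
        if model.allele is None:
            raise ValueError(f"model from {model.source} carries no allele")
        if model.allele in seen:
            raise ValueError(f"duplicate model for allele {model.allele}")
        seen.add(model.allele)
        by_locus.setdefault(model.allele.locus, []).append(model)

    matrix = RMSDMatrix()
    for locus, group in by_locus.items():
        hla_class = group[0].allele.hla_class
        region = (
            region_sets[hla_class]
            if region_sets is not None
            else default_regions(hla_class)
        )
        for m1, m2 in itertools.combinations(group, 2):
            matrix.add(
                RMSDRecord(
                    allele1=m1.allele,
                    allele2=m2.allele,
                    coordinate_rmsd=coordinate_rmsd(m1, m2),
                    revised_rmsd=revised_rmsd(m1, m2, region, fit=fit),
                )
            )
    return matrix


def annotate_mismatches(
    seq1: str | Sequence[str],
    seq2: str | Sequence[str],
    region: RegionSet,
    pocket_map: Mapping[int, Mapping[str, object]] | None = None,
) -> tuple[int, frozenset[str], bool, bool]:
    """Count differing positions inside the recognition region and collect
    their pocket/contact annotations.

    Sequences are aligned, equal length, 1-based position == residue
    number.  ``pocket_map`` maps residue number -> {"pockets": iterable,
    "peptide_binding": bool, "tcr_contact": bool}; it is external
    configuration (pocket residue assignments are not built in).
    """
    if len(seq1) != len(seq2):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq1)} vs {len(seq2)})"
        )
    pocket_map = pocket_map or {}
    n_mismatch = 0
    pockets: set[str] = set()
    peptide_binding = False
    tcr_contact = False
    for pos, (a, b) in enumerate(zip(seq1, seq2), start=1):
        if a == b or pos not in region:
            continue
        n_mismatch += 1
        info = pocket_map.get(pos, {})
        pockets.update(info.get("pockets", ()))
        peptide_binding = peptide_binding or bool(info.get("peptide_binding"))
        tcr_contact = tcr_contact or bool(info.get("tcr_contact"))
    return n_mismatch, frozenset(pockets), peptide_binding, tcr_contact
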