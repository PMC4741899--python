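"""Bundled pilot allo-HSCT study records and their validated loader.

The package ships the transcribed records of the pilot transplant cohort
the scoring system was validated on: 4-locus genotypes (low- and
high-resolution) for 12 retrospective and 25 prospective recipient-donor
pairs, per-locus GVH-direction mismatch records with coordinate and
revised RMSD for the 32 transplanted pairs, observed aGVHD grades, and
candidate-donor panels (sibling and cord-blood) for the five recipients
who had several alternative donors.

Loading is self-checking: every transplanted pair's printed total revised
RMSD must equal the 4-decimal sum of its transcribed per-locus components,
and likewise for every panel donor.  A handful of rows carry transcription
notes where the published tables are internally inconsistent (flagged
``total_discrepant``); those are preserved verbatim and exempted from the
checksum.
"""

from __future__ import annotations

import csv
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .fixedpoint import format4, sum4
from .matching import MatchReport, match_report, SEVERITY_CUTOFF
from .matrix import RMSDMatrix, RMSDRecord
from .nomenclature import Genotype, parse_allele

__all__ = [
    "FixtureIntegrityError",
    "TransplantCase",
    "DonorPanel",
    "PilotStudy",
    "load_pilot_study",
    "write_fixture_files",
]

_FILES = (
    "pilot_genotypes_highres.tsv",
    "pilot_genotypes_lowres.tsv",
    "pilot_mismatch_records.tsv",
    "pilot_outcomes.tsv",
    "panel_donors.tsv",
    "panel_records.tsv",
)


class FixtureIntegrityError(ValueError):
    """A bundled record fails its transcription self-check."""


@dataclass
class TransplantCase:
    """One transplanted recipient-donor pair with its RMSD records."""

    pair_id: str
    group: str  # retrospective | prospective
    recipient: Genotype
    donor: Genotype
    matrix: RMSDMatrix
    printed_total: float
    observed_grade: str
    note: str = ""

    @property
    def total_discrepant(self) -> bool:
        return "total_discrepant" in self.note

    def report(self, cutoff: float = SEVERITY_CUTOFF) -> MatchReport:
        """Re-run the mismatch pipeline on this case's genotypes."""
        return match_report(
            self.recipient,
            self.donor,
            self.matrix,
            observed_grade=self.observed_grade,
            cutoff=cutoff,
        )


@dataclass
class DonorPanel:
    """One recipient's candidate-donor panel.

    Each candidate combination carries its own record set (the records
    published for that recipient-donor pairing), so mismatch resolution
    for one donor never borrows a record from another candidate.
    """

    recipient_id: str
    recipient: Genotype
    donors: list[Genotype]
    matrices: dict[str, RMSDMatrix]
    printed_totals: dict[str, float]
    selected_donor: str

    def rank(self, cutoff: float = SEVERITY_CUTOFF) -> list[tuple[str, MatchReport]]:
        """Rank the candidates ascending by total revised RMSD (stable)."""
        reports = [
            (
                donor.subject_id,
                match_report(self.recipient, donor,
                             self.matrices[donor.subject_id], cutoff=cutoff),
            )
            for donor in self.donors
        ]
        reports.sort(key=lambda item: item[1].total_revised_rmsd)
        return reports


@dataclass
class PilotStudy:
    cases: dict[str, TransplantCase]
    panels: dict[str, DonorPanel]
    lowres_genotypes: list[dict]
    recipients: dict[str, Genotype] = field(default_factory=dict)

    @property
    def retrospective(self) -> list[TransplantCase]:
        return [c for c in self.cases.values() if c.group == "retrospective"]

    @property
    def prospective(self) -> list[TransplantCase]:
        return [c for c in self.cases.values() if c.group == "prospective"]


def _data_root(data_dir: str | Path | None) -> Path:
    if data_dir is not None:
        return Path(data_dir)
    return Path(resources.files("hla_tdsm") / "data")


def _read_tsv(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        return [
            {k: (v or "") for k, v in row.items() if k is not None}
            for row in csv.DictReader(fh, delimiter="\t")
        ]


def _genotype(row: dict, subject_id: str) -> Genotype:
    record = {}
    for locus in ("A", "B", "DRB1", "DQB1"):
        record[locus] = (row[f"{locus}_1"], row[f"{locus}_2"])
    return Genotype(subject_id, record)


def _record(row: dict) -> RMSDRecord:
    return RMSDRecord(
        allele1=parse_allele(row["recipient_allele"]),
        allele2=parse_allele(row["donor_allele"]),
        coordinate_rmsd=float(row["coordinate_rmsd"]),
        revised_rmsd=float(row["revised_rmsd"]),
        n_mismatch_aa=int(row["n_mismatch_aa"]) if row.get("n_mismatch_aa") else None,
        pockets=frozenset(row["pockets"].split(",")) if row.get("pockets") else None,
        peptide_binding=row.get("peptide_binding") == "yes"
        if row.get("peptide_binding")
        else None,
        tcr_contact=row.get("tcr_contact") == "yes"
        if row.get("tcr_contact")
        else None,
    )


def load_pilot_study(data_dir: str | Path | None = None) -> PilotStudy:
    """Load and validate the bundled pilot-study records.

    Raises :class:`FixtureIntegrityError` naming the offending subject if
    any printed total fails to equal the 4-decimal sum of its components
    (rows flagged ``total_discrepant`` excepted).
    """
    root = _data_root(data_dir)

    genotype_rows = _read_tsv(root / "pilot_genotypes_highres.tsv")
    recipients: dict[str, Genotype] = {}
    donors: dict[str, Genotype] = {}
    groups: dict[str, str] = {}
    for row in genotype_rows:
        pid = row["pair_id"]
        groups[pid] = row["group"]
        if row["role"] == "recipient":
            recipients[pid] = _genotype(row, pid)
        else:
            donors[pid] = _genotype(row, f"{pid}-donor")

    record_rows = _read_tsv(root / "pilot_mismatch_records.tsv")
    records_by_pair: dict[str, list[tuple[RMSDRecord, str]]] = {}
    for row in record_rows:
        records_by_pair.setdefault(row["pair_id"], []).append(
            (_record(row), row.get("note", ""))
        )

    cases: dict[str, TransplantCase] = {}
    for row in _read_tsv(root / "pilot_outcomes.tsv"):
        pid = row["pair_id"]
        note = row.get("note", "")
        printed_total = float(row["printed_total_revised_rmsd"])
        pair_records = [rec for rec, _ in records_by_pair.get(pid, [])]
        if "total_discrepant" not in note:
            component_sum = sum4(r.revised_rmsd for r in pair_records)
            if format4(component_sum) != format4(printed_total):
                raise FixtureIntegrityError(
                    f"{pid}: printed total {format4(printed_total)} != "
                    f"component sum {format4(component_sum)}"
                )
        matrix = RMSDMatrix(source=f"fixture:{pid}")
        for rec in pair_records:
            matrix.add(rec, on_duplicate="identical")
        cases[pid] = TransplantCase(
            pair_id=pid,
            group=row["group"],
            recipient=recipients[pid],
            donor=donors[pid],
            matrix=matrix,
            printed_total=printed_total,
            observed_grade=row["observed_grade"],
            note=note,
        )

    panel_record_rows = _read_tsv(root / "panel_records.tsv")
    panel_records: dict[tuple[str, str], list[RMSDRecord]] = {}
    for row in panel_record_rows:
        key = (row["recipient_id"], row["donor_id"])
        panel_records.setdefault(key, []).append(_record(row))

    panels: dict[str, DonorPanel] = {}
    for row in _read_tsv(root / "panel_donors.tsv"):
        rid, did = row["recipient_id"], row["donor_id"]
        printed_total = float(row["printed_total_revised_rmsd"])
        component_sum = sum4(
            r.revised_rmsd for r in panel_records.get((rid, did), [])
        )
        if format4(component_sum) != format4(printed_total):
            raise FixtureIntegrityError(
                f"{rid}/{did}: printed total {format4(printed_total)} != "
                f"component sum {format4(component_sum)}"
            )
        if rid not in panels:
            panels[rid] = DonorPanel(
                recipient_id=rid,
                recipient=recipients[rid],
                donors=[],
                matrices={},
                printed_totals={},
                selected_donor="",
            )
        panel = panels[rid]
        panel.donors.append(_genotype(row, did))
        panel.printed_totals[did] = printed_total
        if row["selected"] == "yes":
            panel.selected_donor = did
        donor_matrix = RMSDMatrix(source=f"fixture-panel:{rid}/{did}")
        for rec in panel_records.get((rid, did), []):
            donor_matrix.add(rec, on_duplicate="identical")
        panel.matrices[did] = donor_matrix

    return PilotStudy(
        cases=cases,
        panels=panels,
        lowres_genotypes=_read_tsv(root / "pilot_genotypes_lowres.tsv"),
        recipients=recipients,
    )


def write_fixture_files(out_dir: str | Path) -> list[Path]:
    """Copy the bundled TSV files to ``out_dir`` (``tdsm fixtures``)."""
    root = _data_root(None)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _FILES:
        dest = out / name
        shutil.copy(root / name, dest)
        written.append(dest)
    return written
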