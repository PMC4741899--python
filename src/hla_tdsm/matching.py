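"""GVH-direction mismatch resolution, aGVHD severity prediction, donor
ranking and concordance scoring.

A *GVH-direction* mismatch at a locus is a recipient allele type absent
from the donor's alleles at that locus — the antigen donor-derived T cells
can attack.  Loci where every recipient allele type appears in the donor
contribute no mismatch even if the donor carries extra alleles (those act
in the rejection direction, which is out of scope here).

Each mismatched recipient allele is paired with a donor allele:

* donor alleles absent from the recipient are the preferred partners;
  with two unshared alleles on each side the pairing is the minimum-
  total-revised-RMSD assignment;
* a donor homozygous for its unshared allele partners it with every
  unmatched recipient allele (several pairs against one allele);
* when the donor has no unshared allele at all (homozygous for a shared
  one), the mismatched recipient allele pairs with the donor allele of
  minimum revised RMSD.

The *total revised RMSD* of a recipient-donor combination is the sum of
revised RMSDs over all its GVH-direction mismatch pairs, computed in
4-decimal fixed point so totals equal the sum of their printed parts
exactly.  Severity is dichotomised at a 0.50 Å cutoff: when the maximum
single or the total revised RMSD reaches the cutoff, grade III-IV aGVHD
is predicted; below it, grade I-II.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .fixedpoint import round_half_up, sum4
from .matrix import MatrixLookupError, RMSDMatrix, classify_acceptable
from .nomenclature import Allele, Genotype

__all__ = [
    "SEVERITY_CUTOFF",
    "MismatchPair",
    "MatchReport",
    "ConcordanceResult",
    "gvh_mismatches",
    "total_revised_rmsd",
    "predict_severity",
    "match_report",
    "rank_donors",
    "concordance",
]

#: Default single/total revised-RMSD severity cutoff (Å).
SEVERITY_CUTOFF = 0.50

MILD = "mild (I-II)"
SEVERE = "severe (III-IV)"

_MILD_GRADES = {"I", "II"}
_SEVERE_GRADES = {"III", "IV"}


@dataclass(frozen=True)
class MismatchPair:
    """One GVH-direction mismatch: recipient allele vs its donor partner."""

    locus: str
    recipient_allele: Allele
    donor_allele: Allele
    revised_rmsd: float
    coordinate_rmsd: float | None = None
    acceptable: bool = False


@dataclass
class MatchReport:
    """Per-combination mismatch summary for one recipient-donor pairing."""

    recipient_id: str
    donor_id: str
    pairs: list[MismatchPair]
    observed_grade: str | None = None
    cutoff: float = SEVERITY_CUTOFF

    @property
    def total_revised_rmsd(self) -> float:
        return total_revised_rmsd(self.pairs)

    @property
    def max_single_revised(self) -> float:
        return max((p.revised_rmsd for p in self.pairs), default=0.0)

    @property
    def predicted_class(self) -> str:
        return predict_severity(
            self.total_revised_rmsd, self.max_single_revised, self.cutoff
        )

    @property
    def acceptable_choice(self) -> bool:
        return self.total_revised_rmsd < self.cutoff

    def to_dict(self) -> dict:
        return {
            "recipient_id": self.recipient_id,
            "donor_id": self.donor_id,
            "pairs": [
                {
                    "locus": p.locus,
                    "recipient_allele": p.recipient_allele.render(),
                    "donor_allele": p.donor_allele.render(),
                    "revised_rmsd": p.revised_rmsd,
                    "coordinate_rmsd": p.coordinate_rmsd,
                    "acceptable": p.acceptable,
                }
                for p in self.pairs
            ],
            "total_revised_rmsd": self.total_revised_rmsd,
            "max_single_revised": self.max_single_revised,
            "predicted_class": self.predicted_class,
            "observed_grade": self.observed_grade,
        }


def _assignment_pairs(
    locus: str,
    rec_only: Sequence[Allele],
    candidates: Sequence[Allele],
    matrix: RMSDMatrix,
) -> list[tuple[Allele, Allele]]:
    """Pair each mismatched recipient allele with a donor candidate by
    minimum-total-revised-RMSD assignment; donor candidates are reused
    only when they are fewer than the recipient alleles."""
    costs = np.full((len(rec_only), len(candidates)), np.nan)
    for i, r in enumerate(rec_only):
        for j, d in enumerate(candidates):
            try:
                costs[i, j] = matrix.lookup(r, d).revised_rmsd
            except MatrixLookupError:
                pass  # stays NaN: forbidden unless no alternative exists

    def require(i: int, j: int) -> tuple[Allele, Allele]:
        if np.isnan(costs[i, j]):
            raise MatrixLookupError(
                f"missing matrix record for required pair "
                f"{rec_only[i]}/{candidates[j]} at locus {locus}"
            )
        return rec_only[i], candidates[j]

    if len(candidates) < len(rec_only):
        # Donor homozygous for its unshared allele (or no unshared allele):
        # every recipient allele takes its cheapest candidate, reuse allowed.
        out = []
        for i in range(len(rec_only)):
            row = costs[i]
            j = 0 if np.all(np.isnan(row)) else int(np.nanargmin(row))
            out.append(require(i, j))
        return out

    big = 1e9  # sentinel steering the assignment away from missing records
    row_idx, col_idx = linear_sum_assignment(np.where(np.isnan(costs), big, costs))
    return [require(i, j) for i, j in zip(row_idx, col_idx)]


def gvh_mismatches(
    recipient: Genotype,
    donor: Genotype,
    matrix: RMSDMatrix,
    loci: Iterable[str] | None = None,
) -> list[MismatchPair]:
    """Resolve all GVH-direction mismatch pairs between two genotypes.

    ``loci`` defaults to the loci present in both genotypes.  Raises
    :class:`MatrixLookupError` when a required record is absent, naming
    the pair.
    """
    if loci is None:
        loci = [l for l in recipient.loci if l in donor.alleles]
    pairs: list[MismatchPair] = []
    for locus in loci:
        rec_distinct = recipient.distinct(locus)
        donor_distinct = donor.distinct(locus)
        donor_set = set(donor_distinct)
        rec_only = [a for a in rec_distinct if a not in donor_set]
        if not rec_only:
            continue  # no MM in GVH direction at this locus
        rec_set = set(rec_distinct)
        donor_only = [a for a in donor_distinct if a not in rec_set]
        candidates = donor_only if donor_only else list(donor_distinct)
        for r, d in _assignment_pairs(locus, rec_only, candidates, matrix):
            record = matrix.lookup(r, d)
            pairs.append(
                MismatchPair(
                    locus=locus,
                    recipient_allele=r,
                    donor_allele=d,
                    revised_rmsd=record.revised_rmsd,
                    coordinate_rmsd=record.coordinate_rmsd,
                    acceptable=classify_acceptable(record),
                )
            )
    return pairs


def total_revised_rmsd(pairs: Iterable[MismatchPair]) -> float:
    """Sum of pair revised RMSDs in 4-decimal fixed point; [] -> 0.0."""
    return sum4(p.revised_rmsd for p in pairs)


def predict_severity(
    total: float,
    max_single: float = 0.0,
    cutoff: float = SEVERITY_CUTOFF,
    boundary: str = "severe",
) -> str:
    """Dichotomised aGVHD severity from single/total revised RMSD.

    Severe (grade III-IV) when the total or the maximum single revised
    RMSD exceeds ``cutoff``; a value exactly at the cutoff classifies as
    severe by default (``boundary="severe"``, the conservative choice for
    an undefined boundary), or as mild with ``boundary="mild"``.
    """
    if cutoff <= 0:
        raise ValueError("severity cutoff must be positive")
    worst = max(total, max_single)
    if boundary == "severe":
        return SEVERE if worst >= cutoff else MILD
    return SEVERE if worst > cutoff else MILD


def match_report(
    recipient: Genotype,
    donor: Genotype,
    matrix: RMSDMatrix,
    observed_grade: str | None = None,
    cutoff: float = SEVERITY_CUTOFF,
    loci: Iterable[str] | None = None,
) -> MatchReport:
    """Run the full pipeline for one recipient-donor combination."""
    pairs = gvh_mismatches(recipient, donor, matrix, loci=loci)
    return MatchReport(
        recipient_id=recipient.subject_id,
        donor_id=donor.subject_id,
        pairs=pairs,
        observed_grade=observed_grade,
        cutoff=cutoff,
    )


def rank_donors(
    recipient: Genotype,
    donors: Sequence[Genotype],
    matrix: RMSDMatrix,
    cutoff: float = SEVERITY_CUTOFF,
    loci: Iterable[str] | None = None,
) -> list[tuple[str, MatchReport]]:
    """Rank candidate donors ascending by total revised RMSD.

    Ties keep input order (stable sort); the optimal donor is first.
    Lookup failures are annotated with the donor that caused them.
    """
    if not donors:
        raise ValueError("rank_donors needs at least one candidate donor")
    reports = []
    for donor in donors:
        try:
            reports.append(
                (donor.subject_id, match_report(recipient, donor, matrix,
                                                cutoff=cutoff, loci=loci))
            )
        except MatrixLookupError as exc:
            raise MatrixLookupError(
                f"donor {donor.subject_id}: {exc.args[0]}"
            ) from exc
    reports.sort(key=lambda item: item[1].total_revised_rmsd)
    return reports


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between predicted severity class and observed grades."""

    n: int
    n_concordant: int
    discordant_ids: tuple[str, ...]

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_rounded(self) -> int:
        return int(round_half_up(self.percent, 0))


def _dichotomise(grade: str) -> str:
    grade = grade.strip().upper()
    if grade in _MILD_GRADES:
        return MILD
    if grade in _SEVERE_GRADES:
        return SEVERE
    raise ValueError(f"unknown aGVHD grade {grade!r}")


def concordance(reports: Sequence[MatchReport]) -> ConcordanceResult:
    """Percent of reports whose predicted class matches the dichotomised
    observed grade (I/II -> mild, III/IV -> severe)."""
    if not reports:
        raise ValueError("concordance needs at least one graded report")
    discordant = []
    for report in reports:
        if report.observed_grade is None:
            raise ValueError(
                f"report {report.recipient_id}/{report.donor_id} has no "
                "observed grade"
            )
        if report.predicted_class != _dichotomise(report.observed_grade):
            discordant.append(report.recipient_id)
    n = len(reports)
    return ConcordanceResult(
        n=n, n_concordant=n - len(discordant), discordant_ids=tuple(discordant)
    )
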