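"""GVH-direction mismatch resolution, severity rule, ranking, concordance."""

import itertools

import pytest

from hla_tdsm import (
    MatchReport,
    MismatchPair,
    RMSDMatrix,
    RMSDRecord,
    concordance,
    gvh_mismatches,
    match_report,
    parse_allele,
    parse_genotype,
    predict_severity,
    rank_donors,
    total_revised_rmsd,
)
from hla_tdsm.matching import MILD, SEVERE
from hla_tdsm.matrix import MatrixLookupError


def rec(a, b, revised):
    return RMSDRecord(parse_allele(a), parse_allele(b),
                      coordinate_rmsd=revised, revised_rmsd=revised)


def geno(sid, **loci):
    return parse_genotype({k: list(v) for k, v in loci.items()}, sid)


@pytest.fixture
def a_matrix():
    """All pairs among four A-locus alleles."""
    names = ["A*01:01", "A*02:01", "A*11:01", "A*33:01"]
    values = {
        ("A*01:01", "A*02:01"): 0.38,
        ("A*01:01", "A*11:01"): 0.05,
        ("A*01:01", "A*33:01"): 0.21,
        ("A*02:01", "A*11:01"): 0.37,
        ("A*02:01", "A*33:01"): 0.09,
        ("A*11:01", "A*33:01"): 0.12,
    }
    return RMSDMatrix([rec(a, b, v) for (a, b), v in values.items()])


def test_identical_genotypes_have_no_gvh_mismatch(a_matrix):
    g = geno("R", A=("A*02:01", "A*11:01"))
    assert gvh_mismatches(g, g, a_matrix) == []


def test_recipient_allele_covered_by_donor_yields_no_pair(a_matrix):
    # donor carries extra alleles but covers every recipient type
    recipient = geno("R", A=("A*11:01", "A*11:01"))
    donor = geno("D", A=("A*11:01", "A*02:01"))
    assert gvh_mismatches(recipient, donor, a_matrix) == []


def test_homozygous_recipient_counts_one_mismatch(a_matrix):
    recipient = geno("R", A=("A*02:01", "A*02:01"))
    donor = geno("D", A=("A*11:01", "A*11:01"))
    (pair,) = gvh_mismatches(recipient, donor, a_matrix)
    assert pair.recipient_allele.render() == "A*02:01"
    assert pair.donor_allele.render() == "A*11:01"


def test_donor_homozygous_for_shared_allele_pairs_with_it(a_matrix):
    # donor has no unshared allele: partner is the donor allele itself
    recipient = geno("R", A=("A*02:01", "A*11:01"))
    donor = geno("D", A=("A*11:01", "A*11:01"))
    (pair,) = gvh_mismatches(recipient, donor, a_matrix)
    assert (pair.recipient_allele.render(), pair.donor_allele.render()) == (
        "A*02:01", "A*11:01",
    )


def test_donor_homozygous_unshared_produces_two_pairs(a_matrix):
    recipient = geno("R", A=("A*01:01", "A*02:01"))
    donor = geno("D", A=("A*11:01", "A*11:01"))
    pairs = gvh_mismatches(recipient, donor, a_matrix)
    assert len(pairs) == 2
    assert {p.donor_allele.render() for p in pairs} == {"A*11:01"}


def test_two_by_two_assignment_minimises_total(a_matrix):
    recipient = geno("R", A=("A*01:01", "A*02:01"))
    donor = geno("D", A=("A*11:01", "A*33:01"))
    pairs = gvh_mismatches(recipient, donor, a_matrix)
    chosen = {(p.recipient_allele.render(), p.donor_allele.render())
              for p in pairs}
    # 0.05 + 0.09 beats 0.21 + 0.37
    assert chosen == {("A*01:01", "A*11:01"), ("A*02:01", "A*33:01")}


def test_assignment_optimality_exhaustive_2x2():
    """The chosen pairing's sum never exceeds the alternative's."""
    r1, r2 = "A*01:01", "A*02:01"
    d1, d2 = "A*11:01", "A*33:01"
    recipient = geno("R", A=(r1, r2))
    donor = geno("D", A=(d1, d2))
    for v in itertools.product([0.05, 0.2, 0.4], repeat=4):
        matrix = RMSDMatrix([
            rec(r1, d1, v[0]), rec(r1, d2, v[1]),
            rec(r2, d1, v[2]), rec(r2, d2, v[3]),
        ])
        pairs = gvh_mismatches(recipient, donor, matrix)
        chosen = sum(p.revised_rmsd for p in pairs)
        assert chosen <= min(v[0] + v[3], v[1] + v[2]) + 1e-12


def test_gvh_mismatch_invariant_to_slot_order(a_matrix):
    r1 = geno("R", A=("A*01:01", "A*02:01"))
    r2 = geno("R", A=("A*02:01", "A*01:01"))
    d = geno("D", A=("A*11:01", "A*33:01"))
    assert gvh_mismatches(r1, d, a_matrix) == gvh_mismatches(r2, d, a_matrix)


def test_missing_record_error_names_the_pair():
    matrix = RMSDMatrix([rec("A*01:01", "A*02:01", 0.1)])
    recipient = geno("R", A=("A*11:01", "A*11:01"))
    donor = geno("D", A=("A*33:01", "A*33:01"))
    with pytest.raises(MatrixLookupError, match=r"A\*11:01/A\*33:01"):
        gvh_mismatches(recipient, donor, matrix)


# -- totals ----------------------------------------------------------------


def mk_pair(revised, locus="A"):
    a = parse_allele("A*01:01")
    return MismatchPair(locus, a, parse_allele("A*02:01"), revised)


def test_total_revised_rmsd_empty_is_zero():
    assert total_revised_rmsd([]) == 0.0


def test_total_is_exact_fixed_point_sum():
    # a sum that drifts in binary floating point
    pairs = [mk_pair(v) for v in (0.3625, 0.3657, 0.1508, 0.5304)]
    assert total_revised_rmsd(pairs) == 1.4094


def test_single_pair_total_equals_component():
    assert total_revised_rmsd([mk_pair(0.3755)]) == 0.3755


# -- severity --------------------------------------------------------------


@pytest.mark.parametrize(
    "total, single, expected",
    [
        (0.9975, 0.4260, SEVERE),
        (0.2958, 0.1192, MILD),
        (0.6474, 0.3517, SEVERE),  # total rule alone
        (0.0, 0.0, MILD),
        (0.50, 0.1, SEVERE),  # boundary is conservative
    ],
)
def test_predict_severity_rule(total, single, expected):
    assert predict_severity(total, single) == expected


def test_predict_severity_boundary_configurable():
    assert predict_severity(0.50, 0.0, boundary="mild") == MILD


def test_predict_severity_monotone():
    totals = [0.1, 0.3, 0.5, 0.7, 1.2]
    classes = [predict_severity(t, 0.0) for t in totals]
    # once severe, never back to mild as the total grows
    first_severe = classes.index(SEVERE)
    assert all(c == SEVERE for c in classes[first_severe:])


# -- ranking ---------------------------------------------------------------


def test_rank_donors_orders_by_total_and_keeps_ties_stable(a_matrix):
    recipient = geno("R", A=("A*01:01", "A*01:01"))
    donors = [
        geno("D-mid", A=("A*33:01", "A*33:01")),   # 0.21
        geno("D-best1", A=("A*11:01", "A*11:01")),  # 0.05
        geno("D-best2", A=("A*11:01", "A*11:01")),  # 0.05 tie
        geno("D-worst", A=("A*02:01", "A*02:01")),  # 0.38
    ]
    ranked = rank_donors(recipient, donors, a_matrix)
    assert [d for d, _ in ranked] == ["D-best1", "D-best2", "D-mid", "D-worst"]
    assert ranked[0][1].acceptable_choice


def test_rank_donors_single_candidate(a_matrix):
    recipient = geno("R", A=("A*01:01", "A*01:01"))
    ranked = rank_donors(recipient, [geno("D", A=("A*11:01", "A*11:01"))], a_matrix)
    assert len(ranked) == 1 and ranked[0][0] == "D"


def test_rank_donors_annotates_failing_donor(a_matrix):
    recipient = geno("R", A=("A*01:01", "A*01:01"))
    donors = [geno("D-bad", B=("B*07:02", "B*07:02"),
                   A=("A*99:01", "A*99:01"))]
    with pytest.raises(MatrixLookupError, match="D-bad"):
        rank_donors(recipient, donors, a_matrix)


def test_rank_donors_requires_candidates(a_matrix):
    with pytest.raises(ValueError):
        rank_donors(geno("R", A=("A*01:01", "A*01:01")), [], a_matrix)


# -- concordance -----------------------------------------------------------


def report_with(total, grade):
    return MatchReport("R", "D", [mk_pair(total)] if total else [],
                       observed_grade=grade)


def test_concordance_all_concordant_is_100():
    reports = [report_with(0.1, "I"), report_with(0.9, "IV")]
    assert concordance(reports).percent_rounded == 100


def test_concordance_alternating_is_50():
    reports = [
        report_with(0.1, "I"), report_with(0.1, "III"),
        report_with(0.9, "IV"), report_with(0.9, "II"),
    ]
    result = concordance(reports)
    assert result.percent_rounded == 50 and len(result.discordant_ids) == 2


def test_concordance_rounds_half_up():
    # 11/12 = 91.67 -> 92
    reports = [report_with(0.1, "I")] * 11 + [report_with(0.1, "III")]
    assert concordance(reports).percent_rounded == 92


def test_concordance_rejects_empty_and_ungraded():
    with pytest.raises(ValueError):
        concordance([])
    with pytest.raises(ValueError, match="observed grade"):
        concordance([MatchReport("R", "D", [])])
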