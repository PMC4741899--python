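# Methods

## The discrepancy score

Two HLA allele structure models are compared as single-chain Cα traces
in mature-protein 1-based numbering. Residues are paired by residue
number (positions absent from either model are dropped; at least three
common residues are required). The models are superposed by the weighted
Kabsch algorithm — the proper rotation R and translation t minimising
Σ wᵢ |xᵢ − R yᵢ − t|², solved by SVD of the weighted cross-covariance
with the determinant-sign correction — and scored as

RMSD = sqrt( Σ wᵢ |xᵢ − yᵢ|² / Σ wᵢ ),

which with unit weights is the ordinary RMSD over N pairs. Weights
default to 1 for every residue; a per-residue weight vector may be
supplied but no published weighting scheme is assumed. Doubling all
weights leaves the score unchanged.

The **coordinate RMSD** uses all common residues. The **revised RMSD**
restricts pairing to the functional recognition region — the α-helices
and β-sheet of the peptide-binding groove plus TCR-contact stretches:

- class I (A/B/Cw): residues 3–13, 20–38, 45–85, 92–103, 109–127,
  132–178 (149 positions);
- class II (DRB1/DQB1/DPB1): residues 9–18, 21–30, 33–39, 42–47, 50–87
  (71 positions).

Random-coil residues outside these stretches vary without affecting
peptide presentation or TCR engagement, so their displacement is noise
for the clinical question; excluding them is the entire point of the
revised score.

Two open choices were settled as follows. *Fit set*: the revised RMSD
superposes on the region residues themselves (`fit="region"`, default).
The alternative — superpose on all residues, score the region — is
exposed as `fit="all"`; region-fit is never worse on the scored set and
keeps the score a pure function of the region geometry. *Atom
selection*: one coordinate per residue, the Cα atom; the per-residue
formulation of the score names residues, not atoms. A per-file integer
numbering offset handles structure files numbered with the leader
peptide.

Degenerate inputs: fewer than three common residues, a zero weight sum,
or a collinear/coincident point configuration (rotation not uniquely
determined) raise errors naming the condition. Reported values are
rounded half-up to 4 decimals; internal arithmetic is full precision.

## The decision layer

**Acceptability.** A mismatched pair is an acceptable (permissible)
mismatch when its revised RMSD is at or below 0.2 Å for class I loci or
0.1 Å for class II loci. Class II molecules are structurally more
conserved in the scored region, hence the tighter threshold. Thresholds
are configurable; the defaults are the system's published operating
constants.

**GVH-direction resolution.** At each locus typed in both subjects, the
recipient's distinct alleles absent from the donor's alleles are the
GVH-direction mismatches (set semantics on allele types: a recipient
allele carried anywhere by the donor is covered, and a locus where every
recipient allele appears in the donor contributes nothing even if the
donor has extra alleles — those act in the rejection direction, which
this package does not score). Partner selection: donor alleles absent
from the recipient are preferred; with two unshared alleles per side the
pairing is the minimum-total-revised-RMSD bipartite assignment (for 2×2
a two-permutation comparison; solved generally with a linear sum
assignment). A donor homozygous for its unshared allele partners it
with every unmatched recipient allele; a donor with no unshared allele
at all partners the mismatched recipient allele with the donor allele of
minimum revised RMSD.

**Totals and severity.** The total revised RMSD is the sum over all
mismatch pairs, computed in 4-decimal fixed point (decimal arithmetic)
so a reported total equals the sum of its reported components exactly,
with no binary floating drift. Severity is dichotomised: grade III–IV
aGVHD is predicted when the maximum single or the total revised RMSD
reaches the 0.50 Å cutoff, grade I–II otherwise. The published rule
leaves exact equality undefined ("< 0.50" mild, "> 0.50" severe); this
implementation classifies equality as severe — the conservative reading
for a screening rule — and exposes the boundary as a parameter. Since
the total bounds every single value, the single-value clause only
matters if the rule is applied to partial reports.

**Ranking and concordance.** Candidate donors are ordered ascending by
total revised RMSD with stable ties (input order preserved); donors
under the 0.50 Å cutoff are flagged acceptable choices. Concordance
between predicted class and observed grade (I/II mild, III/IV severe)
is reported as an exact fraction and as a half-up-rounded integer
percent.

## Bundled pilot-study records

The package ships transcriptions of the pilot allo-HSCT cohort used to
validate the approach: low-resolution 4-locus genotypes for all 37
recipient–donor pairs, high-resolution genotypes and per-locus mismatch
records (coordinate and revised RMSD, mismatched-residue counts, pocket
and contact annotations) for the 32 transplanted pairs, observed aGVHD
grades, and candidate-donor panels for the five recipients with several
alternative donors. Loading is self-checking: each stated total must
equal the 4-decimal sum of its components, and a violation names the
offending subject.

Source-table inconsistencies are preserved verbatim rather than silently
corrected, and flagged:

- two prospective pairs (P-UPN04, P-UPN05) have stated totals that do
  not equal the sum of their own components; they carry a
  `total_discrepant` note and are exempted from the checksum;
- one pair's A-locus revised RMSD is stated as 0.0929 in the transplant
  table and 0.0930 in the donor-panel table; each record set keeps its
  own value, which is why per-case and per-panel lookups are separate;
- two rows state a mismatch pair that contradicts the genotypes printed
  beside it (a shared allele listed as mismatched); the records are
  stored under the genotype-derived pair with a note.

Each candidate-donor combination keeps its own record set: the published
per-combination pairings are not always the global minimum-sum
assignment over records pooled across a panel (the source appears to
have paired alleles in haplotype listing order in one sibling panel), so
pooling would change one donor's total. Mismatch resolution for a
combination therefore only consults the records published for it.

One retrospective pair (R-UPN07) is a known discordant case — a
recipient with an HLA-A/B locus recombination developed grade IV aGVHD
despite a 0.43 Å single revised RMSD; it is flagged in the records and
bounds the retrospective concordance at 11/12 (92%). The prospective
concordance recomputed under the stated rule is 20/20; the published
95% figure is not derivable from the printed records and is not asserted
anywhere.

## Synthetic data

**Structure pairs.** The generator builds a deterministic pseudo-helical
Cα trace (ideal α-helix geometry, 2.3 Å radius, 1.5 Å rise, 100°/residue,
plus a small seeded wobble so configurations are never degenerate) and a
perturbed copy with a prescribed coordinate or revised RMSD. Gaussian
displacement vectors are restricted to the chosen scope (all residues,
recognition region only, or outside-region only) and projected
orthogonal to the six infinitesimal rigid-body modes of the fit set, so
superposition cannot absorb them; the amplitude is then solved by
Brent's method on the actually-scored RMSD, recovering the target to
~1e-9 (tested at 1e-6 across 100 seeds). The copy is additionally
re-posed by a random rigid transform, which the score must ignore.
Outside-region perturbations leave the revised RMSD at numerical zero by
construction.

**Cohorts.** The cohort simulator draws recipient genotypes from an
invented pool of 8 alleles per locus (A, B, DRB1, DQB1), introduces a
donor mismatch per locus with probability 0.5 by default, and assigns
every within-locus pair a revised RMSD drawn lognormal(μ=−1.4, σ=0.8) —
median ≈ 0.25 Å, bulk within 0.05–0.6 Å, matching the spread of
single-locus clinical values. Observed severity is the 0.50 Å rule
applied to the simulated total, flipped with a configurable probability
f, so expected prediction concordance is exactly 100·(1−f) percent.
What these simulations do **not** emulate: real allele frequencies and
linkage between loci, the empirical shape of the structural-discrepancy
distribution, non-HLA drivers of aGVHD, and clinical grade assignment
noise — passing simulation tests shows the pipeline's internal
consistency, not clinical validity.

## Problem sizes and limitations

The default test and acceptance runs use the bundled 37-pair cohort, 2×2
assignment cases, synthetic traces of 180 (class I) or 90 (class II)
residues, and simulated cohorts of up to 2,000 pairs — sizes chosen to
exercise every code path while keeping any run under a few seconds.

Known limitations: the allele structure corpus itself is an input (no
homology modelling is performed); pocket A–F residue assignments are
external configuration, never built in; legacy 3-digit allele names
(e.g. A*203) are kept as opaque tokens rather than mapped to modern
equivalents; low-resolution alleles parse and report but are rejected by
RMSD lookup, which is keyed on high-resolution names; and the
host-versus-graft (rejection) direction is not scored, though the same
engine runs with arguments swapped.
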