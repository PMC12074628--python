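# Methods

## Coordinate frame and identity conventions

All calls are expressed against a species-keyed reference CDS partitioned
into three exons that tile `1..len(cds)` exactly (1-based, inclusive).
Codons are numbered from the start codon, so "codon 139" is amino-acid
position 139; exon boundaries need not respect codon boundaries. Mutation
identity is the tuple `(species, codon_index, ref_codon, alt_codon)`;
display labels such as `Y139F` are derived by translating both codons with
the standard genetic code. This protects against label typos in input
tables — the shipped catalogue contains one silent Arg codon swap at codon
12 (CGG→CGA) that some sources label as an alanine substitution; the
derived label is `R12R` and the discrepancy is simply not propagated.

The catalogue is data, not code: a TSV of known *Vkorc1* substitutions with
status `resistance_associated`, `novel`, `known_other` or `species_fixed`
and free-text evidence. New literature mutations are row additions, not
releases. `species_fixed` marks positions where two species' wild types
differ — codon 90 is Ile in *R. norvegicus* but Leu in *R. rattus* — which
surface as apparent variants when one reference serves both rat species;
they are annotated and shown but never counted as mutations or toward
prevalence. Substitutions creating a stop codon are classified `nonsense`
even though none is catalogued.

## Exon extraction and assembly

The reference exon is aligned semi-globally against each amplicon (free end
gaps on the amplicon only) on both strands; the higher-scoring strand wins,
a tie goes to `+` with a warning flag. Scoring: +1 when the two symbols'
IUPAC base sets intersect (so a heterozygous W over a reference T is a
match), −1 otherwise, gap open −5, gap extend −1. An extraction is accepted
when identity over the reference exon length is ≥ 0.90 and the alignment is
gap-free. These thresholds are declared defaults, not inferences: how exon
boundaries were located and reads QC'd in the field workflow this models is
not standardised. Indel-bearing amplicons are quarantined with a report
line rather than called — every catalogued resistance variant is a
substitution, and calling codons across an indel from a consensus trace
would be unsafe. Assembly concatenates the three accepted exons in
reference order and is keyed by sample id, so file order cannot scramble a
cohort. Alignment is delegated to biopython's `PairwiseAligner` with a
custom 15×15 IUPAC compatibility matrix; tests verify it against an
exhaustive window-scoring oracle on substitution-only amplicons.

Species identification from a COI barcode is a global pairwise alignment
against a labelled panel; identity = exact-match columns / alignment
length, assignment requires ≥ 98%, ties go to the first panel record and
are flagged. This is a minimal percent-identity classifier, not a
phylogenetic placement.

## Zygosity and codon calls

Zygosity is inferred purely from IUPAC symbols, as Sanger double peaks
admit nothing better: an unambiguous non-reference base is `hom_alt`; a
two-base symbol containing the reference base is `het`; any other ambiguity
(reference-excluding, or 3–4 bases) is `complex_het`, reported but excluded
from counts. `N` is a no-call. Codons are expanded by Cartesian product of
their per-position base sets; a codon with a single heterozygous position
yields exactly the ref and alt alleles, while ≥ 2 heterozygous positions
cannot be phased from one consensus trace — all candidate alleles are
listed, the codon is flagged `phase_ambiguous` and excluded from
single-mutation counts with an explicit report line. Compound
heterozygosity *across* codons (e.g. mice heterozygous for both L128S and
Y139C) is reported per animal; phase across codons is unknown and never
asserted.

## Cohort statistics

A mutation's frequency is `100 · (homozygous + heterozygous carriers) /
species census`; the census includes genotyped animals with zero variants.
Resistance prevalence counts animals with ≥ 1 `resistance_associated`
variant, each once — `novel` and `known_other` variants are listed but
never counted toward prevalence. Rounding is half-up at a per-species
configurable precision (default one decimal for the rat tables, two for
the mouse table, matching the printing conventions of published
frequency tables for these cohort sizes); full precision is kept in the
TSV output, and rendered outputs are byte-stable across runs.

## Structural triage

The binding-site residue set is every protein residue with a heavy atom
within a cutoff (default 5 Å) of any ligand heavy atom. Hydrogens are
ignored everywhere: predicted models lack them and the selection convention
predates protonation. A mutation is "suitable for docking" iff its residue
is in that set; otherwise the reason is its annotated region (cap domain,
ER-luminal region, cytoplasmic interface, membrane), supplied as a YAML
config of residue ranges because such boundaries are drawn on structures,
not derivable from coordinates alone. The ligand's residue name is likewise
configuration. Superposition between species models pairs residues by
number (their sequences are near-identical; an offset parameter covers
numbering shifts) and atoms by name over a backbone (N/CA/C/O) or
sidechain-heavy-atom selection — glycine contributes no sidechain atoms —
then solves the least-squares rigid rotation by SVD of the cross-covariance
matrix with the determinant correction that forbids reflections. Degenerate
(< 3 pairs, collinear) inputs are rejected. Hydrogen bonds are N/O/S
heavy-atom pairs within 3.5 Å, distance-only for the same reason hydrogens
are ignored. PDB parsing goes through gemmi (first model, highest-occupancy
altloc, tie → 'A'). Docking itself — grids, search, binding energies — is
out of scope by design: the triage answers which variants are worth
docking, not what their binding energies are.

## Synthetic cohorts

The generator emulates a three-species field study at the sequence level:
per-animal genotypes (het → IUPAC code, hom → alternate base) applied to
the species reference, species-fixed substitutions applied to every animal
of the species, the CDS split at exon boundaries, each exon wrapped in
20–120 nt of random non-exonic padding (20–200 nt in the randomised
property-test specs) and emitted on a random strand, plus a COI barcode at
< 2% divergence from the species' panel entry. Identical specs produce
byte-identical outputs.

The fixture cohort is the deterministic study-shaped instance: 24 brown
rats, 35 black rats and 8 house mice whose per-animal assignments aggregate
exactly to the published per-mutation homozygote/heterozygote counts, under
the published co-occurrence constraints — the 9 Y139F and 4 R61W brown-rat
carriers are disjoint (13 resistant), 10 black rats carry W59R, and exactly
3 of the 8 mice are heterozygous for both L128S and Y139C so that 4 + 5 − 3
= 6 mice are resistant carriers — giving 29/67 resistant animals (43.28%).
Aggregates determine these statistics but not every joint (which animal
carries which background silent SNP); the remaining joints are drawn by a
fixed-seed shuffle inside the spec builder, so the fixture truth is a
single object. The builder re-counts its own output and fails loudly if the
constraints were ever infeasible.

Real reference sequences are not shipped. A deterministic pseudo-reference
builder plants every catalogue wild-type codon at its codon index inside an
otherwise random 161-codon CDS (ATG start, terminal stop, no internal
stops) with exon partition (1–160, 161–339, 340–483), chosen so exon
boundaries fall inside codons. Both rat species share one reference, so the
black rat's Leu90 wild type surfaces as the species-fixed difference, as it
does when a single *R. norvegicus* reference is used for both rat species.

### What the synthetic data does and does not show

It exercises strand orientation, padding, heterozygote encoding, species
mixing, species-fixed sites and exact count recovery. It does **not** model
base-calling error, chromatogram quality, primer artefacts, indels or
allele dropout — so a green round trip demonstrates the correctness of the
assembly/calling/aggregation logic, not robustness to noisy traces. Inputs
are assumed to be already-called IUPAC consensus sequences.

## Numerical and scale choices

Frequencies are exact rationals rendered by half-up decimal rounding;
determinism everywhere means byte-identical outputs for identical inputs.
The test suite runs the full 67-animal fixture once per session (a few
seconds), 20 randomised 8-animal round-trip cohorts, and oracle comparisons
on ≤ 500 nt amplicons and ≤ 200-atom toy structures; the rotation-search
oracle for the superposition uses a 13³ Euler grid refined by Nelder–Mead
and agrees with the closed-form solution to 10⁻³ Å. Validation of triage
against a real crystal complex and predicted species models requires
downloading those structures and is therefore left as an optional exercise
documented here rather than wired into the default suite; the shipped tests
use a synthetic binding-site stand-in (residues 87/123/128/139 placed in
contact, the remaining panel residues far) to pin the expected
suitable/not-suitable split.

## Known limitations

- No trace/quality model: a peak-height threshold separating hom from het
  calls cannot be represented; the IUPAC symbol is taken at face value.
- Phasing: within-codon double heterozygotes and across-codon compound
  heterozygotes are reported, never resolved.
- The percent-identity species classifier has no confidence model beyond
  the threshold; equidistant panel hits are flagged, not resolved.
- Region annotations for triage are configuration; a different cap-domain
  boundary changes the *reason* strings, never the suitable set.
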