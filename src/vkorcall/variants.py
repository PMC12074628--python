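"""Nucleotide- and codon-level variant calling with IUPAC-derived zygosity.

Sanger consensus sequences encode a heterozygous position as the IUPAC
symbol of its double peak, so zygosity is read directly off the symbol:
an unambiguous non-reference base is a homozygous alternate; a two-base
code containing the reference base is a clean heterozygote; anything else
(a code excluding the reference, or a 3-4 base code) is a complex call
that is reported but excluded from table-style counts.  No read-depth or
peak-height model exists for these data and none is pretended.

Codons with two or more heterozygous positions cannot be phased from a
single consensus trace; all candidate alleles are listed and the codon is
flagged ``phase_ambiguous``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .amplicon import AssembledCDS
from .references import (
    CatalogueEntry,
    ReferenceSet,
    catalogue_lookup,
    expand_iupac,
    translate_codon,
)

__all__ = [
    "NucVariant",
    "CodonVariant",
    "AnnotatedVariant",
    "call_nucleotide_variants",
    "call_codon_variants",
    "classify_variant",
    "call_sample",
]


@dataclass(frozen=True)
class NucVariant:
    cds_pos: int  # 1-based
    ref_base: str
    observed_code: str
    zygosity: str  # hom_alt | het | complex_het

    @property
    def codon_index(self) -> int:
        return (self.cds_pos - 1) // 3 + 1


@dataclass(frozen=True)
class CodonVariant:
    codon_index: int
    ref_codon: str
    observed_codon: str
    allele_codons: tuple[str, ...]  # unambiguous, ref first when present
    effect: str  # silent | missense | nonsense
    zygosity: str
    phase_ambiguous: bool

    @property
    def alt_codons(self) -> tuple[str, ...]:
        return tuple(c for c in self.allele_codons if c != self.ref_codon)

    @property
    def aa_change_label(self) -> str:
        """Derived label, e.g. ``Y139F``; multi-allele codons join with '/'."""
        ref_aa = translate_codon(self.ref_codon)
        alts = self.alt_codons or (self.ref_codon,)
        return "/".join(
            f"{ref_aa}{self.codon_index}{translate_codon(c)}" for c in alts
        )


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: CodonVariant
    catalogue_status: str  # resistance_associated | novel | known_other | species_fixed | unlisted
    evidence: str = ""

    @property
    def excluded_from_counts(self) -> bool:
        """Species-fixed wild types and unphaseable/complex calls do not
        enter frequency tables or prevalence."""
        return (
            self.catalogue_status == "species_fixed"
            or self.variant.phase_ambiguous
            or self.variant.zygosity == "complex_het"
        )


def _zygosity(ref_base: str, observed: str) -> str:
    alleles = expand_iupac(observed)
    if len(alleles) == 1:
        return "hom_alt"
    if len(alleles) == 2 and ref_base in alleles:
        return "het"
    return "complex_het"


def call_nucleotide_variants(
    cds: AssembledCDS, ref: ReferenceSet
) -> tuple[list[NucVariant], list[int]]:
    """All positions where the observed symbol differs from the reference.

    Returns ``(variants, no_call_positions)``; positions observed as N are
    no-calls, skipped with a warning entry rather than called.
    """
    if len(cds.sequence) != len(ref.cds):
        raise ValueError(
            f"{cds.sample_id}: CDS length {len(cds.sequence)} != reference "
            f"{len(ref.cds)}"
        )
    variants: list[NucVariant] = []
    no_calls: list[int] = []
    for pos, (obs, ref_base) in enumerate(zip(cds.sequence, ref.cds), start=1):
        if obs == ref_base:
            continue
        if obs == "N":
            no_calls.append(pos)
            continue
        variants.append(
            NucVariant(
                cds_pos=pos,
                ref_base=ref_base,
                observed_code=obs,
                zygosity=_zygosity(ref_base, obs),
            )
        )
    return variants, no_calls


def call_codon_variants(
    nuc_variants: Sequence[NucVariant],
    cds: AssembledCDS,
    ref: ReferenceSet,
) -> list[CodonVariant]:
    """Group nucleotide variants by codon and expand alleles.

    The observed codon's IUPAC symbols are expanded by Cartesian product.
    A codon with one two-base heterozygous position yields exactly the
    ref and alt alleles; two or more heterozygous positions produce an
    unphaseable expansion flagged ``phase_ambiguous`` with the effect
    evaluated per candidate allele.
    """
    out: list[CodonVariant] = []
    for codon_index in sorted({v.codon_index for v in nuc_variants}):
        ref_codon = ref.codon(codon_index)
        observed = cds.sequence[3 * (codon_index - 1) : 3 * codon_index]
        per_pos = [sorted(expand_iupac(sym)) for sym in observed]
        expansion = ["".join(p) for p in itertools.product(*per_pos)]
        het_positions = sum(1 for p in per_pos if len(p) > 1)
        in_codon = [v for v in nuc_variants if v.codon_index == codon_index]

        phase_ambiguous = len(expansion) > 2
        if any(v.zygosity == "complex_het" for v in in_codon):
            zygosity = "complex_het"
        elif het_positions >= 1:
            zygosity = "het"
        else:
            zygosity = "hom_alt"

        alleles = sorted(set(expansion), key=lambda c: (c != ref_codon, c))
        ref_aa = translate_codon(ref_codon)
        alt_aas = [translate_codon(c) for c in alleles if c != ref_codon]
        if any(aa == "*" for aa in alt_aas):
            effect = "nonsense"
        elif any(aa != ref_aa for aa in alt_aas):
            effect = "missense"
        else:
            effect = "silent"

        out.append(
            CodonVariant(
                codon_index=codon_index,
                ref_codon=ref_codon,
                observed_codon=observed,
                allele_codons=tuple(alleles),
                effect=effect,
                zygosity=zygosity,
                phase_ambiguous=phase_ambiguous,
            )
        )
    return out


def classify_variant(
    cv: CodonVariant,
    species_id: str,
    catalogue: Iterable[CatalogueEntry] | Mapping[tuple, CatalogueEntry],
) -> AnnotatedVariant:
    """Annotate one codon variant with its catalogue status.

    Lookup is by ``(species, codon_index, ref_codon, alt_codon)``; a
    species-fixed hit (the other species' wild type, e.g. Leu90 in the
    black rat) is annotated as such and excluded from count tables by the
    ``excluded_from_counts`` flag.  Unmatched variants are ``unlisted``.
    """
    index = (
        catalogue
        if isinstance(catalogue, Mapping)
        else catalogue_lookup(catalogue)
    )
    for alt in cv.alt_codons:
        entry = index.get((species_id, cv.codon_index, cv.ref_codon, alt))
        if entry is not None:
            return AnnotatedVariant(
                variant=cv, catalogue_status=entry.status, evidence=entry.evidence
            )
    return AnnotatedVariant(variant=cv, catalogue_status="unlisted")


def call_sample(
    cds: AssembledCDS,
    ref: ReferenceSet,
    catalogue: Iterable[CatalogueEntry] | Mapping[tuple, CatalogueEntry],
) -> tuple[list[AnnotatedVariant], list[int]]:
    """Full per-sample call: nucleotide -> codon -> annotated variants."""
    nuc, no_calls = call_nucleotide_variants(cds, ref)
    codon_variants = call_codon_variants(nuc, cds, ref)
    index = (
        catalogue if isinstance(catalogue, Mapping) else catalogue_lookup(catalogue)
    )
    annotated = [classify_variant(cv, cds.species_id, index) for cv in codon_variants]
    return annotated, no_calls
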