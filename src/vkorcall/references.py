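"""Reference sequences, exon partitions, the genetic code and the mutation catalogue.

Everything downstream is expressed in the coordinate frame defined here: a
species-keyed coding sequence (CDS) split into three exons, with codons
numbered 1-based from the start codon so that "codon 139" means amino-acid
position 139.  The resistance-mutation catalogue is data, not code: a TSV of
known *Vkorc1* codon substitutions with their literature status, shipped as a
package resource and extensible without a code change.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData

__all__ = [
    "ReferenceSet",
    "CatalogueEntry",
    "STOP_SYMBOL",
    "translate_codon",
    "expand_iupac",
    "iupac_for",
    "load_reference",
    "load_catalogue",
    "default_catalogue_path",
    "CATALOGUE_STATUSES",
]

STOP_SYMBOL = "*"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: 15 IUPAC nucleotide symbols (gap excluded) -> constituent base sets.
_IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code != "X"
}
_IUPAC_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in _IUPAC_SETS.items()}

CATALOGUE_STATUSES = frozenset(
    {"resistance_associated", "novel", "known_other", "species_fixed"}
)


def translate_codon(codon: str) -> str:
    """Translate an unambiguous DNA triplet to a one-letter amino-acid symbol.

    Stop codons return ``"*"``.  Ambiguity codes or a wrong length raise
    ``ValueError`` — zygosity-aware code must expand IUPAC symbols first.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an unambiguous DNA triplet: {codon!r}")
    if codon in _STANDARD_TABLE.stop_codons:
        return STOP_SYMBOL
    return _STANDARD_TABLE.forward_table[codon]


def expand_iupac(code: str) -> frozenset[str]:
    """Return the base set denoted by a single IUPAC nucleotide symbol.

    ``W -> {A, T}``; unambiguous bases return singletons; ``N`` returns all
    four bases.  Unknown symbols raise ``ValueError``.
    """
    try:
        return _IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC nucleotide symbol: {code!r}") from None


def iupac_for(bases: Iterable[str]) -> str:
    """Inverse of :func:`expand_iupac`: the IUPAC symbol for a base set."""
    key = frozenset(b.upper() for b in bases)
    try:
        return _IUPAC_FOR_SET[key]
    except KeyError:
        raise ValueError(f"no IUPAC symbol for base set {sorted(key)}") from None


@dataclass(frozen=True)
class ReferenceSet:
    """A species reference CDS with its exon partition.

    ``exons`` is an ordered list of ``(exon_index, start, end)`` in 1-based
    inclusive CDS coordinates; the intervals must tile ``1..len(cds)``
    without gap or overlap.  Codon ``i`` occupies CDS positions
    ``3i-2 .. 3i``; exon boundaries need not fall on codon boundaries.
    """

    species_id: str
    cds: str
    exons: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        for i, b in enumerate(cds, start=1):
            if b not in "ACGT":
                raise ValueError(
                    f"{self.species_id}: ambiguity code {b!r} in reference at position {i}"
                )
        if len(cds) % 3 != 0:
            raise ValueError(
                f"{self.species_id}: CDS length {len(cds)} not divisible by 3"
            )
        exons = tuple(sorted(self.exons, key=lambda e: e[0]))
        object.__setattr__(self, "exons", exons)
        if [e[0] for e in exons] != list(range(1, len(exons) + 1)):
            raise ValueError(f"{self.species_id}: exon indices must be 1..{len(exons)}")
        cursor = 1
        for idx, start, end in exons:
            if start > end:
                raise ValueError(f"{self.species_id}: exon {idx} has start > end")
            if start < cursor:
                raise ValueError(
                    f"{self.species_id}: exon overlap at position {start}"
                )
            if start > cursor:
                raise ValueError(
                    f"{self.species_id}: exon tiling gap at position {cursor}"
                )
            cursor = end + 1
        if cursor != len(cds) + 1:
            raise ValueError(
                f"{self.species_id}: exons end at {cursor - 1}, CDS length is {len(cds)}"
            )

    @property
    def codon_count(self) -> int:
        return len(self.cds) // 3

    def exon_interval(self, exon_index: int) -> tuple[int, int]:
        for idx, start, end in self.exons:
            if idx == exon_index:
                return start, end
        raise KeyError(f"no exon {exon_index} in reference {self.species_id}")

    def exon_sequence(self, exon_index: int) -> str:
        start, end = self.exon_interval(exon_index)
        return self.cds[start - 1 : end]

    def codon(self, codon_index: int) -> str:
        if not 1 <= codon_index <= self.codon_count:
            raise IndexError(f"codon {codon_index} out of range 1..{self.codon_count}")
        return self.cds[3 * (codon_index - 1) : 3 * codon_index]


@dataclass(frozen=True)
class CatalogueEntry:
    """One known codon substitution with its literature status.

    The display label is *derived* from translation of ``ref_codon`` and
    ``alt_codon`` — any label column in the input TSV is informative only,
    never trusted (printed labels occasionally disagree with the codons).
    """

    species_scope: tuple[str, ...]
    codon_index: int
    ref_codon: str
    alt_codon: str
    status: str
    evidence: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_codon", self.ref_codon.upper())
        object.__setattr__(self, "alt_codon", self.alt_codon.upper())
        for c in (self.ref_codon, self.alt_codon):
            translate_codon(c)  # validates triplet
        if self.ref_codon == self.alt_codon:
            raise ValueError(f"codon {self.codon_index}: ref and alt codons are equal")
        if self.status not in CATALOGUE_STATUSES:
            raise ValueError(f"unknown catalogue status {self.status!r}")
        if self.status == "species_fixed" and len(self.species_scope) != 1:
            raise ValueError(
                "species_fixed entries must be scoped to exactly one species"
            )

    @property
    def label(self) -> str:
        """e.g. ``Y139F``; silent entries come out as e.g. ``R12R``."""
        return (
            f"{translate_codon(self.ref_codon)}{self.codon_index}"
            f"{translate_codon(self.alt_codon)}"
        )

    @property
    def is_silent(self) -> bool:
        return translate_codon(self.ref_codon) == translate_codon(self.alt_codon)


def load_reference(
    fasta_path: str | Path, exon_table_path: str | Path
) -> dict[str, ReferenceSet]:
    """Load species references from FASTA plus an exon-partition TSV.

    The FASTA holds one record per species (record id = species label).  The
    TSV has columns ``species``, ``exon_index``, ``start``, ``end`` (1-based
    inclusive CDS coordinates).  All :class:`ReferenceSet` invariants are
    enforced; violations raise ``ValueError`` naming the offending position.
    """
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    exons: dict[str, list[tuple[int, int, int]]] = {}
    with open(exon_table_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sp = row["species"]
            if sp not in records:
                raise ValueError(f"exon table references unknown species {sp!r}")
            exons.setdefault(sp, []).append(
                (int(row["exon_index"]), int(row["start"]), int(row["end"]))
            )
    out = {}
    for sp, cds in records.items():
        if sp not in exons:
            raise ValueError(f"no exon partition for species {sp!r}")
        out[sp] = ReferenceSet(species_id=sp, cds=cds, exons=tuple(exons[sp]))
    return out


def default_catalogue_path() -> Path:
    """Path of the catalogue TSV shipped with the package."""
    return Path(str(resources.files("vkorcall").joinpath("data/catalogue.tsv")))


def load_catalogue(
    tsv_path: str | Path | None = None,
    references: Mapping[str, ReferenceSet] | None = None,
) -> list[CatalogueEntry]:
    """Load and validate the mutation catalogue.

    Columns: ``species_scope`` (comma-separated species labels),
    ``codon_index``, ``ref_codon``, ``alt_codon``, ``status``, ``evidence``.
    Duplicate ``(species, codon_index, alt_codon)`` keys raise.  When
    ``references`` is given, each entry's ``ref_codon`` is checked against
    the reference codon at that index (species-fixed substitutions of other
    entries notwithstanding: the check is against the stated reference).
    """
    path = Path(tsv_path) if tsv_path is not None else default_catalogue_path()
    entries: list[CatalogueEntry] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entry = CatalogueEntry(
                species_scope=tuple(
                    s.strip() for s in row["species_scope"].split(",") if s.strip()
                ),
                codon_index=int(row["codon_index"]),
                ref_codon=row["ref_codon"],
                alt_codon=row["alt_codon"],
                status=row["status"],
                evidence=row.get("evidence", ""),
            )
            for sp in entry.species_scope:
                key = (sp, entry.codon_index, entry.alt_codon)
                if key in seen:
                    raise ValueError(
                        f"duplicate catalogue entry for {sp} codon "
                        f"{entry.codon_index} alt {entry.alt_codon}"
                    )
                seen.add(key)
                if references is not None and sp in references:
                    ref_codon = references[sp].codon(entry.codon_index)
                    if ref_codon != entry.ref_codon:
                        raise ValueError(
                            f"catalogue ref codon {entry.ref_codon} at codon "
                            f"{entry.codon_index} disagrees with {sp} reference "
                            f"({ref_codon})"
                        )
            entries.append(entry)
    return entries


def catalogue_lookup(
    catalogue: Iterable[CatalogueEntry],
) -> dict[tuple[str, int, str, str], CatalogueEntry]:
    """Index catalogue entries by ``(species, codon_index, ref_codon, alt_codon)``."""
    index: dict[tuple[str, int, str, str], CatalogueEntry] = {}
    for entry in catalogue:
        for sp in entry.species_scope:
            index[(sp, entry.codon_index, entry.ref_codon, entry.alt_codon)] = entry
    return index
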