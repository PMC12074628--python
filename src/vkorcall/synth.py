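"""Synthetic rodent cohorts with planted *Vkorc1* genotypes.

Generates everything the pipeline consumes — per-exon amplicon FASTAs with
random non-exonic padding and random strand, COI barcodes, reference FASTA
and exon table, and a truth TSV of planted genotypes — so every stage is
testable end to end without any external download.

The shipped fixture cohort mirrors the field study this package models:
24 brown rats, 35 black rats and 8 house mice (67 animals), with per-animal
homozygous/heterozygous codon substitutions whose aggregates reproduce the
published per-species frequency tables and the 29/67 resistance prevalence,
honouring the published co-occurrence constraints (Y139F and R61W disjoint
in brown rats; exactly three mice heterozygous for both L128S and Y139C).
Joint details the aggregates do not determine (which animal carries which
background silent SNP) are assigned by a fixed-seed shuffle.

Real GenBank references are not required: a deterministic pseudo-reference
builder plants every catalogue wild-type codon at its codon index inside an
otherwise random 161-codon CDS (ATG start, terminal stop, no internal
stops) partitioned into three exons whose boundaries do not fall on codon
boundaries.  Both rat species share one reference — as a study using a
single *R. norvegicus* reference would — so the Leu90 wild type of the
black rat surfaces as a species-fixed substitution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import revcomp
from .references import (
    CatalogueEntry,
    ReferenceSet,
    iupac_for,
    load_catalogue,
    translate_codon,
)
from .structure import Atom, Structure

__all__ = [
    "SPECIES_NAMES",
    "CohortSpec",
    "GeneratedCohort",
    "build_fixture_spec",
    "make_pseudo_references",
    "make_barcode_panel",
    "generate_cohort",
    "verify_roundtrip",
    "random_spec",
    "write_pdb",
]

SPECIES_NAMES = {
    "Rnor": "Rattus norvegicus",
    "Rrat": "Rattus rattus",
    "Mmus": "Mus musculus",
}

CDS_CODONS = 161
EXON_PARTITION = ((1, 1, 160), (2, 161, 339), (3, 340, 483))
_REFERENCE_SEED = 104729  # fixed: references are part of the study frame
_PANEL_SEED = 15485863
_FIXTURE_JOINT_SEED = 2023
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate_codon(a + b + c) != "*"
]

#: per-species (codon_index, alt_codon, hom_count, het_count) aggregates of
#: the fixture cohort; resistance rows are placed under the explicit
#: co-occurrence constraints, everything else by seeded shuffle.
FIXTURE_COUNTS: dict[str, list[tuple[int, str, int, int]]] = {
    "Rnor": [
        (28, "CAG", 1, 0),
        (61, "TGG", 2, 2),
        (82, "ATT", 10, 0),
        (96, "GGC", 0, 1),
        (123, "AGC", 1, 0),
        (139, "TTT", 9, 0),
    ],
    "Rrat": [
        (7, "GGC", 0, 1),
        (12, "CGA", 34, 1),
        (28, "CAG", 1, 2),
        (35, "CGT", 0, 1),
        (36, "CAT", 1, 0),
        (41, "GCA", 8, 6),
        (42, "CCC", 5, 3),
        (59, "AGG", 6, 4),
        (94, "CTA", 18, 2),
        (96, "GGC", 0, 1),
        (107, "ATA", 34, 0),
        (123, "TTC", 0, 3),
        (137, "ACT", 34, 0),
        (143, "GCA", 17, 13),
    ],
    "Mmus": [
        (78, "CAC", 0, 1),
        (85, "CGC", 0, 1),
        (87, "TTA", 0, 1),
        (128, "TCA", 1, 3),
        (139, "TGT", 1, 4),
    ],
}

FIXTURE_CENSUS = {"Rnor": 24, "Rrat": 35, "Mmus": 8}


@dataclass
class CohortSpec:
    """Truth specification of a synthetic cohort.

    ``assignments`` maps each sample id to its planted genotypes as
    ``(codon_index, alt_codon, zygosity)`` triples (zygosity ``hom_alt`` or
    ``het``); species-fixed substitutions are applied implicitly from the
    catalogue and are not assignments.  ``background_rates`` optionally adds
    per-animal sampled silent mutations on top (used by randomised specs,
    empty for the fixture whose counts are exact).
    """

    seed: int
    census: dict[str, int]
    animals: tuple[tuple[str, str], ...]  # (sample_id, species)
    assignments: dict[str, tuple[tuple[int, str, str], ...]]
    background_rates: dict[str, dict[tuple[int, str], tuple[float, float]]] = field(
        default_factory=dict
    )
    pad_range: tuple[int, int] = (20, 120)

    def __post_init__(self) -> None:
        for sp, n in self.census.items():
            have = sum(1 for _, s in self.animals if s == sp)
            if have != n:
                raise ValueError(f"census says {n} {sp} animals, got {have}")
        species_of = dict(self.animals)
        for sample in self.assignments:
            if sample not in species_of:
                raise ValueError(f"assignment for unknown sample {sample!r}")
            codons = [c for c, _, _ in self.assignments[sample]]
            if len(codons) != len(set(codons)):
                raise ValueError(f"{sample}: multiple assignments at one codon")

    def aggregate_counts(self) -> dict[str, dict[tuple[int, str], tuple[int, int]]]:
        """Recount (hom, het) per (codon, alt) per species from assignments."""
        species_of = dict(self.animals)
        out: dict[str, dict[tuple[int, str], list[int]]] = {}
        for sample, geno in self.assignments.items():
            sp = species_of[sample]
            for codon, alt, zyg in geno:
                rec = out.setdefault(sp, {}).setdefault((codon, alt), [0, 0])
                rec[0 if zyg == "hom_alt" else 1] += 1
        return {
            sp: {k: (v[0], v[1]) for k, v in d.items()} for sp, d in out.items()
        }

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "census": self.census,
            "animals": [list(a) for a in self.animals],
            "assignments": {
                s: [list(g) for g in geno] for s, geno in self.assignments.items()
            },
            "background_rates": {
                sp: {f"{c}:{a}": list(p) for (c, a), p in d.items()}
                for sp, d in self.background_rates.items()
            },
            "pad_range": list(self.pad_range),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            seed=int(d["seed"]),
            census={k: int(v) for k, v in d["census"].items()},
            animals=tuple((a, s) for a, s in d["animals"]),
            assignments={
                s: tuple((int(c), alt, z) for c, alt, z in geno)
                for s, geno in d["assignments"].items()
            },
            background_rates={
                sp: {
                    (int(k.split(":")[0]), k.split(":")[1]): (float(p[0]), float(p[1]))
                    for k, p in d.items()
                }
                for sp, d in d.get("background_rates", {}).items()
            },
            pad_range=tuple(d.get("pad_range", (20, 120))),
        )


def make_pseudo_references(
    catalogue: Sequence[CatalogueEntry] | None = None,
    seed: int = _REFERENCE_SEED,
) -> dict[str, ReferenceSet]:
    """Deterministic stand-in references with catalogue wild-type codons
    planted at their codon indices.  Both rat species share one CDS."""
    catalogue = list(catalogue) if catalogue is not None else load_catalogue()
    rng = np.random.default_rng(seed)

    def build(species_ids: Iterable[str]) -> str:
        ids = set(species_ids)
        planted: dict[int, str] = {}
        for entry in catalogue:
            if not ids & set(entry.species_scope):
                continue
            if entry.status == "species_fixed":
                # the shared reference carries the *other* species' wild type
                planted.setdefault(entry.codon_index, entry.ref_codon)
                continue
            prev = planted.get(entry.codon_index)
            if prev is not None and prev != entry.ref_codon:
                raise ValueError(
                    f"conflicting reference codons at codon {entry.codon_index}"
                )
            planted[entry.codon_index] = entry.ref_codon
        codons = ["ATG"]
        for idx in range(2, CDS_CODONS):
            codons.append(
                planted.get(idx, _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))])
            )
        codons.append("TAA")
        return "".join(codons)

    rat_cds = build({"Rnor", "Rrat"})
    mouse_cds = build({"Mmus"})
    return {
        "Rnor": ReferenceSet("Rnor", rat_cds, EXON_PARTITION),
        "Rrat": ReferenceSet("Rrat", rat_cds, EXON_PARTITION),
        "Mmus": ReferenceSet("Mmus", mouse_cds, EXON_PARTITION),
    }


def make_barcode_panel(length: int = 620, seed: int = _PANEL_SEED) -> dict[str, str]:
    """Fixed species-labelled COI barcode panel (independent random
    sequences; pairwise identity ~25%, far below any threshold)."""
    rng = np.random.default_rng(seed)
    return {
        sp: "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        for sp in sorted(SPECIES_NAMES)
    }


def build_fixture_spec(seed: int = 0) -> CohortSpec:
    """The deterministic study-shaped fixture: 24 + 35 + 8 animals whose
    assignments aggregate exactly to the published per-mutation counts.

    ``seed`` controls only the sequence-level randomness downstream
    (padding, strand, barcode noise); the genotype joints use a fixed
    internal seed so the cohort's truth is one object, not a family.
    """
    rng = np.random.default_rng(_FIXTURE_JOINT_SEED)
    animals: list[tuple[str, str]] = []
    for sp, n in FIXTURE_CENSUS.items():
        animals.extend((f"{sp}_{i:02d}", sp) for i in range(1, n + 1))
    assignments: dict[str, list[tuple[int, str, str]]] = {a: [] for a, _ in animals}

    def ids(sp: str) -> list[str]:
        return [a for a, s in animals if s == sp]

    def place(pool: Sequence[str], codon: int, alt: str, hom: int, het: int) -> list[str]:
        chosen = list(rng.choice(pool, size=hom + het, replace=False))
        for sample in chosen[:hom]:
            assignments[sample].append((codon, alt, "hom_alt"))
        for sample in chosen[hom:]:
            assignments[sample].append((codon, alt, "het"))
        return chosen

    # brown rats: Y139F and R61W carriers are disjoint
    rn = ids("Rnor")
    y139f = place(rn, 139, "TTT", 9, 0)
    place([a for a in rn if a not in y139f], 61, "TGG", 2, 2)
    for codon, alt, hom, het in FIXTURE_COUNTS["Rnor"]:
        if codon in (139, 61):
            continue
        place(rn, codon, alt, hom, het)

    # black rats: no cross-mutation constraint
    rr = ids("Rrat")
    for codon, alt, hom, het in FIXTURE_COUNTS["Rrat"]:
        place(rr, codon, alt, hom, het)

    # mice: |L128S ∩ Y139C| = 3, all heterozygous on both
    mm = ids("Mmus")
    picked = list(rng.choice(mm, size=6, replace=False))
    l128s_hom, doubles, y139c_hom, y139c_het = picked[0], picked[1:4], picked[4], picked[5]
    assignments[l128s_hom].append((128, "TCA", "hom_alt"))
    for sample in doubles:
        assignments[sample].append((128, "TCA", "het"))
        assignments[sample].append((139, "TGT", "het"))
    assignments[y139c_hom].append((139, "TGT", "hom_alt"))
    assignments[y139c_het].append((139, "TGT", "het"))
    for codon, alt, hom, het in FIXTURE_COUNTS["Mmus"]:
        if codon in (128, 139):
            continue
        place(mm, codon, alt, hom, het)

    spec = CohortSpec(
        seed=seed,
        census=dict(FIXTURE_CENSUS),
        animals=tuple(animals),
        assignments={a: tuple(g) for a, g in assignments.items()},
    )
    # self-check: aggregates must match the declared counts exactly
    agg = spec.aggregate_counts()
    for sp, rows in FIXTURE_COUNTS.items():
        for codon, alt, hom, het in rows:
            got = agg.get(sp, {}).get((codon, alt), (0, 0))
            if got != (hom, het):
                raise RuntimeError(
                    f"fixture spec infeasible: {sp} codon {codon} {alt} "
                    f"expected {(hom, het)}, built {got}"
                )
    return spec


def _mutate_codon(cds: list[str], codon_index: int, alt: str, zygosity: str) -> None:
    start = 3 * (codon_index - 1)
    for offset in range(3):
        ref_base = cds[start + offset]
        alt_base = alt[offset]
        if alt_base == ref_base:
            continue
        if zygosity == "hom_alt":
            cds[start + offset] = alt_base
        else:
            cds[start + offset] = iupac_for({ref_base, alt_base})


@dataclass
class GeneratedCohort:
    out_dir: Path
    spec: CohortSpec
    truth: pd.DataFrame
    exon_fastas: dict[int, Path]
    coi_fasta: Path
    panel_fasta: Path
    reference_fasta: Path
    exon_table: Path
    truth_path: Path


def generate_cohort(
    spec: CohortSpec,
    references: Mapping[str, ReferenceSet],
    catalogue: Sequence[CatalogueEntry],
    out_dir: str | Path,
) -> GeneratedCohort:
    """Materialise a cohort: per-exon amplicon FASTAs, COI FASTA + panel,
    reference FASTA + exon table, truth TSV and a spec echo JSON.

    Heterozygous genotypes become IUPAC codes in a single consensus
    sequence, as Sanger double peaks would; each exon is wrapped in random
    padding drawn from ``spec.pad_range`` and emitted on a random strand.
    Same spec -> byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    panel = make_barcode_panel()
    fixed_by_species: dict[str, list[CatalogueEntry]] = {}
    for entry in catalogue:
        if entry.status == "species_fixed":
            fixed_by_species.setdefault(entry.species_scope[0], []).append(entry)

    exon_records: dict[int, list[tuple[str, str]]] = {e[0]: [] for e in EXON_PARTITION}
    coi_records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    bases = np.array(list("ACGT"))

    for sample, sp in spec.animals:
        ref = references[sp]
        cds = list(ref.cds)
        for entry in fixed_by_species.get(sp, []):
            _mutate_codon(cds, entry.codon_index, entry.alt_codon, "hom_alt")
        genotypes = list(spec.assignments.get(sample, ()))
        assigned_codons = {c for c, _, _ in genotypes}
        for (codon, alt), (p_hom, p_het) in sorted(
            spec.background_rates.get(sp, {}).items()
        ):
            if codon in assigned_codons:
                continue
            u = rng.random()
            if u < p_hom:
                genotypes.append((codon, alt, "hom_alt"))
            elif u < p_hom + p_het:
                genotypes.append((codon, alt, "het"))
        for codon, alt, zyg in genotypes:
            ref_codon = ref.codon(codon)
            _mutate_codon(cds, codon, alt, zyg)
            truth_rows.append(
                {
                    "sample_id": sample,
                    "species": sp,
                    "codon_index": codon,
                    "ref_codon": ref_codon,
                    "alt_codon": alt,
                    "zygosity": zyg,
                }
            )
        seq = "".join(cds)
        for exon_idx, start, end in ref.exons:
            exon_seq = seq[start - 1 : end]
            lo, hi = spec.pad_range
            left = "".join(bases[rng.integers(0, 4, size=rng.integers(lo, hi + 1))])
            right = "".join(bases[rng.integers(0, 4, size=rng.integers(lo, hi + 1))])
            amplicon = left + exon_seq + right
            if rng.random() < 0.5:
                amplicon = revcomp(amplicon)
            exon_records[exon_idx].append((f"{sample}|{sp}|exon{exon_idx}", amplicon))
        coi = list(panel[sp])
        n_mut = rng.integers(0, max(2, len(coi) // 100))  # < 2% divergence
        for pos in rng.choice(len(coi), size=n_mut, replace=False):
            alternatives = [b for b in "ACGT" if b != coi[pos]]
            coi[pos] = alternatives[rng.integers(0, 3)]
        coi_records.append((f"{sample}|{sp}", "".join(coi)))

    def write_fasta(path: Path, records: Iterable[tuple[str, str]]) -> Path:
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        return path

    exon_fastas = {
        idx: write_fasta(out_dir / f"exon{idx}.fasta", recs)
        for idx, recs in exon_records.items()
    }
    coi_fasta = write_fasta(out_dir / "coi.fasta", coi_records)
    panel_fasta = write_fasta(out_dir / "coi_panel.fasta", sorted(panel.items()))

    seen: set[str] = set()
    ref_records = []
    for sp in sorted(references):
        ref_records.append((sp, references[sp].cds))
        seen.add(sp)
    reference_fasta = write_fasta(out_dir / "references.fasta", ref_records)
    exon_table = out_dir / "exons.tsv"
    with open(exon_table, "w") as fh:
        fh.write("species\texon_index\tstart\tend\n")
        for sp in sorted(references):
            for idx, start, end in references[sp].exons:
                fh.write(f"{sp}\t{idx}\t{start}\t{end}\n")

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "species", "codon_index", "ref_codon", "alt_codon", "zygosity"],
    ).sort_values(["sample_id", "codon_index"], kind="stable").reset_index(drop=True)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    with open(out_dir / "spec.json", "w") as fh:
        json.dump(spec.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return GeneratedCohort(
        out_dir=out_dir,
        spec=spec,
        truth=truth,
        exon_fastas=exon_fastas,
        coi_fasta=coi_fasta,
        panel_fasta=panel_fasta,
        reference_fasta=reference_fasta,
        exon_table=exon_table,
        truth_path=truth_path,
    )


@dataclass
class RoundTripReport:
    mismatches: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def verify_roundtrip(
    truth: pd.DataFrame, variants_by_sample: Mapping[str, Sequence]
) -> RoundTripReport:
    """Exact comparison of planted genotypes against pipeline calls.

    Species-fixed calls are not part of the truth (they are the species
    wild type, applied implicitly) and are ignored on the call side.
    """
    expected = {
        (r.sample_id, int(r.codon_index), r.alt_codon, r.zygosity)
        for r in truth.itertuples()
    }
    observed = set()
    for sample, annotated in variants_by_sample.items():
        for av in annotated:
            if av.catalogue_status == "species_fixed":
                continue
            cv = av.variant
            for alt in cv.alt_codons:
                observed.add((sample, cv.codon_index, alt, cv.zygosity))
    mismatches = [f"missing call: {t}" for t in sorted(expected - observed)]
    mismatches += [f"unexpected call: {t}" for t in sorted(observed - expected)]
    return RoundTripReport(mismatches=mismatches)


def random_spec(
    seed: int,
    references: Mapping[str, ReferenceSet],
    catalogue: Sequence[CatalogueEntry],
    census: Mapping[str, int] | None = None,
    pad_range: tuple[int, int] = (20, 200),
) -> CohortSpec:
    """A randomised small cohort for property tests: each animal receives a
    random subset of catalogued genotypes of its species at random
    zygosity."""
    rng = np.random.default_rng(seed)
    census = dict(census or {"Rnor": 3, "Rrat": 3, "Mmus": 2})
    animals = []
    for sp, n in census.items():
        animals.extend((f"{sp}_{i:02d}", sp) for i in range(1, n + 1))
    by_species: dict[str, list[CatalogueEntry]] = {}
    for entry in catalogue:
        if entry.status == "species_fixed":
            continue
        for sp in entry.species_scope:
            by_species.setdefault(sp, []).append(entry)
    assignments = {}
    for sample, sp in animals:
        pool = by_species.get(sp, [])
        genotypes = []
        used_codons: set[int] = set()
        for entry in pool:
            if entry.codon_index in used_codons or rng.random() > 0.3:
                continue
            used_codons.add(entry.codon_index)
            zyg = "hom_alt" if rng.random() < 0.5 else "het"
            genotypes.append((entry.codon_index, entry.alt_codon, zyg))
        assignments[sample] = tuple(genotypes)
    return CohortSpec(
        seed=seed,
        census=census,
        animals=tuple(animals),
        assignments=assignments,
        pad_range=pad_range,
    )


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a minimal PDB coordinate file (toy fixtures only)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            record = "HETATM" if a.is_ligand else "ATOM"
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3}"
            fh.write(
                f"{record:<6}{i:>5} {name}{a.altloc or ' '}{a.residue_name:>3} "
                f"{a.chain}{a.residue_number:>4}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}\n"
            )
        fh.write("END\n")
    return path
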