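"""End-to-end genotyping: amplicons -> assembled CDS -> annotated variants
-> cohort summary."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .amplicon import (
    AssembledCDS,
    ExonAmplicon,
    SpeciesCall,
    assemble_cds,
    extract_exon,
    identify_species,
    read_amplicon_fasta,
)
from .cohort import CohortSummary, summarize_cohort
from .references import CatalogueEntry, ReferenceSet, catalogue_lookup
from .variants import AnnotatedVariant, call_sample

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files"]


@dataclass
class PipelineResult:
    summary: CohortSummary
    variants_by_sample: dict[str, list[AnnotatedVariant]]
    census: dict[str, str]
    assembled: dict[str, AssembledCDS]
    species_calls: dict[str, SpeciesCall]
    assembly_report: pd.DataFrame
    quarantined: dict[str, list[str]] = field(default_factory=dict)
    no_calls: dict[str, list[int]] = field(default_factory=dict)


def run_pipeline(
    amplicons: Sequence[ExonAmplicon],
    references: Mapping[str, ReferenceSet],
    catalogue: Sequence[CatalogueEntry],
    coi_by_sample: Mapping[str, str] | None = None,
    barcode_panel: Mapping[str, str] | None = None,
    min_identity: float = 0.90,
    precision: Mapping[str, int] | None = None,
) -> PipelineResult:
    """Genotype a cohort of exon amplicons.

    Species come from COI identification when a barcode panel and per-sample
    COI sequences are supplied, else from the amplicon species hints.
    Samples whose exons fail extraction (indel, low identity, missing exon)
    are quarantined and reported, not called; they still do not enter the
    census denominator, since without an accepted assembly the animal was
    not genotyped.
    """
    by_sample: dict[str, list[ExonAmplicon]] = {}
    for amp in amplicons:
        by_sample.setdefault(amp.sample_id, []).append(amp)

    species_calls: dict[str, SpeciesCall] = {}
    census: dict[str, str] = {}
    assembled: dict[str, AssembledCDS] = {}
    quarantined: dict[str, list[str]] = {}
    report_rows: list[dict] = []

    for sample in sorted(by_sample):
        amps = by_sample[sample]
        if coi_by_sample is not None and barcode_panel is not None and sample in coi_by_sample:
            call = identify_species(coi_by_sample[sample], barcode_panel)
            species_calls[sample] = call
            if call.decision != "assigned":
                quarantined[sample] = ["species unresolved from COI barcode"]
                continue
            species = call.best_species
        else:
            hints = {a.species_hint for a in amps if a.species_hint}
            if len(hints) != 1:
                quarantined[sample] = [f"ambiguous species hints {sorted(hints)}"]
                continue
            species = hints.pop()
        if species not in references:
            quarantined[sample] = [f"no reference for species {species!r}"]
            continue
        ref = references[species]

        alignments = []
        problems = []
        for amp in sorted(amps, key=lambda a: a.exon_index):
            aln = extract_exon(amp, ref, min_identity=min_identity)
            report_rows.append(
                {
                    "sample_id": sample,
                    "species": species,
                    "exon_index": aln.exon_index,
                    "strand": aln.strand,
                    "identity": round(aln.identity, 4),
                    "gap_count": aln.gap_count,
                    "accepted": aln.accepted,
                    "flags": ",".join(aln.flags),
                }
            )
            if aln.accepted:
                alignments.append(aln)
            else:
                problems.append(f"exon {aln.exon_index}: {','.join(aln.flags)}")
        if problems or len(alignments) != len(ref.exons):
            quarantined[sample] = problems or ["incomplete exon set"]
            continue
        assembled[sample] = assemble_cds(alignments, ref, sample, species)
        census[sample] = species

    index = catalogue_lookup(catalogue)
    variants_by_sample: dict[str, list[AnnotatedVariant]] = {}
    no_calls: dict[str, list[int]] = {}
    for sample, cds in assembled.items():
        annotated, ncs = call_sample(cds, references[cds.species_id], index)
        variants_by_sample[sample] = annotated
        if ncs:
            no_calls[sample] = ncs

    summary = summarize_cohort(variants_by_sample, census, precision=precision)
    return PipelineResult(
        summary=summary,
        variants_by_sample=variants_by_sample,
        census=census,
        assembled=assembled,
        species_calls=species_calls,
        assembly_report=pd.DataFrame(
            report_rows,
            columns=[
                "sample_id",
                "species",
                "exon_index",
                "strand",
                "identity",
                "gap_count",
                "accepted",
                "flags",
            ],
        ),
        quarantined=quarantined,
        no_calls=no_calls,
    )


def run_pipeline_files(
    exon_fastas: Sequence[str | Path],
    references: Mapping[str, ReferenceSet],
    catalogue: Sequence[CatalogueEntry],
    coi_fasta: str | Path | None = None,
    panel_fasta: str | Path | None = None,
    **kwargs,
) -> PipelineResult:
    """File-level front end of :func:`run_pipeline` (FASTA dialect
    ``sampleID|species|exonN``)."""
    from Bio import SeqIO

    amplicons: list[ExonAmplicon] = []
    for path in exon_fastas:
        amplicons.extend(read_amplicon_fasta(path))
    coi_by_sample = None
    panel = None
    if coi_fasta is not None and panel_fasta is not None:
        coi_by_sample = {
            rec.id.split("|")[0]: str(rec.seq)
            for rec in SeqIO.parse(str(coi_fasta), "fasta")
        }
        panel = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(panel_fasta), "fasta")
        }
    return run_pipeline(
        amplicons,
        references,
        catalogue,
        coi_by_sample=coi_by_sample,
        barcode_panel=panel,
        **kwargs,
    )
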