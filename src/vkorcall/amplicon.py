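"""Exon location inside Sanger amplicons, strand resolution and CDS assembly.

Each animal is sequenced as three exon amplicons: the exon plus flanking
non-exonic sequence, on an unknown strand.  The reference exon is aligned
semi-globally against the amplicon (free end gaps on the amplicon side) on
both strands with an IUPAC-compatibility scoring scheme, so a heterozygous
double-peak code (e.g. W over a reference T) scores as a match.  Accepted
extractions are gap-free; indel-bearing amplicons are quarantined rather
than called, since every catalogued variant is a substitution.

Samples are keyed by sample id throughout — assembly never depends on file
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .references import ReferenceSet, expand_iupac

__all__ = [
    "ExonAmplicon",
    "ExonAlignment",
    "AssembledCDS",
    "SpeciesCall",
    "identify_species",
    "extract_exon",
    "assemble_cds",
    "read_amplicon_fasta",
]

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"

# Scoring: match +1 when the two symbols' base sets intersect, else -1;
# gap open -5, extend -1; end gaps on the amplicon are free.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0


def bases_compatible(a: str, b: str) -> bool:
    """True when two IUPAC symbols can denote the same base."""
    return bool(expand_iupac(a) & expand_iupac(b))


def _iupac_matrix() -> substitution_matrices.Array:
    mat = substitution_matrices.Array(alphabet=IUPAC_ALPHABET, dims=2)
    for a in IUPAC_ALPHABET:
        for b in IUPAC_ALPHABET:
            mat[a, b] = MATCH_SCORE if bases_compatible(a, b) else MISMATCH_SCORE
    return mat


_MATRIX = _iupac_matrix()


def _semiglobal_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps on the amplicon (target) only: the exon floats inside it
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (W stays W, R <-> Y, ...)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ExonAmplicon:
    sample_id: str
    exon_index: int
    sequence: str
    species_hint: str | None = None
    source_file: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.sample_id} exon {self.exon_index}: empty sequence")
        bad = set(seq) - set(IUPAC_ALPHABET)
        if bad:
            raise ValueError(
                f"{self.sample_id} exon {self.exon_index}: "
                f"non-IUPAC symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class ExonAlignment:
    """Where the reference exon sits inside one amplicon.

    ``amplicon_window`` is 1-based inclusive on the reported strand;
    ``extracted_exon`` has exactly the reference exon length whenever the
    extraction is accepted.
    """

    exon_index: int
    strand: str
    amplicon_window: tuple[int, int]
    identity: float
    gap_count: int
    extracted_exon: str
    accepted: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AssembledCDS:
    sample_id: str
    species_id: str
    sequence: str
    provenance: tuple[ExonAlignment, ...]


@dataclass(frozen=True)
class SpeciesCall:
    sample_id: str
    best_species: str
    identity_pct: float
    decision: str  # assigned | unresolved
    tie: bool = False


def extract_exon(
    amplicon: ExonAmplicon,
    ref: ReferenceSet,
    min_identity: float = 0.90,
) -> ExonAlignment:
    """Locate the reference exon inside an amplicon on either strand.

    The higher-scoring strand wins (tie -> '+', flagged).  Acceptance
    requires identity >= ``min_identity`` over the reference exon length and
    a gap-free alignment; indels flag the amplicon for quarantine instead of
    producing a call.
    """
    exon_seq = ref.exon_sequence(amplicon.exon_index)
    aligner = _semiglobal_aligner()
    candidates = []
    for strand, seq in (("+", amplicon.sequence), ("-", revcomp(amplicon.sequence))):
        aln = aligner.align(seq, exon_seq)[0]
        candidates.append((aln.score, strand, seq, aln))
    (score_f, _, _, _), (score_r, _, _, _) = candidates
    flags: list[str] = []
    if score_f == score_r:
        best = candidates[0]
        flags.append("strand_tie")
    else:
        best = max(candidates, key=lambda c: c[0])
    _, strand, seq, aln = best

    t_blocks, q_blocks = aln.aligned
    exon_len = len(exon_seq)
    covered = int(sum(e - s for s, e in q_blocks))
    internal_gaps = 0
    for (t0, t1), (t0n, _), (q0, q1), (q0n, _) in zip(
        t_blocks, t_blocks[1:], q_blocks, q_blocks[1:]
    ):
        internal_gaps += (t0n - t1) + (q0n - q1)
    gap_count = internal_gaps + (exon_len - covered)

    if gap_count == 0:
        start = int(t_blocks[0][0])
        window = seq[start : start + exon_len]
        identity = (
            sum(bases_compatible(a, b) for a, b in zip(window, exon_seq)) / exon_len
        )
        extracted = window
        span = (start + 1, start + exon_len)
    else:
        # gapped best alignment: identity over aligned columns, for reporting
        matched = sum(
            bases_compatible(seq[ti], exon_seq[qi])
            for (ts, te), (qs, _) in zip(t_blocks, q_blocks)
            for ti, qi in zip(range(ts, te), itertools.count(qs))
        )
        identity = matched / exon_len
        extracted = ""
        span = (int(t_blocks[0][0]) + 1, int(t_blocks[-1][1]))
        flags.append("indel")

    accepted = gap_count == 0 and identity >= min_identity
    if identity < min_identity:
        flags.append("exon_not_found")
    return ExonAlignment(
        exon_index=amplicon.exon_index,
        strand=strand,
        amplicon_window=span,
        identity=identity,
        gap_count=gap_count,
        extracted_exon=extracted,
        accepted=accepted,
        flags=tuple(flags),
    )


def assemble_cds(
    alignments: Iterable[ExonAlignment],
    ref: ReferenceSet,
    sample_id: str,
    species_id: str,
) -> AssembledCDS:
    """Join the three extracted exons into the complete CDS.

    Requires exactly one accepted alignment per exon index; concatenation
    follows the reference exon order regardless of input order.
    """
    by_exon: dict[int, ExonAlignment] = {}
    for aln in alignments:
        if aln.exon_index in by_exon:
            raise ValueError(f"{sample_id}: duplicate alignment for exon {aln.exon_index}")
        by_exon[aln.exon_index] = aln
    expected = [e[0] for e in ref.exons]
    missing = [i for i in expected if i not in by_exon]
    if missing:
        raise ValueError(f"{sample_id}: missing exon(s) {missing}")
    rejected = [i for i in expected if not by_exon[i].accepted]
    if rejected:
        raise ValueError(f"{sample_id}: exon(s) {rejected} not accepted for assembly")
    sequence = "".join(by_exon[i].extracted_exon for i in expected)
    if len(sequence) != len(ref.cds):
        raise RuntimeError(
            f"{sample_id}: assembled length {len(sequence)} != reference "
            f"{len(ref.cds)}"
        )
    return AssembledCDS(
        sample_id=sample_id,
        species_id=species_id,
        sequence=sequence,
        provenance=tuple(by_exon[i] for i in expected),
    )


def identify_species(
    coi_sequence: str,
    barcode_panel: Sequence[tuple[str, str]] | Mapping[str, str],
    threshold: float = 98.0,
) -> SpeciesCall:
    """Assign a species by percent identity against a COI barcode panel.

    ``barcode_panel`` is an ordered ``(species, sequence)`` collection (or
    mapping).  Identity is exact-match columns over alignment length of a
    global pairwise alignment.  Assignment requires identity >= ``threshold``
    (percent); ties go to the first panel entry and are flagged.
    """
    if isinstance(barcode_panel, Mapping):
        panel = list(barcode_panel.items())
    else:
        panel = list(barcode_panel)
    if not panel:
        raise ValueError("empty barcode panel")
    coi = coi_sequence.upper()
    bad = set(coi) - set(IUPAC_ALPHABET)
    if bad:
        raise ValueError(f"non-nucleotide symbols in COI query: {sorted(bad)}")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND

    best_species, best_identity, tie = None, -1.0, False
    for species, barcode in panel:
        aln = aligner.align(barcode.upper(), coi)[0]
        counts = aln.counts()
        identity = 100.0 * counts.identities / aln.length
        if identity > best_identity:
            best_species, best_identity, tie = species, identity, False
        elif identity == best_identity:
            tie = True
    decision = "assigned" if best_identity >= threshold else "unresolved"
    return SpeciesCall(
        sample_id="",
        best_species=best_species,
        identity_pct=round(best_identity, 2),
        decision=decision,
        tie=tie,
    )


def read_amplicon_fasta(
    path: str | Path, exon_index: int | None = None
) -> list[ExonAmplicon]:
    """Read amplicons from FASTA with record ids ``sampleID|species|exonN``.

    A two-field id ``sampleID|species`` is allowed when ``exon_index`` is
    given explicitly (one-file-per-exon layout).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 3 and parts[2].lower().startswith("exon"):
            sample, species, exon = parts[0], parts[1], int(parts[2][4:])
        elif len(parts) == 2 and exon_index is not None:
            sample, species, exon = parts[0], parts[1], exon_index
        else:
            raise ValueError(
                f"cannot parse amplicon record id {rec.id!r}; expected "
                "'sampleID|species|exonN'"
            )
        out.append(
            ExonAmplicon(
                sample_id=sample,
                exon_index=exon,
                sequence=str(rec.seq),
                species_hint=species,
                source_file=str(path),
            )
        )
    return out
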