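# vkorcall

Genotyping of anticoagulant-rodenticide resistance in rodents from Sanger
*Vkorc1* exon amplicons, with a geometric triage of candidate mutations
against a protein–ligand complex and a synthetic-cohort generator that makes
the whole pipeline testable end to end without any external data.

## The problem

Anticoagulant rodenticides (warfarin and the second-generation compounds
such as brodifacoum) inhibit the vitamin K epoxide reductase (VKOR) enzyme.
Point mutations in *Vkorc1*, the gene encoding its catalytic subunit, confer
resistance in brown rats (*Rattus norvegicus*), black rats (*R. rattus*) and
house mice (*Mus musculus*), and monitoring their spread is the basis of
integrated pest-control policy. Field genotyping of *Vkorc1* proceeds by
Sanger sequencing three exon amplicons per animal, joining the exons into
the complete coding sequence (CDS), and comparing against a species
reference. A heterozygous animal shows a double peak at the variant
position, which base callers encode as an IUPAC ambiguity symbol (W = A/T,
R = A/G, …), so both the variant and its zygosity are readable from a
single consensus sequence.

`vkorcall` implements that analysis as a reusable pipeline:

1. **amplicon** — locate each exon inside its amplicon on either strand by
   semi-global alignment with IUPAC-compatibility scoring, and assemble the
   CDS per animal (samples keyed by id, never by file order). Optional COI
   barcode identification confirms the species by percent identity.
2. **variants** — call nucleotide and codon-level variants against the
   reference; zygosity from the IUPAC symbol (hom / het / complex); effect
   (silent / missense / nonsense) derived by translation; annotation against
   a shipped catalogue of known *Vkorc1* mutations
   (resistance-associated / novel / known-other / species-fixed).
3. **cohort** — per-species frequency tables (frequency = carriers/census,
   homozygous + heterozygous) and the resistance prevalence headline, each
   animal counted once however many resistance SNPs it carries.
4. **structure** — binding-site contact sets (residues within 5 Å of the
   ligand), Kabsch superposition RMSD, distance-based hydrogen-bond
   detection, and the "suitable for docking" classification of mutations by
   their position relative to the binding site.
5. **synth** — synthetic cohorts with planted genotypes and a truth table,
   including a deterministic 67-animal fixture (24 brown rats, 35 black
   rats, 8 mice) whose aggregates reproduce published per-mutation counts.

Mutation labels follow the `Y139F` convention (wild-type amino acid, codon
number, variant amino acid) and are always *derived* by translation of the
ref/alt codons, never trusted from input.

## Worked example

```bash
vkorcall simulate --seed 2 --out sim/       # study-shaped 67-animal cohort
vkorcall run \
  --exons sim/exon1.fasta --exons sim/exon2.fasta --exons sim/exon3.fasta \
  --reference sim/references.fasta --exon-table sim/exons.tsv \
  --coi sim/coi.fasta --panel sim/coi_panel.fasta \
  --out run/
```

prints

```
29/67 animals carry a resistance-associated SNP (43.28%)
```

and `run/report.txt` contains, per species, the frequency table — e.g. for
the house mice:

```
Mmus (n = 8)
codon mutation       freq %  homo  het  status
   78 Q78H CAA>CAC    12.50     0    1  novel
   85 C85R TGC>CGC    12.50     0    1  novel
   87 F87L TTC>TTA    12.50     0    1  novel
  128 L128S TTA>TCA    50.00     1    3  resistance_associated
  139 Y139C TAT>TGT    62.50     1    4  resistance_associated
resistant animals: 6/8
```

Half the mice carry L128S (one homozygous, three heterozygous), five of
eight carry Y139C, three mice are heterozygous for both — counted once —
so six of eight mice are resistant carriers. `run/summary_*.tsv` holds the
same tables at full precision and `run/summary.json` the machine-readable
counts.

Structural triage works the same way from the shell:

```bash
vkorcall triage --structure complex.pdb --ligand BFC \
  --mutations mutations.tsv --out triage.tsv
```

classifying each mutated residue as `suitable` (within 5 Å of the ligand)
or `not_suitable` with its structural region (cap domain, ER-luminal,
cytoplasmic interface, membrane) as the reason.

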