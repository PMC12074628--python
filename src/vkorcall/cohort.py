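"""Per-species frequency tables and resistance prevalence.

A mutation's frequency is the number of animals carrying it — homozygous or
heterozygous — over the species census.  Resistance prevalence counts each
animal once if it carries at least one resistance-associated variant,
regardless of how many it carries.  Species-fixed wild-type differences and
unphaseable/complex calls are listed but never counted.

Rounding is half-up at a per-species configurable precision (brown/black
rat tables conventionally print one decimal, the mouse table two); full
precision is retained in the TSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .variants import AnnotatedVariant

__all__ = [
    "CohortSummary",
    "summarize_cohort",
    "compute_prevalence",
    "render_tables",
    "round_half_up",
    "DEFAULT_PRECISION",
]

#: printed decimals per species; species not listed default to 1
DEFAULT_PRECISION: dict[str, int] = {"Mmus": 2}

_TABLE_COLUMNS = [
    "codon_index",
    "ref_codon",
    "alt_codon",
    "label",
    "effect",
    "status",
    "frequency_pct",
    "frequency",
    "homo",
    "het",
    "carriers",
]


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (3.25 -> 3.3 at one decimal), as printed
    tables conventionally round."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Aggregated cohort: per-species mutation tables plus the headline."""

    species_tables: dict[str, pd.DataFrame]
    n_animals: dict[str, int]
    resistant_by_species: dict[str, int]
    resistant_animal_count: int
    total_animals: int
    prevalence_pct: float
    excluded_records: list[dict] = field(default_factory=list)
    precision: dict[str, int] = field(default_factory=dict)

    def frequency(self, species: str, codon_index: int, alt_codon: str) -> float:
        """Rendered frequency cell for one mutation, in percent."""
        df = self.species_tables[species]
        row = df[(df.codon_index == codon_index) & (df.alt_codon == alt_codon)]
        if row.empty:
            return 0.0
        return float(row.iloc[0]["frequency"])

    def counts(self, species: str, codon_index: int, alt_codon: str) -> tuple[int, int]:
        df = self.species_tables[species]
        row = df[(df.codon_index == codon_index) & (df.alt_codon == alt_codon)]
        if row.empty:
            return 0, 0
        return int(row.iloc[0]["homo"]), int(row.iloc[0]["het"])

    def to_json_dict(self) -> dict:
        out: dict = {"species": {}, "prevalence": {
            "resistant": self.resistant_animal_count,
            "total": self.total_animals,
            "pct": self.prevalence_pct,
        }}
        for sp in sorted(self.species_tables):
            df = self.species_tables[sp]
            out["species"][sp] = {
                "n": self.n_animals[sp],
                "resistant": self.resistant_by_species.get(sp, 0),
                "mutations": df.to_dict(orient="records"),
            }
        out["excluded"] = self.excluded_records
        return out


def summarize_cohort(
    variants_by_sample: Mapping[str, Sequence[AnnotatedVariant]],
    census: Mapping[str, str],
    precision: Mapping[str, int] | None = None,
) -> CohortSummary:
    """Build per-species tables and the resistance headline.

    ``census`` maps every animal — including those with zero variants — to
    its species; denominators come from the census, never from the variant
    lists.  An animal in ``variants_by_sample`` but not in the census is an
    error.
    """
    precision = dict(DEFAULT_PRECISION) | dict(precision or {})
    for sample in variants_by_sample:
        if sample not in census:
            raise ValueError(f"sample {sample!r} has no species in the census")

    species_list = sorted(set(census.values()))
    n_animals = {sp: sum(1 for s in census.values() if s == sp) for sp in species_list}

    counts: dict[str, dict[tuple, dict]] = {sp: {} for sp in species_list}
    resistant: dict[str, set[str]] = {sp: set() for sp in species_list}
    excluded: list[dict] = []

    for sample, annotated in variants_by_sample.items():
        sp = census[sample]
        for av in annotated:
            cv = av.variant
            if cv.phase_ambiguous or cv.zygosity == "complex_het":
                excluded.append(
                    {
                        "sample_id": sample,
                        "species": sp,
                        "codon_index": cv.codon_index,
                        "observed_codon": cv.observed_codon,
                        "alleles": "/".join(cv.allele_codons),
                        "reason": "phase unresolved"
                        if cv.phase_ambiguous
                        else "complex heterozygote",
                    }
                )
                continue
            alt = cv.alt_codons[0]
            key = (cv.codon_index, cv.ref_codon, alt)
            rec = counts[sp].setdefault(
                key,
                {
                    "label": cv.aa_change_label,
                    "effect": cv.effect,
                    "status": av.catalogue_status,
                    "homo": 0,
                    "het": 0,
                },
            )
            rec["homo" if cv.zygosity == "hom_alt" else "het"] += 1
            if av.catalogue_status == "resistance_associated":
                resistant[sp].add(sample)

    tables: dict[str, pd.DataFrame] = {}
    for sp in species_list:
        rows = []
        dec = precision.get(sp, 1)
        for (codon_index, ref_codon, alt_codon), rec in sorted(counts[sp].items()):
            carriers = rec["homo"] + rec["het"]
            freq = 100.0 * carriers / n_animals[sp]
            rows.append(
                {
                    "codon_index": codon_index,
                    "ref_codon": ref_codon,
                    "alt_codon": alt_codon,
                    "label": rec["label"],
                    "effect": rec["effect"],
                    "status": rec["status"],
                    "frequency_pct": freq,
                    "frequency": round_half_up(freq, dec),
                    "homo": rec["homo"],
                    "het": rec["het"],
                    "carriers": carriers,
                }
            )
        tables[sp] = pd.DataFrame(rows, columns=_TABLE_COLUMNS)

    resistant_total = sum(len(v) for v in resistant.values())
    total = sum(n_animals.values())
    prevalence = round_half_up(100.0 * resistant_total / total, 2) if total else 0.0
    return CohortSummary(
        species_tables=tables,
        n_animals=n_animals,
        resistant_by_species={sp: len(v) for sp, v in resistant.items()},
        resistant_animal_count=resistant_total,
        total_animals=total,
        prevalence_pct=prevalence,
        excluded_records=excluded,
        precision=precision,
    )


def compute_prevalence(summary: CohortSummary) -> tuple[int, int, float]:
    """Headline triple: (resistant animals, total animals, percent)."""
    return (
        summary.resistant_animal_count,
        summary.total_animals,
        summary.prevalence_pct,
    )


def render_tables(summary: CohortSummary, out_dir: str | Path) -> list[Path]:
    """Write per-species TSVs, a human-readable text report and a
    machine-readable JSON.  Output bytes are stable across runs: rows are
    sorted by codon index then alternate codon, floats formatted fixedly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for sp in sorted(summary.species_tables):
        df = summary.species_tables[sp].copy()
        dec = summary.precision.get(sp, 1)
        path = out_dir / f"summary_{sp}.tsv"
        df["frequency_pct"] = df["frequency_pct"].map(lambda v: f"{v:.6f}")
        df["frequency"] = df["frequency"].map(lambda v: f"{v:.{dec}f}")
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    lines = ["Cohort genotyping summary", "========================="]
    for sp in sorted(summary.species_tables):
        df = summary.species_tables[sp]
        dec = summary.precision.get(sp, 1)
        lines.append("")
        lines.append(f"{sp} (n = {summary.n_animals[sp]})")
        lines.append(f"{'codon':>5} {'mutation':<12} {'freq %':>8} {'homo':>5} {'het':>4}  status")
        for _, r in df.iterrows():
            lines.append(
                f"{r.codon_index:>5} {r.label + ' ' + r.ref_codon + '>' + r.alt_codon:<12} "
                f"{r.frequency:>8.{dec}f} {r.homo:>5} {r.het:>4}  {r.status}"
            )
        lines.append(
            f"resistant animals: {summary.resistant_by_species.get(sp, 0)}"
            f"/{summary.n_animals[sp]}"
        )
    lines.append("")
    lines.append(
        f"Cohort prevalence of resistance-associated Vkorc1 SNPs: "
        f"{summary.resistant_animal_count}/{summary.total_animals} "
        f"= {summary.prevalence_pct:.2f}%"
    )
    if summary.excluded_records:
        lines.append("")
        lines.append("Excluded calls (not counted):")
        for rec in summary.excluded_records:
            lines.append(
                f"  {rec['sample_id']} codon {rec['codon_index']} "
                f"{rec['observed_codon']} ({rec['reason']})"
            )
    lines.append("")
    report = out_dir / "report.txt"
    report.write_text("\n".join(lines))
    written.append(report)

    json_path = out_dir / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(json_path)
    return written
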