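"""Geometric triage of mutations against a protein-ligand complex.

The question a docking study has to answer *before* docking is which
mutated residues can plausibly change ligand binding at all.  The triage
here is purely geometric: a residue whose heavy atoms come within a cutoff
(default 5 A) of any ligand heavy atom is "suitable for docking"; anything
else is excluded with the structural region it sits in (cap domain,
ER-luminal region, cytoplasmic interface, membrane) as the reason.
Superposition quality between species models is quantified by least-squares
rigid-body (Kabsch) RMSD over a configurable atom selection, and putative
hydrogen bonds are detected as polar heavy-atom pairs within a distance
cutoff — models without hydrogens support no angle criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "Structure",
    "ContactSet",
    "SuperpositionResult",
    "TriageDecision",
    "read_structure",
    "ligand_neighborhood",
    "kabsch_superpose",
    "superpose_structures",
    "detect_hbonds",
    "triage_mutation",
    "load_regions",
    "default_regions_path",
]

POLAR_ELEMENTS = frozenset({"N", "O", "S"})
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    is_ligand: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class Structure:
    """A flat atom list from the first model of a PDB file, with the ligand
    tagged by selector (residue name, or ``chain:resnum``)."""

    atoms: tuple[Atom, ...]
    ligand_selector: str

    def protein_atoms(self, heavy_only: bool = True) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if not a.is_ligand and (not heavy_only or not a.is_hydrogen)
        ]

    def ligand_atoms(self, heavy_only: bool = True) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.is_ligand and (not heavy_only or not a.is_hydrogen)
        ]

    def residue_numbers(self) -> frozenset[int]:
        return frozenset(a.residue_number for a in self.atoms if not a.is_ligand)

    def residue_atoms(
        self, residue_number: int, selection: str = "all"
    ) -> list[Atom]:
        """``selection``: all | backbone | sidechain (heavy atoms only).
        Glycine contributes no sidechain atoms."""
        atoms = [
            a
            for a in self.atoms
            if not a.is_ligand
            and a.residue_number == residue_number
            and not a.is_hydrogen
        ]
        if selection == "backbone":
            return [a for a in atoms if a.atom_name in BACKBONE_ATOMS]
        if selection == "sidechain":
            return [a for a in atoms if a.atom_name not in BACKBONE_ATOMS]
        return atoms


@dataclass(frozen=True)
class ContactSet:
    """Protein residues with any heavy atom within ``cutoff`` of any ligand
    heavy atom, with per-residue minimum distances."""

    cutoff: float
    members: tuple[tuple[str, int, str], ...]  # (chain, resnum, resname)
    min_distances: Mapping[tuple[str, int, str], float]
    structure_residues: frozenset[int]

    @property
    def residue_numbers(self) -> frozenset[int]:
        return frozenset(m[1] for m in self.members)

    def __contains__(self, residue_number: int) -> bool:
        return residue_number in self.residue_numbers


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    atom_pair_count: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class TriageDecision:
    mutation_label: str
    residue_number: int
    decision: str  # suitable | not_suitable
    reason: str


def _match_ligand(res: gemmi.Residue, chain_name: str, selector: str) -> bool:
    if ":" in selector:
        chain, num = selector.split(":", 1)
        return chain_name == chain and res.seqid.num == int(num)
    return res.name == selector


def read_structure(pdb_path: str | Path, ligand_selector: str) -> Structure:
    """Parse PDB coordinates (first model only) and tag the ligand.

    Alternate locations are resolved to the highest-occupancy conformer
    (tie: altloc 'A').  Raises when the file has no atoms or the selector
    matches nothing.
    """
    st = gemmi.read_structure(str(pdb_path))
    if len(st) == 0:
        raise ValueError(f"no models in {pdb_path}")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            is_lig = _match_ligand(res, chain.name, ligand_selector)
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if (
                    prev is None
                    or atom.occ > prev.occ
                    or (atom.occ == prev.occ and atom.altloc < prev.altloc)
                ):
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=atom.occ,
                        altloc=atom.altloc,
                        is_ligand=is_lig,
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms in {pdb_path}")
    if not any(a.is_ligand for a in atoms):
        raise ValueError(f"ligand selector {ligand_selector!r} matches no residue")
    if not all(np.isfinite([a.x, a.y, a.z]).all() for a in atoms):
        raise ValueError("non-finite coordinates")
    return Structure(atoms=tuple(atoms), ligand_selector=ligand_selector)


def ligand_neighborhood(s: Structure, cutoff: float = 5.0) -> ContactSet:
    """Binding-site residue set: protein residues with any heavy atom within
    ``cutoff`` A of any ligand heavy atom (hydrogens excluded)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot = s.protein_atoms()
    lig = s.ligand_atoms()
    min_d: dict[tuple[str, int, str], float] = {}
    if prot and lig:
        p = np.array([[a.x, a.y, a.z] for a in prot])
        l = np.array([[a.x, a.y, a.z] for a in lig])
        d = np.sqrt(((p[:, None, :] - l[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        for atom, dist in zip(prot, d):
            key = (atom.chain, atom.residue_number, atom.residue_name)
            min_d[key] = min(min_d.get(key, np.inf), float(dist))
    members = tuple(sorted(k for k, v in min_d.items() if v <= cutoff))
    return ContactSet(
        cutoff=cutoff,
        members=members,
        min_distances={k: min_d[k] for k in members},
        structure_residues=s.residue_numbers(),
    )


def kabsch_superpose(
    fixed_coords: np.ndarray, mobile_coords: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid-body superposition of paired coordinate sets.

    Returns the proper rotation (det +1 — reflections are forbidden) and
    translation minimising the RMSD of ``mobile`` onto ``fixed``, computed
    by SVD of the cross-covariance matrix.  Requires >= 3 non-collinear
    pairs.
    """
    fixed = np.asarray(fixed_coords, dtype=float)
    mobile = np.asarray(mobile_coords, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = fixed.shape[0]
    if n < 3:
        raise ValueError("at least 3 atom pairs required")
    fc = fixed.mean(axis=0)
    mc = mobile.mean(axis=0)
    f0 = fixed - fc
    m0 = mobile - mc
    if np.linalg.matrix_rank(f0, tol=1e-8) < 2 or np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    h = m0.T @ f0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = fc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum() / n))
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, atom_pair_count=n
    )


def superpose_structures(
    fixed: Structure,
    mobile: Structure,
    residue_numbers: Iterable[int],
    selection: str = "backbone",
    residue_offset: int = 0,
) -> SuperpositionResult:
    """Superpose two structures over paired residues.

    Residues are paired by number (``mobile_number = fixed_number +
    residue_offset``); within a residue, atoms pair by name over the chosen
    ``selection`` (backbone N/CA/C/O or sidechain heavy atoms).  Sequence
    near-identity between species models justifies number-based pairing; no
    structural alignment is attempted.
    """
    fixed_pts, mobile_pts = [], []
    for rn in residue_numbers:
        fa = {a.atom_name: a for a in fixed.residue_atoms(rn, selection)}
        ma = {a.atom_name: a for a in mobile.residue_atoms(rn + residue_offset, selection)}
        for name in sorted(fa.keys() & ma.keys()):
            fixed_pts.append(fa[name].coords)
            mobile_pts.append(ma[name].coords)
    if len(fixed_pts) < 3:
        raise ValueError("fewer than 3 paired atoms in the selection")
    return kabsch_superpose(np.array(fixed_pts), np.array(mobile_pts))


def detect_hbonds(
    s: Structure,
    dist_cutoff: float = 3.5,
    polar_elements: frozenset[str] = POLAR_ELEMENTS,
) -> list[tuple[Atom, Atom, float]]:
    """Putative protein-ligand hydrogen bonds: polar heavy-atom pairs
    (N/O/S) within ``dist_cutoff`` A, sorted by distance.  Distance-only —
    hydrogen positions (hence donor-acceptor angles) are unavailable in the
    models this targets."""
    prot = [a for a in s.protein_atoms() if a.element in polar_elements]
    lig = [a for a in s.ligand_atoms() if a.element in polar_elements]
    out = []
    for pa in prot:
        for la in lig:
            d = float(np.linalg.norm(pa.coords - la.coords))
            if d <= dist_cutoff:
                out.append((pa, la, d))
    out.sort(key=lambda t: (t[2], t[0].residue_number, t[0].atom_name, t[1].atom_name))
    return out


def default_regions_path() -> Path:
    from importlib import resources

    return Path(str(resources.files("vkorcall").joinpath("data/regions.yaml")))


def load_regions(path: str | Path | None = None) -> dict[str, list[tuple[int, int]]]:
    """Load the region-annotation config: tag -> list of residue ranges."""
    with open(path or default_regions_path()) as fh:
        raw = yaml.safe_load(fh)
    return {tag: [(int(a), int(b)) for a, b in ranges] for tag, ranges in raw.items()}


def _region_tag(
    residue_number: int, regions: Mapping[str, Sequence[tuple[int, int]]]
) -> str:
    for tag, ranges in regions.items():
        for lo, hi in ranges:
            if lo <= residue_number <= hi:
                return tag
    return "other region"


def triage_mutation(
    mutation_label: str,
    residue_number: int,
    contact_set: ContactSet,
    region_annotations: Mapping[str, Sequence[tuple[int, int]]],
) -> TriageDecision:
    """Docking-suitability decision for one mutated residue.

    Suitable iff the residue belongs to the ligand neighborhood; otherwise
    not suitable, with its annotated region as the reason.  A residue absent
    from the structure entirely is an error.
    """
    if residue_number not in contact_set.structure_residues:
        raise ValueError(f"residue {residue_number} absent from the structure")
    if residue_number in contact_set:
        return TriageDecision(
            mutation_label=mutation_label,
            residue_number=residue_number,
            decision="suitable",
            reason="in contact with the ligand "
            f"(within {contact_set.cutoff:g} A)",
        )
    return TriageDecision(
        mutation_label=mutation_label,
        residue_number=residue_number,
        decision="not_suitable",
        reason=_region_tag(residue_number, region_annotations),
    )
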