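"""Protein structures, solvent exposure, residue contacts and surface neighborhoods.

This module is the geometric substrate of the contact-prediction pipeline:
it parses PDB files into a light-weight residue/atom model, computes
solvent-accessible surface areas (SASA) per residue, selects surface
residues as contact candidates, finds heavy-atom residue contacts at a
distance criterion (5 A by default, the CAPRI convention), and builds the
spatial neighborhoods used to aggregate per-pair descriptors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Residue identifier: (chain id, residue number, insertion code; '' if none).
ResidueId = tuple[str, int, str]

# van der Waals radii in Angstrom for heavy elements commonly found in
# protein structures.  Unlisted elements fall back to 1.7 A with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

#: Backbone heavy-atom names; everything else counts as side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Heavy-atom contact criterion (A) used throughout, per the CAPRI convention.
CONTACT_DISTANCE = 5.0

#: Default full-residue exposed-area cutoff (A^2) for surface candidates.
SURFACE_AREA_CUTOFF = 38.0


class StructureError(ValueError):
    """Raised for malformed or empty structure input."""


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) float64, Angstrom

    @property
    def rid(self) -> ResidueId:
        return (self.chain, self.number, self.icode)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_coord(self, name: str) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None


@dataclass
class Structure:
    """Chains -> residues -> heavy atoms, in file order."""

    id: str
    residues: list[Residue]
    _index: dict[ResidueId, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {r.rid: i for i, r in enumerate(self.residues)}
        if len(self._index) != len(self.residues):
            raise StructureError(
                f"duplicate residue identifiers in structure {self.id!r}"
            )

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self._index

    def residue(self, rid: ResidueId) -> Residue:
        return self.residues[self._index[rid]]

    def residue_ids(self) -> list[ResidueId]:
        return [r.rid for r in self.residues]

    def all_coords(self) -> np.ndarray:
        return np.concatenate([r.coords for r in self.residues])

    def atom_residue_index(self) -> np.ndarray:
        """Residue index of every atom, aligned with :meth:`all_coords`."""
        return np.repeat(
            np.arange(len(self.residues)), [r.n_atoms for r in self.residues]
        )

    def sequence1(self, chain: str) -> str:
        """One-letter sequence of a chain (``X`` for non-standard residues)."""
        return "".join(
            THREE_TO_ONE.get(r.name, "X") for r in self.residues if r.chain == chain
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates mapped to ``R @ x + t``."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        residues = [
            Residue(
                r.chain,
                r.number,
                r.icode,
                r.name,
                list(r.atom_names),
                list(r.elements),
                r.coords @ rot.T + t,
            )
            for r in self.residues
        ]
        return Structure(self.id, residues)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _validate_pdb_lines(pdb_text: str) -> None:
    """Check coordinate and occupancy fields of ATOM/HETATM records.

    gemmi is forgiving about garbage in fixed-column fields; the pipeline
    wants a hard error naming the offending line instead.
    """
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureError(f"PDB line {lineno}: truncated ATOM record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                value = float(line[lo:hi])
            except ValueError:
                raise StructureError(
                    f"PDB line {lineno}: unparseable {what} coordinate "
                    f"{line[lo:hi].strip()!r}"
                ) from None
            if not math.isfinite(value):
                raise StructureError(f"PDB line {lineno}: non-finite {what} coordinate")


def parse_structure(
    pdb_text: str,
    structure_id: str = "",
    include_hetatm: bool = False,
) -> Structure:
    """Parse PDB text into a heavy-atom :class:`Structure`.

    Hydrogens (and deuterium) are removed.  Alternate locations are resolved
    deterministically: for each atom name within a residue, the altloc with
    the highest occupancy wins, ties going to the first in file order.
    Residues keep their file order.  Only the first model is read.
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no model found in PDB input")
    residues: list[Residue] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and not include_hetatm:
                if res.name != "MSE":  # selenomethionine treated as standard
                    continue
            # best altloc per atom name: highest occupancy, ties -> first seen
            by_name: dict[str, tuple[float, str, np.ndarray]] = {}
            order: list[str] = []
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                prev = by_name.get(atom.name)
                if prev is None:
                    order.append(atom.name)
                    by_name[atom.name] = (atom.occ, atom.element.name.upper(), pos)
                elif atom.occ > prev[0]:
                    by_name[atom.name] = (atom.occ, atom.element.name.upper(), pos)
            if not by_name:
                continue
            names = order
            coords = np.array([by_name[n][2] for n in names])
            elements = [by_name[n][1] for n in names]
            if not np.isfinite(coords).all():
                raise StructureError(
                    f"non-finite coordinates in residue {chain.name} {res.seqid.num}"
                )
            residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name,
                    atom_names=names,
                    elements=elements,
                    coords=coords,
                )
            )
    if not residues:
        raise StructureError("structure contains no heavy atoms")
    return Structure(structure_id or st.name or "structure", residues)


def write_pdb(structure: Structure) -> str:
    """Serialize a structure as minimal PDB ATOM records (deterministic)."""
    lines = []
    serial = 0
    for r in structure.residues:
        for name, elem, (x, y, z) in zip(r.atom_names, r.elements, r.coords):
            serial += 1
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{r.name:<3s} {r.chain:1s}"
                f"{r.number:4d}{r.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def vdw_radius(element: str, _warned: set = set()) -> float:
    el = element.upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    if el not in _warned:
        _warned.add(el)
        logger.warning(
            "no van der Waals radius for element %r; using %.2f A",
            element, DEFAULT_VDW_RADIUS,
        )
    return DEFAULT_VDW_RADIUS


@dataclass
class ResidueAreas:
    """Per-residue solvent-exposed areas in A^2 (full residue and side chain)."""

    full: dict[ResidueId, float]
    side_chain: dict[ResidueId, float]

    def __getitem__(self, rid: ResidueId) -> tuple[float, float]:
        return self.full[rid], self.side_chain[rid]


def compute_residue_areas(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> ResidueAreas:
    """Shrake-Rupley SASA per residue, heavy atoms only.

    A probe sphere is rolled over the heavy atoms; each atom's accessible
    area is estimated from ``n_sphere_points`` Fibonacci-distributed test
    points and summed per residue.  Side-chain areas sum over atoms outside
    the N/CA/C/O backbone, so glycine has side-chain area 0.
    """
    import biotite.structure as struc

    if len(structure) == 0:
        raise StructureError("empty structure")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")

    coords = structure.all_coords()
    n_atoms = coords.shape[0]
    arr = struc.AtomArray(n_atoms)
    arr.coord = coords.astype(np.float32)
    res_index = structure.atom_residue_index()
    arr.res_id = res_index + 1
    arr.chain_id = np.array(
        [structure.residues[i].chain for i in res_index], dtype="U4"
    )
    elements = np.array(
        [e for r in structure.residues for e in r.elements], dtype="U2"
    )
    arr.element = elements
    arr.atom_name = np.array(
        [n for r in structure.residues for n in r.atom_names], dtype="U6"
    )
    arr.res_name = np.array(
        [structure.residues[i].name for i in res_index], dtype="U5"
    )
    radii = np.array([vdw_radius(e) for e in elements])

    atom_sasa = struc.sasa(
        arr,
        probe_radius=probe_radius,
        vdw_radii=radii,
        point_number=n_sphere_points,
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)

    full: dict[ResidueId, float] = {}
    side: dict[ResidueId, float] = {}
    pos = 0
    for r in structure.residues:
        chunk = atom_sasa[pos : pos + r.n_atoms]
        pos += r.n_atoms
        full[r.rid] = float(chunk.sum())
        side_mask = np.array([n not in BACKBONE_ATOMS for n in r.atom_names])
        side[r.rid] = float(chunk[side_mask].sum()) if side_mask.any() else 0.0
    return ResidueAreas(full=full, side_chain=side)


def select_surface_residues(
    areas: ResidueAreas, cutoff: float = SURFACE_AREA_CUTOFF
) -> set[ResidueId]:
    """Residues with full-residue exposed area strictly greater than ``cutoff``."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return {rid for rid, a in areas.full.items() if a > cutoff}


@dataclass
class ContactSet:
    """Residue pairs whose minimum heavy-atom distance is within a criterion.

    Pairs are stored once under a canonical order: for inter-protein sets the
    first element always belongs to partner A; for intra-protein sets the
    lexicographically smaller residue id comes first.
    """

    pairs: set[tuple[ResidueId, ResidueId]]
    max_dist: float
    intra: bool

    def __contains__(self, pair: tuple[ResidueId, ResidueId]) -> bool:
        if self.intra:
            a, b = pair
            return (min(a, b), max(a, b)) in self.pairs
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def partners_of(self, rid: ResidueId) -> set[ResidueId]:
        out = set()
        for a, b in self.pairs:
            if a == rid:
                out.add(b)
            elif b == rid:
                out.add(a)
        return out


def find_contacts(
    struct_a: Structure,
    struct_b: Structure,
    max_dist: float = CONTACT_DISTANCE,
) -> ContactSet:
    """Residue pairs with minimum heavy-atom center distance <= ``max_dist``.

    Pass the same structure twice for intra-protein contacts (self pairs are
    excluded and each pair stored once).
    """
    if len(struct_a) == 0 or len(struct_b) == 0:
        raise StructureError("cannot compute contacts on an empty structure")
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    intra = struct_a is struct_b
    ca, cb = struct_a.all_coords(), struct_b.all_coords()
    ia, ib = struct_a.atom_residue_index(), struct_b.atom_residue_index()
    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    pairs_atoms = tree_a.query_ball_tree(tree_b, r=max_dist)
    rids_a, rids_b = struct_a.residue_ids(), struct_b.residue_ids()
    found: set[tuple[ResidueId, ResidueId]] = set()
    for atom_i, neighbors in enumerate(pairs_atoms):
        ra = rids_a[ia[atom_i]]
        for atom_j in neighbors:
            rb = rids_b[ib[atom_j]]
            if intra:
                if ra == rb:
                    continue
                found.add((min(ra, rb), max(ra, rb)))
            else:
                found.add((ra, rb))
    return ContactSet(pairs=found, max_dist=max_dist, intra=intra)


@dataclass
class NeighborhoodMap:
    """Closed surface neighborhoods: residue plus contacting candidates."""

    members: dict[ResidueId, frozenset[ResidueId]]

    def __getitem__(self, rid: ResidueId) -> frozenset[ResidueId]:
        return self.members[rid]


def build_neighborhoods(
    candidates: set[ResidueId], intra_contacts: ContactSet
) -> NeighborhoodMap:
    """Neighborhood of each candidate: itself plus candidate residues in contact.

    ``intra_contacts`` must be an intra-protein contact set of the same
    structure computed at the heavy-atom contact criterion.
    """
    if not intra_contacts.intra:
        raise ValueError("build_neighborhoods requires an intra-protein ContactSet")
    adjacency: dict[ResidueId, set[ResidueId]] = {c: {c} for c in candidates}
    for a, b in intra_contacts.pairs:
        if a in adjacency and b in adjacency:
            adjacency[a].add(b)
            adjacency[b].add(a)
    return NeighborhoodMap(
        members={rid: frozenset(m) for rid, m in adjacency.items()}
    )


@dataclass
class CutoffStats:
    """Per-complex candidate-filter statistics over a grid of area cutoffs.

    ``potential``: cutoff -> number of candidate pairs (|surface A| x |surface B|).
    ``surviving``: cutoff -> number of true contacts with both residues on the
    candidate surface.  ``true_total``: true contacts before any filtering.
    """

    potential: dict[float, int]
    surviving: dict[float, int]
    true_total: int


def cutoff_stats_for_complex(
    struct_a: Structure,
    struct_b: Structure,
    areas_a: ResidueAreas,
    areas_b: ResidueAreas,
    cutoff_grid: list[float],
    contact_dist: float = CONTACT_DISTANCE,
) -> CutoffStats:
    """Evaluate candidate-pair counts and true-contact survival per cutoff."""
    contacts = find_contacts(struct_a, struct_b, contact_dist)
    potential: dict[float, int] = {}
    surviving: dict[float, int] = {}
    for cutoff in cutoff_grid:
        cand_a = select_surface_residues(areas_a, cutoff)
        cand_b = select_surface_residues(areas_b, cutoff)
        potential[cutoff] = len(cand_a) * len(cand_b)
        surviving[cutoff] = sum(
            1 for a, b in contacts.pairs if a in cand_a and b in cand_b
        )
    return CutoffStats(potential, surviving, len(contacts))


def select_area_cutoff(
    training_complexes: list[CutoffStats],
    cutoff_grid: list[float] | None = None,
) -> float:
    """Pick the surface-area cutoff minimizing the candidate/true-contact trade-off.

    For each cutoff the objective is the product of two measures over the
    training complexes:

    * the ratio of the mean number of potential (candidate) contact pairs to
      the minimum number of surviving true contacts in any complex, and
    * the fraction of true contacts lost in the complex that retains the
      fewest true contacts at that cutoff.

    A cutoff at which some complex retains zero true contacts scores +inf.
    Ties break toward the smaller cutoff (keeping more true contacts).
    """
    if not training_complexes:
        raise ValueError("no training complexes given")
    if cutoff_grid is None:
        cutoff_grid = sorted(training_complexes[0].potential.keys())
    best_cutoff, best_score = None, math.inf
    for cutoff in sorted(cutoff_grid):
        survivors = [c.surviving[cutoff] for c in training_complexes]
        min_surv = min(survivors)
        if min_surv == 0:
            score = math.inf
        else:
            mean_potential = float(
                np.mean([c.potential[cutoff] for c in training_complexes])
            )
            ratio = mean_potential / min_surv
            j = int(np.argmin(survivors))
            frac_lost = 1.0 - survivors[j] / training_complexes[j].true_total
            score = ratio * frac_lost
        if score < best_score:
            best_cutoff, best_score = cutoff, score
    if best_cutoff is None or math.isinf(best_score):
        # every cutoff loses all true contacts somewhere; fall back to smallest
        best_cutoff = min(cutoff_grid)
    return float(best_cutoff)
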