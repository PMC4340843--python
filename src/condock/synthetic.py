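"""Seeded generators for toy complexes, paired alignments and feature tables.

Every downstream stage (surface filtering, descriptor computation, the
classifier, feature selection, docking and evaluation) is testable offline
against these generators.  Toy "residues" are small blobs of pseudo-atoms
(single carbon vdW radius) arranged on two jittered lattices facing each
other across an interface plane, with a designated number of residue pairs
pulled within the 5 A heavy-atom contact criterion.  Synthetic alignments
plant conservation, coevolution and gap structure with tunable strengths.

None of this attempts to mimic real protein geometry, fold topology or
phylogeny; the generators emulate only the statistical structure the
pipeline exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import (
    CONTACT_DISTANCE,
    ONE_TO_THREE,
    ContactSet,
    Residue,
    ResidueId,
    Structure,
    find_contacts,
)
from .msa import Alignment, PairedAlignment, pair_rows_by_organism

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ToyComplexSpec:
    """Geometry of a generated two-partner toy complex."""

    n_residues_a: int = 30
    n_residues_b: int = 24
    atoms_per_residue: tuple[int, int] = (3, 4)
    n_contacts: int = 6
    interface_gap: float = 5.2  # A between non-contact facing residue centers
    contact_gap: float = 4.2    # A between designated contact residue centers
    lattice_spacing: float = 4.5
    jitter: float = 0.4
    roughness: float = 1.2      # sigma of the joint interface corrugation
    seed: int = 0


def _blob(center: np.ndarray, n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-atoms within ~1 A of the residue center; first atom at center."""
    coords = [center]
    for _ in range(n_atoms - 1):
        offset = rng.normal(size=3)
        offset *= rng.uniform(0.4, 1.0) / np.linalg.norm(offset)
        coords.append(center + offset)
    return np.array(coords)


def _lattice_positions(n: int, spacing: float) -> np.ndarray:
    """First ``n`` sites of a compact cubic lattice, ordered layer by layer."""
    side = int(np.ceil(n ** (1 / 3)))
    sites = [
        (x, y, z)
        for x in range(side + 1)
        for y in range(side)
        for z in range(side)
    ]
    return np.array(sites[:n], dtype=float) * spacing


def _build_partner(
    chain: str,
    centers: np.ndarray,
    spec: ToyComplexSpec,
    rng: np.random.Generator,
) -> Structure:
    lo, hi = spec.atoms_per_residue
    residues = []
    for i, center in enumerate(centers):
        n_atoms = int(rng.integers(lo, hi + 1))
        coords = _blob(center, n_atoms, rng)
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        names = ["CA"] + [f"C{j}" for j in range(1, n_atoms)]
        residues.append(
            Residue(
                chain=chain,
                number=i + 1,
                icode="",
                name=ONE_TO_THREE[aa],
                atom_names=names,
                elements=["C"] * n_atoms,
                coords=coords,
            )
        )
    return Structure(f"toy_{chain}", residues)


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[Structure, Structure, ContactSet]:
    """Generate a deterministic two-partner toy complex with planted contacts.

    Partner A occupies x < 0, partner B x > 0; the residues nearest the
    interface plane form facing pairs, of which ``spec.n_contacts`` are
    pulled to within the contact criterion.  The returned contact set is the
    ground truth recomputed with :func:`find_contacts` at 5 A, so it may
    exceed the designated count but never falls below it.
    """
    rng = np.random.default_rng(spec.seed)
    max_pairs = spec.n_residues_a * spec.n_residues_b
    if spec.n_contacts > max_pairs:
        raise ValueError(
            f"cannot plant {spec.n_contacts} contacts among {max_pairs} pairs"
        )

    pos_a = _lattice_positions(spec.n_residues_a, spec.lattice_spacing)
    pos_b = _lattice_positions(spec.n_residues_b, spec.lattice_spacing)
    # mirror A to negative x so layer x=0 faces B's layer x=0
    pos_a[:, 0] = -pos_a[:, 0] - spec.interface_gap / 2
    pos_b[:, 0] = pos_b[:, 0] + spec.interface_gap / 2
    pos_a += rng.normal(scale=spec.jitter, size=pos_a.shape)
    pos_b += rng.normal(scale=spec.jitter, size=pos_b.shape)

    # facing pairs: residues of each partner on the interface layer (x = 0
    # lattice plane), matched by identical (y, z) lattice coordinates
    base_a = _lattice_positions(spec.n_residues_a, spec.lattice_spacing)
    base_b = _lattice_positions(spec.n_residues_b, spec.lattice_spacing)
    sites_a = {
        (round(p[1]), round(p[2])): i
        for i, p in enumerate(base_a) if np.isclose(p[0], 0)
    }
    sites_b = {
        (round(p[1]), round(p[2])): i
        for i, p in enumerate(base_b) if np.isclose(p[0], 0)
    }
    common = sorted(set(sites_a) & set(sites_b))
    face_a = [sites_a[yz] for yz in common]
    face_b = [sites_b[yz] for yz in common]
    n_facing = len(common)
    if spec.n_contacts > n_facing:
        raise ValueError(
            f"spec plants {spec.n_contacts} contacts but only {n_facing} "
            "facing residue pairs exist; increase residue counts"
        )
    # corrugate the interface with a smooth random height field: each facing
    # pair shifts by the same x offset on both sides, creating interlocking
    # bumps and dents (shape complementarity) that pin the bound pose
    # laterally, while smoothness avoids clashes between neighboring sites
    wavelength = 2.0 * spec.lattice_spacing
    theta = rng.uniform(0, 2 * np.pi)
    phases = rng.uniform(0, 2 * np.pi, size=2)

    def height(yz: np.ndarray) -> float:
        u = yz[0] * np.cos(theta) + yz[1] * np.sin(theta)
        v = -yz[0] * np.sin(theta) + yz[1] * np.cos(theta)
        return spec.roughness * (
            np.sin(2 * np.pi * u / wavelength + phases[0])
            + np.sin(2 * np.pi * v / wavelength + phases[1])
        ) / np.sqrt(2)

    for k in range(n_facing):
        ia, ib = face_a[k], face_b[k]
        mid_yz = (pos_a[ia, 1:] + pos_b[ib, 1:]) / 2
        bump_x = height(mid_yz)
        pos_a[ia, 0] = -spec.interface_gap / 2 + bump_x
        pos_b[ib, 0] = spec.interface_gap / 2 + bump_x
        pos_a[ia, 1:] = mid_yz + rng.normal(scale=0.2, size=2)
        pos_b[ib, 1:] = mid_yz + rng.normal(scale=0.2, size=2)
    chosen = rng.choice(n_facing, size=spec.n_contacts, replace=False)
    for k in chosen:
        ia, ib = face_a[k], face_b[k]
        # pull the designated pair to contact distance, keeping its bump
        bump_x = (pos_b[ib, 0] + pos_a[ia, 0]) / 2
        pos_a[ia, 0] = bump_x - spec.contact_gap / 2
        pos_b[ib, 0] = bump_x + spec.contact_gap / 2

    struct_a = _build_partner("A", pos_a, spec, rng)
    struct_b = _build_partner("B", pos_b, spec, rng)
    contacts = find_contacts(struct_a, struct_b, CONTACT_DISTANCE)

    if len(contacts) < spec.n_contacts:
        raise RuntimeError(
            "generator failed to realize the designated contacts; "
            "loosen the spec (smaller contact_gap or jitter)"
        )
    min_dist = _min_interatomic_distance(struct_a, struct_b)
    if min_dist < 2.0:
        raise RuntimeError(
            f"partners interpenetrate (closest atoms {min_dist:.2f} A); "
            "reduce jitter or increase gaps"
        )
    return struct_a, struct_b, contacts


def _min_interatomic_distance(sa: Structure, sb: Structure) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(sb.all_coords()).query(sa.all_coords(), k=1)
    return float(np.min(d))


@dataclass
class SyntheticMSASpec:
    """Statistical structure of a generated pair of matched alignments."""

    n_organisms: int = 50
    substitution_rate: float = 0.3
    coevolution_strength: float = 0.0
    gap_rate: float = 0.02
    seed: int = 0
    organism_format: str = "os"  # "os" -> 'OS=...' headers, "bracket" -> '[...]'


def _mutate_columns(
    seq: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return out


def make_synthetic_alignments(
    struct_a: Structure,
    struct_b: Structure,
    contacts: ContactSet,
    spec: SyntheticMSASpec,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> PairedAlignment:
    """Paired alignments with planted coevolution at contact column pairs.

    Row 0 of each alignment is the ungapped query, equal to the structure's
    chain sequence.  Every other organism receives both chains mutated
    jointly: designated contact column pairs are co-substituted with
    probability ``coevolution_strength`` (both columns set via a fixed
    amino-acid coupling, creating mutual information), all other columns
    mutate independently at ``substitution_rate``; gaps are inserted at
    ``gap_rate`` per cell in non-query rows.
    """
    rng = np.random.default_rng(spec.seed)
    chain_a = chain_a or struct_a.chains[0]
    chain_b = chain_b or struct_b.chains[0]
    seq_a = list(struct_a.sequence1(chain_a))
    seq_b = list(struct_b.sequence1(chain_b))
    index_a = {r.rid: i for i, r in enumerate(struct_a.residues) if r.chain == chain_a}
    index_b = {r.rid: i for i, r in enumerate(struct_b.residues) if r.chain == chain_b}
    contact_cols = [
        (index_a[a], index_b[b])
        for a, b in sorted(contacts.pairs)
        if a in index_a and b in index_b
    ]
    # fixed random bijection coupling the co-substituted amino acids
    perm = rng.permutation(len(AMINO_ACIDS))
    couple = {AMINO_ACIDS[i]: AMINO_ACIDS[perm[i]] for i in range(len(AMINO_ACIDS))}

    def header(tag: str, organism: str) -> str:
        if spec.organism_format == "bracket":
            return f"{tag} [{organism}]"
        return f"{tag} OS={organism} OX=0"

    rows_a = [(header("queryA", "query organism"), "query organism", "".join(seq_a))]
    rows_b = [(header("queryB", "query organism"), "query organism", "".join(seq_b))]
    for org_idx in range(1, spec.n_organisms):
        organism = f"organism {org_idx:03d}"
        sa = _mutate_columns(seq_a, spec.substitution_rate, rng)
        sb = _mutate_columns(seq_b, spec.substitution_rate, rng)
        for ca, cb in contact_cols:
            if rng.random() < spec.coevolution_strength:
                aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                sa[ca] = aa
                sb[cb] = couple[aa]
        for s in (sa, sb):
            gap_mask = rng.random(len(s)) < spec.gap_rate
            for i in np.where(gap_mask)[0]:
                s[i] = "-"
        rows_a.append((header(f"homA{org_idx}", organism), organism, "".join(sa)))
        rows_b.append((header(f"homB{org_idx}", organism), organism, "".join(sb)))

    aln_a = Alignment(rows=rows_a, query_index=0)
    aln_b = Alignment(rows=rows_b, query_index=0)
    return pair_rows_by_organism(aln_a, aln_b)


def make_feature_table(
    n_pairs: int,
    n_features: int,
    informative: set[int] | list[int],
    mean_shift: float,
    prevalence: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian feature table with class-mean shift on informative features.

    Negatives are standard normal per feature; positives are shifted by
    ``mean_shift`` (in sigma units) on the ``informative`` feature indices
    only.  The number of positives is ``round(prevalence * n_pairs)``.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = int(round(prevalence * n_pairs))
    labels = np.zeros(n_pairs, dtype=int)
    labels[:n_pos] = 1
    features = rng.normal(size=(n_pairs, n_features))
    informative = sorted(informative)
    features[:n_pos, informative] += mean_shift
    order = rng.permutation(n_pairs)
    return features[order], labels[order]


def make_complex_feature_tables(
    n_complexes: int,
    pairs_per_complex: int,
    n_features: int,
    informative: set[int] | list[int],
    mean_shift: float,
    prevalence: float,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray, list]]:
    """Per-complex labeled feature tables for the cross-validation harness.

    Returns ``{complex_id: (features, labels, pair_ids)}`` with synthetic
    pair identifiers suitable for deterministic tie-breaking.
    """
    rng = np.random.default_rng(seed)
    tables = {}
    for c in range(n_complexes):
        sub_seed = int(rng.integers(2**31 - 1))
        features, labels = make_feature_table(
            pairs_per_complex, n_features, informative, mean_shift,
            prevalence, seed=sub_seed,
        )
        pair_ids = [
            (("A", i + 1, ""), ("B", i + 1, "")) for i in range(pairs_per_complex)
        ]
        tables[f"complex{c:03d}"] = (features, labels, pair_ids)
    return tables


def make_ragged_alignment_text() -> str:
    """Aligned-FASTA text with rows of unequal length (corrupt fixture)."""
    return ">row1 OS=org one OX=1\nACDEFGHIKL\n>row2 OS=org two OX=2\nACDEFGHIK\n"


def make_all_gap_column_alignment(n_rows: int = 5, n_cols: int = 8) -> str:
    """Aligned FASTA whose third column is gapped in all non-query rows."""
    lines = [">query OS=query organism OX=0", "A" * n_cols]
    for i in range(1, n_rows):
        row = list("A" * n_cols)
        row[2] = "-"
        lines.append(f">hom{i} OS=organism {i} OX={i}")
        lines.append("".join(row))
    return "\n".join(lines) + "\n"
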