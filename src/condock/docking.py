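"""Grid-based rigid-body docking pruned by residue-contact constraints.

The geometric search digitizes each partner onto a cubic lattice: *core*
cells fall within the van der Waals envelope of the heavy atoms, *surface*
cells within an additional margin.  A rigid placement of the ligand partner
is a sampled rotation followed by a lattice translation; its score is the
number of overlapping surface-surface cell pairs, and placements whose
core-core overlap exceeds a tolerance are discarded (hard-core by default,
a soft-core budget is available for unbound-style runs).

A predicted residue contact becomes a distance constraint that prunes the
translational search before scoring: translations incompatible with the
constrained residues ever coming within the allowed distance are excluded
by a sound centroid-plus-radii bound, and surviving candidate placements
are verified by the exact minimum heavy-atom distance.  Screening many
predicted contacts then samples a fixed quota of retained models from each
constraint, so that a single high-scoring but wrong epitope cannot crowd
every other hypothesis out of the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import ResidueId, Structure, vdw_radius


@dataclass
class DockGrid:
    """Digitized structure: cubic lattice with core and surface occupancy."""

    resolution: float
    origin: np.ndarray            # (3,) A; cell (i,j,k) center = origin + (ijk+0.5)*res
    core: np.ndarray              # bool (nx, ny, nz)
    surface: np.ndarray           # bool, disjoint from core

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.core.shape

    def cell_centers(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.resolution


def digitize(
    structure: Structure,
    resolution: float = 1.0,
    surface_margin: float = 1.5,
) -> DockGrid:
    """Digitize heavy atoms onto a cubic lattice by cell-center test.

    A cell belongs to the core if its center lies within the vdW radius of
    any atom, and to the surface layer if within radius + margin but not in
    the core.  ``surface_margin=0`` yields an empty surface layer.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if surface_margin < 0:
        raise ValueError("surface_margin must be >= 0")
    coords = structure.all_coords()
    radii = np.array(
        [vdw_radius(e) for r in structure.residues for e in r.elements]
    )
    reach = radii + surface_margin
    lo = (coords - reach[:, None]).min(axis=0) - resolution
    hi = (coords + reach[:, None]).max(axis=0) + resolution
    origin = lo
    shape = np.ceil((hi - lo) / resolution).astype(int) + 1
    core = np.zeros(shape, dtype=bool)
    near = np.zeros(shape, dtype=bool)
    for p, r_core, r_near in zip(coords, radii, reach):
        lo_idx = np.floor((p - r_near - origin) / resolution - 0.5).astype(int)
        hi_idx = np.ceil((p + r_near - origin) / resolution - 0.5).astype(int)
        lo_idx = np.maximum(lo_idx, 0)
        hi_idx = np.minimum(hi_idx, shape - 1)
        axes = [np.arange(lo_idx[d], hi_idx[d] + 1) for d in range(3)]
        centers = [origin[d] + (axes[d] + 0.5) * resolution - p[d] for d in range(3)]
        d2 = (
            centers[0][:, None, None] ** 2
            + centers[1][None, :, None] ** 2
            + centers[2][None, None, :] ** 2
        )
        sub = np.ix_(axes[0], axes[1], axes[2])
        core[sub] |= d2 <= r_core**2
        near[sub] |= d2 <= r_near**2
    return DockGrid(
        resolution=resolution,
        origin=origin.astype(float),
        core=core,
        surface=near & ~core,
    )


@dataclass
class TranslationScan:
    """Scores of every lattice translation of grid B against grid A.

    Index ``m`` of the full correlation arrays corresponds to the integer
    translation ``t = m + offset`` (per axis); placing the ligand means
    mapping its coordinates ``x -> R x + delta`` with
    ``delta = origin_A - origin_B + t * resolution``.
    """

    surface_score: np.ndarray   # int (full correlation shape)
    core_overlap: np.ndarray    # int
    valid: np.ndarray           # bool: core overlap within tolerance
    offset: np.ndarray          # (3,) int: t = index + offset

    def translations(self) -> np.ndarray:
        """Integer translations of all valid cells, as an (n, 3) array."""
        return np.argwhere(self.valid) + self.offset


def _int_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = correlate(a.astype(float), b.astype(float), mode="full", method="auto")
    return np.rint(out).astype(np.int64)


def search_translations(
    grid_a: DockGrid,
    grid_b: DockGrid,
    allowed_region: np.ndarray | None = None,
    core_overlap_tol: int = 0,
) -> TranslationScan:
    """Enumerate and score all lattice translations of B relative to A.

    The surface score of translation t is the number of overlapping
    surface-surface cell pairs; translations with core-core overlap above
    ``core_overlap_tol`` are marked invalid, as are translations outside
    ``allowed_region`` (a boolean mask over the full correlation domain,
    as produced by :func:`translation_region`).
    """
    if grid_a.resolution != grid_b.resolution:
        raise ValueError("grids must share a resolution")
    surface_score = _int_correlate(grid_a.surface, grid_b.surface)
    core_overlap = _int_correlate(grid_a.core, grid_b.core)
    valid = core_overlap <= core_overlap_tol
    if allowed_region is not None:
        if allowed_region.shape != valid.shape:
            raise ValueError("allowed_region shape does not match scan domain")
        valid &= allowed_region
    offset = -(np.array(grid_b.shape) - 1)
    return TranslationScan(surface_score, core_overlap, valid, offset)


def translation_region(
    grid_a: DockGrid,
    grid_b: DockGrid,
    target_delta: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Mask of lattice translations whose displacement lies within a ball.

    Marks every translation t with
    ``| (origin_A - origin_B + t * res) - target_delta | <= radius`` over
    the full correlation domain of the two grids.
    """
    shape = tuple(np.array(grid_a.shape) + np.array(grid_b.shape) - 1)
    offset = -(np.array(grid_b.shape) - 1)
    res = grid_a.resolution
    base = grid_a.origin - grid_b.origin - np.asarray(target_delta, dtype=float)
    ax = [base[d] + (np.arange(shape[d]) + offset[d]) * res for d in range(3)]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    return d2 <= radius**2


@dataclass
class Constraint:
    """Maximum-distance requirement between one residue of each partner."""

    residue_a: ResidueId
    residue_b: ResidueId
    max_dist: float = 8.0  # 5 A contact criterion + 3 A discretization slack
    id: str = ""

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("constraint max_dist must be positive")
        if not self.id:
            a, b = self.residue_a, self.residue_b
            self.id = f"{a[0]}{a[1]}{a[2]}-{b[0]}{b[1]}{b[2]}"


def constraints_from_contacts(
    pairs: list[tuple[ResidueId, ResidueId]],
    max_dist: float = 8.0,
) -> list[Constraint]:
    """Build one constraint per predicted contact pair (ranking order kept)."""
    return [Constraint(a, b, max_dist) for a, b in pairs]


def _residue_ball(structure: Structure, rid: ResidueId) -> tuple[np.ndarray, float]:
    if rid not in structure:
        raise KeyError(f"residue {rid} not found in structure {structure.id!r}")
    coords = structure.residue(rid).coords
    centroid = coords.mean(axis=0)
    rho = float(np.linalg.norm(coords - centroid, axis=1).max())
    return centroid, rho


def prune_with_constraint(
    constraint: Constraint,
    struct_a: Structure,
    struct_b_rotated: Structure,
    grid_a: DockGrid,
    grid_b: DockGrid,
    slack: float = 0.0,
) -> np.ndarray:
    """Sound translational pruning region for one contact constraint.

    Using the centroids and radii of the two constrained residues, every
    translation where *any* heavy-atom pair of the residues could be within
    ``constraint.max_dist`` satisfies
    ``|delta - (centroid_A - centroid_B)| <= max_dist + rho_A + rho_B``, so
    the returned ball (plus ``slack``) is a guaranteed superset of the
    exact feasible set.  For single-atom residues and zero slack it is
    exactly the feasible ball.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    cent_a, rho_a = _residue_ball(struct_a, constraint.residue_a)
    cent_b, rho_b = _residue_ball(struct_b_rotated, constraint.residue_b)
    radius = constraint.max_dist + rho_a + rho_b + slack
    return translation_region(grid_a, grid_b, cent_a - cent_b, radius)


@dataclass
class DockModel:
    """One rigid placement of the ligand partner.

    Ligand coordinates map as ``x -> R x + translation``; ``rotation`` is
    the unit quaternion (x, y, z, w) of R.
    """

    rotation: np.ndarray
    rotation_index: int
    lattice_translation: tuple[int, int, int]
    translation: np.ndarray     # (3,) A
    score: int
    constraint_id: str | None = None

    @property
    def placement_key(self) -> tuple:
        return (self.rotation_index, *self.lattice_translation)

    def apply(self, struct_b: Structure) -> Structure:
        rot = Rotation.from_quat(self.rotation).as_matrix()
        return struct_b.transformed(rot, self.translation)


def euler_grid_rotations(step_deg: float = 24.0) -> list[Rotation]:
    """Deterministic rotation sampling on a uniform ZYZ Euler-angle grid."""
    alphas = np.arange(0.0, 360.0, step_deg)
    betas = np.arange(0.0, 180.0 + 1e-9, step_deg)
    gammas = np.arange(0.0, 360.0, step_deg)
    out = []
    for b in betas:
        for a in alphas if b not in (0.0, 180.0) else [0.0]:
            for g in gammas:
                out.append(Rotation.from_euler("zyz", [a, b, g], degrees=True))
    return out


def random_rotations(n: int, seed: int = 0) -> list[Rotation]:
    rng = np.random.default_rng(seed)
    return [Rotation.random(rng=rng) for _ in range(n)]


@dataclass
class DockingConfig:
    resolution: float = 1.0
    surface_margin: float = 1.5
    core_overlap_tol: int = 0
    prune_slack: float = 0.0
    top_k_unconstrained: int = 500


def _constraint_satisfied(
    res_a: np.ndarray, res_b_rot: np.ndarray, delta: np.ndarray, max_dist: float
) -> bool:
    return bool(cdist(res_a, res_b_rot + delta).min() <= max_dist + 1e-9)


@dataclass
class DockingRun:
    """Models grouped by constraint id (None key = unconstrained)."""

    models: dict[str | None, list[DockModel]] = field(default_factory=dict)
    translations_scored: dict[tuple[str | None, int], int] = field(
        default_factory=dict
    )


def run_constrained_docking(
    struct_a: Structure,
    struct_b: Structure,
    constraints: list[Constraint] | None,
    rotations: list[Rotation] | None = None,
    models_per_constraint: int = 5,
    config: DockingConfig | None = None,
) -> DockingRun:
    """Rigid docking over sampled rotations, pruned per constraint.

    For each constraint, only the translations inside its pruning region
    are considered; surviving candidates are ordered by surface score (ties
    by rotation index, then z, y, x lattice translation), verified by the
    exact minimum heavy-atom distance of the constrained residue pair, and
    the best ``models_per_constraint`` verified placements are kept.  With
    no constraints the top ``config.top_k_unconstrained`` placements
    overall are kept under the same ordering.
    """
    config = config or DockingConfig()
    rotations = rotations if rotations is not None else [Rotation.identity()]
    grid_a = digitize(struct_a, config.resolution, config.surface_margin)

    run = DockingRun()
    keys: list[str | None] = (
        [c.id for c in constraints] if constraints else [None]
    )
    # candidate placements per constraint, accumulated across rotations
    buckets: dict[str | None, list[tuple]] = {k: [] for k in keys}

    for rot_idx, rotation in enumerate(rotations):
        rot_matrix = rotation.as_matrix()
        sb_rot = struct_b.transformed(rot_matrix, np.zeros(3))
        grid_b = digitize(sb_rot, config.resolution, config.surface_margin)
        scan = search_translations(
            grid_a, grid_b, core_overlap_tol=config.core_overlap_tol
        )
        if constraints:
            for c in constraints:
                region = prune_with_constraint(
                    c, struct_a, sb_rot, grid_a, grid_b, config.prune_slack
                )
                mask = scan.valid & region
                run.translations_scored[(c.id, rot_idx)] = int(region.sum())
                _collect(buckets[c.id], mask, scan, rot_idx, grid_a, grid_b)
        else:
            run.translations_scored[(None, rot_idx)] = int(
                np.prod(scan.valid.shape)
            )
            _collect(
                buckets[None], scan.valid, scan, rot_idx, grid_a, grid_b,
                keep=config.top_k_unconstrained,
            )

    quat_by_idx = {i: r.as_quat() for i, r in enumerate(rotations)}
    rot_by_idx = {i: r.as_matrix() for i, r in enumerate(rotations)}
    for c in constraints or []:
        res_a = struct_a.residue(c.residue_a).coords
        res_b = struct_b.residue(c.residue_b).coords
        picked: list[DockModel] = []
        for neg_score, rot_idx, tz, ty, tx, delta in sorted(buckets[c.id]):
            if len(picked) >= models_per_constraint:
                break
            res_b_rot = res_b @ rot_by_idx[rot_idx].T
            if not _constraint_satisfied(res_a, res_b_rot, delta, c.max_dist):
                continue
            picked.append(
                DockModel(
                    rotation=quat_by_idx[rot_idx],
                    rotation_index=rot_idx,
                    lattice_translation=(tx, ty, tz),
                    translation=delta,
                    score=-neg_score,
                    constraint_id=c.id,
                )
            )
        run.models[c.id] = picked
    if not constraints:
        picked = [
            DockModel(
                rotation=quat_by_idx[rot_idx],
                rotation_index=rot_idx,
                lattice_translation=(tx, ty, tz),
                translation=delta,
                score=-neg_score,
                constraint_id=None,
            )
            for neg_score, rot_idx, tz, ty, tx, delta in sorted(buckets[None])[
                : config.top_k_unconstrained
            ]
        ]
        run.models[None] = picked
    return run


def _collect(
    bucket: list,
    mask: np.ndarray,
    scan: TranslationScan,
    rot_idx: int,
    grid_a: DockGrid,
    grid_b: DockGrid,
    keep: int | None = None,
) -> None:
    """Append (-score, rot_idx, tz, ty, tx, delta) for allowed translations.

    Entries are pre-sorted within the rotation; ``keep`` truncates to the
    best placements (exact for the final top-k selection since ordering is
    global once buckets are merged).
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        return
    scores = scan.surface_score[mask]
    ts = idx + scan.offset
    order = np.lexsort((ts[:, 0], ts[:, 1], ts[:, 2], -scores))
    if keep is not None:
        order = order[:keep]
    base = grid_a.origin - grid_b.origin
    res = grid_a.resolution
    for i in order:
        tx, ty, tz = (int(ts[i, 0]), int(ts[i, 1]), int(ts[i, 2]))
        bucket.append(
            (-int(scores[i]), rot_idx, tz, ty, tx, base + ts[i] * res)
        )


def sample_across_constraints(
    models_by_constraint: dict[str, list[DockModel]],
    total: int,
) -> list[DockModel]:
    """Retain an equal per-constraint quota of models summing to ``total``.

    Quotas follow largest-remainder rounding of total/n_constraints (ties
    toward earlier constraints), e.g. 100 constraints and total 500 keeps 5
    models per constraint.  Identical placements arising under different
    constraints are deduplicated, keeping the higher-score provenance.
    """
    n = len(models_by_constraint)
    if n == 0:
        raise ValueError("no constraints to sample from")
    if total < n:
        raise ValueError(f"total {total} < number of constraints {n}")
    base = total // n
    remainder = total - base * n
    # all fractional remainders are equal (same divisor), so largest-
    # remainder rounding devolves to first-come extra units
    quotas = {
        cid: base + (1 if i < remainder else 0)
        for i, cid in enumerate(models_by_constraint)
    }
    seen: dict[tuple, DockModel] = {}
    for cid, models in models_by_constraint.items():
        for m in models[: quotas[cid]]:
            key = m.placement_key
            if key not in seen or m.score > seen[key].score:
                seen[key] = m
    return list(seen.values())
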