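"""Grid digitization, translational scan, constraint pruning and sampling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from condock.docking import (
    Constraint,
    DockingConfig,
    DockModel,
    constraints_from_contacts,
    digitize,
    prune_with_constraint,
    run_constrained_docking,
    sample_across_constraints,
    search_translations,
    translation_region,
)
from condock.structure import Structure
from condock.synthetic import ToyComplexSpec, make_toy_complex
from conftest import blob_structure, single_atom_structure


def brute_force_scan(grid_a, grid_b):
    """Independent enumeration of every lattice translation by shifting."""
    sa = np.array(grid_a.shape)
    sb = np.array(grid_b.shape)
    full = sa + sb - 1
    offset = -(sb - 1)
    surf = np.zeros(full, dtype=int)
    core = np.zeros(full, dtype=int)
    for m in np.ndindex(*full):
        t = np.array(m) + offset
        s_count = c_count = 0
        for u in np.argwhere(grid_b.surface | grid_b.core):
            v = u + t
            if np.all(v >= 0) and np.all(v < sa):
                if grid_b.surface[tuple(u)] and grid_a.surface[tuple(v)]:
                    s_count += 1
                if grid_b.core[tuple(u)] and grid_a.core[tuple(v)]:
                    c_count += 1
        surf[m], core[m] = s_count, c_count
    return surf, core


class TestDigitize:
    def test_single_atom_core_matches_center_test(self):
        s = single_atom_structure("C")  # vdW 1.7
        grid = digitize(s, resolution=1.0, surface_margin=1.5)
        centers = grid.origin + (
            np.indices(grid.shape).reshape(3, -1).T + 0.5
        ) * 1.0
        d = np.linalg.norm(centers, axis=1).reshape(grid.shape)
        assert np.array_equal(grid.core, d <= 1.7)
        assert np.array_equal(grid.surface, (d <= 3.2) & (d > 1.7))

    def test_zero_margin_gives_empty_surface(self):
        s = single_atom_structure("C")
        grid = digitize(s, resolution=1.0, surface_margin=0.0)
        assert grid.surface.sum() == 0
        assert grid.core.sum() > 0

    def test_lattice_translation_equivariance(self):
        s = single_atom_structure("C", coord=(0.3, -0.2, 0.9))
        s2 = s.transformed(np.eye(3), np.array([1.0, 0.0, 0.0]))
        g1 = digitize(s, resolution=1.0, surface_margin=1.0)
        g2 = digitize(s2, resolution=1.0, surface_margin=1.0)
        assert np.array_equal(g1.core, g2.core)
        assert np.allclose(g2.origin - g1.origin, [1.0, 0.0, 0.0])

    def test_core_and_surface_disjoint_and_atoms_covered(self, toy_complex_small):
        sa, _, _ = toy_complex_small
        grid = digitize(sa, resolution=1.5, surface_margin=1.5)
        assert not np.any(grid.core & grid.surface)
        idx = np.floor((sa.all_coords() - grid.origin) / 1.5).astype(int)
        assert np.all(idx >= 0) and np.all(idx < np.array(grid.shape))


class TestSearchTranslations:
    def test_two_atoms_best_translation_is_adjacent_contact(self):
        a = single_atom_structure("C")
        b = single_atom_structure("C")
        ga = digitize(a, 1.0, 1.5)
        gb = digitize(b, 1.0, 1.5)
        scan = search_translations(ga, gb)
        best = np.unravel_index(
            np.argmax(np.where(scan.valid, scan.surface_score, -1)), scan.valid.shape
        )
        t = np.array(best) + scan.offset
        delta = ga.origin - gb.origin + t * 1.0
        dist = np.linalg.norm(delta)
        assert scan.surface_score[best] > 0
        assert scan.core_overlap[best] == 0
        # atoms neither interpenetrating (cores) nor out of surface reach
        assert 3.0 < dist < 6.5

    def test_matches_brute_force_enumeration(self):
        a = blob_structure([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]], chain="A")
        b = blob_structure([[0.0, 0.0, 0.0]], chain="B")
        ga = digitize(a, 1.5, 1.5)
        gb = digitize(b, 1.5, 1.5)
        scan = search_translations(ga, gb, core_overlap_tol=0)
        surf, core = brute_force_scan(ga, gb)
        assert np.array_equal(scan.surface_score, surf)
        assert np.array_equal(scan.core_overlap, core)
        assert np.array_equal(scan.valid, core == 0)

    def test_empty_allowed_region_empties_result(self):
        a = single_atom_structure("C")
        ga = digitize(a, 1.0, 1.0)
        scan = search_translations(ga, ga, allowed_region=np.zeros(
            tuple(np.array(ga.shape) * 2 - 1), dtype=bool))
        assert scan.valid.sum() == 0

    def test_region_restriction_consistency(self):
        a = blob_structure([[0.0, 0.0, 0.0], [3.0, 1.0, 0.0]], chain="A")
        b = blob_structure([[0.0, 0.0, 0.0]], chain="B")
        ga, gb = digitize(a, 1.0, 1.5), digitize(b, 1.0, 1.5)
        region = translation_region(ga, gb, np.zeros(3), radius=4.0)
        unrestricted = search_translations(ga, gb)
        restricted = search_translations(ga, gb, allowed_region=region)
        assert np.array_equal(restricted.valid, unrestricted.valid & region)
        assert np.array_equal(
            restricted.surface_score[restricted.valid],
            unrestricted.surface_score[restricted.valid],
        )


class TestConstraintPruning:
    def test_soundness_against_brute_force_atom_distance(self):
        """Over random toy complexes, every lattice translation at which
        the constrained residues' atoms actually come within max_dist lies
        inside the pruned region."""
        for seed in range(25):
            spec = ToyComplexSpec(
                n_residues_a=8, n_residues_b=6, n_contacts=2, seed=seed
            )
            sa, sb, contacts = make_toy_complex(spec)
            pair = sorted(contacts.pairs)[seed % len(contacts.pairs)]
            c = Constraint(pair[0], pair[1], max_dist=6.0)
            ga, gb = digitize(sa, 1.5, 1.5), digitize(sb, 1.5, 1.5)
            region = prune_with_constraint(c, sa, sb, ga, gb, slack=0.0)
            res_a = sa.residue(c.residue_a).coords
            res_b = sb.residue(c.residue_b).coords
            shape = tuple(np.array(ga.shape) + np.array(gb.shape) - 1)
            offset = -(np.array(gb.shape) - 1)
            base = ga.origin - gb.origin
            for m in np.argwhere(np.ones(shape, dtype=bool)):
                delta = base + (m + offset) * 1.5
                dmin = np.min(
                    np.linalg.norm(
                        res_a[:, None, :] - (res_b[None, :, :] + delta), axis=2
                    )
                )
                if dmin <= c.max_dist:
                    assert region[tuple(m)], (seed, m, dmin)

    def test_single_atom_residues_zero_slack_is_exact_ball(self):
        a = single_atom_structure("C", coord=(1.0, 2.0, 3.0))
        b = single_atom_structure("C", coord=(-2.0, 0.0, 1.0))
        ga, gb = digitize(a, 1.0, 1.0), digitize(b, 1.0, 1.0)
        c = Constraint(("A", 1, ""), ("A", 1, ""), max_dist=5.0)
        region = prune_with_constraint(c, a, b, ga, gb, slack=0.0)
        shape = region.shape
        offset = -(np.array(gb.shape) - 1)
        base = ga.origin - gb.origin
        for m in np.ndindex(*shape):
            delta = base + (np.array(m) + offset) * 1.0
            exact = np.linalg.norm(
                np.array([1.0, 2.0, 3.0]) - (np.array([-2.0, 0.0, 1.0]) + delta)
            ) <= 5.0
            assert region[m] == exact

    def test_region_nests_with_max_dist(self):
        a = single_atom_structure("C")
        ga = digitize(a, 1.0, 1.0)
        sizes = []
        for d in (2.0, 4.0, 6.0, 8.0):
            c = Constraint(("A", 1, ""), ("A", 1, ""), max_dist=d)
            sizes.append(prune_with_constraint(c, a, a, ga, ga).sum())
        assert sizes == sorted(sizes)

    def test_missing_residue_rejected(self):
        a = single_atom_structure("C")
        ga = digitize(a, 1.0, 1.0)
        c = Constraint(("Z", 9, ""), ("A", 1, ""), max_dist=5.0)
        with pytest.raises(KeyError):
            prune_with_constraint(c, a, a, ga, ga)


class TestConstrainedDocking:
    def test_models_satisfy_their_constraints(self, toy_complex_small):
        sa, sb, contacts = toy_complex_small
        pairs = sorted(contacts.pairs)[:3]
        constraints = constraints_from_contacts(pairs, max_dist=8.0)
        run = run_constrained_docking(sa, sb, constraints, models_per_constraint=4)
        assert any(run.models[c.id] for c in constraints)
        for c in constraints:
            res_a = sa.residue(c.residue_a).coords
            res_b = sb.residue(c.residue_b).coords
            for m in run.models[c.id]:
                rot = Rotation.from_quat(m.rotation).as_matrix()
                moved = res_b @ rot.T + m.translation
                dmin = np.min(
                    np.linalg.norm(res_a[:, None, :] - moved[None, :, :], axis=2)
                )
                assert dmin <= c.max_dist + 1e-6

    def test_constrained_scan_never_larger_than_unconstrained(self, toy_complex_small):
        sa, sb, contacts = toy_complex_small
        pair = sorted(contacts.pairs)[0]
        constraints = constraints_from_contacts([pair])
        run_c = run_constrained_docking(sa, sb, constraints, models_per_constraint=2)
        run_u = run_constrained_docking(sa, sb, None)
        for (cid, rot_idx), n in run_c.translations_scored.items():
            assert n <= run_u.translations_scored[(None, rot_idx)]

    def test_planted_pose_recovered_with_true_constraint(self):
        """A true-contact constraint guides the search to within 2 grid
        cells of the true (generated) pose."""
        hits = 0
        for seed in range(5):
            sa, sb, contacts = make_toy_complex(ToyComplexSpec(seed=seed))
            pair = sorted(contacts.pairs)[0]
            constraints = constraints_from_contacts([pair], max_dist=8.0)
            run = run_constrained_docking(
                sa, sb, constraints, models_per_constraint=10
            )
            best = min(
                np.linalg.norm(m.translation)
                for m in run.models[constraints[0].id]
            )
            hits += best <= 2.0
        assert hits >= 4

    def test_unconstrained_mode_returns_top_k(self, toy_complex_small):
        sa, sb, _ = toy_complex_small
        run = run_constrained_docking(
            sa, sb, None, config=DockingConfig(top_k_unconstrained=7)
        )
        models = run.models[None]
        assert len(models) == 7
        scores = [m.score for m in models]
        assert scores == sorted(scores, reverse=True)


def dummy_models(cid, n, score0=100):
    return [
        DockModel(
            rotation=np.array([0, 0, 0, 1.0]),
            rotation_index=0,
            lattice_translation=(int(cid[1:]), i, 0),
            translation=np.zeros(3),
            score=score0 - i,
            constraint_id=cid,
        )
        for i in range(n)
    ]


class TestSampling:
    @pytest.mark.parametrize("total,quota", [(500, 5), (1000, 10)])
    def test_one_percent_per_constraint_with_100_constraints(self, total, quota):
        grouped = {f"c{i}": dummy_models(f"c{i}", 20) for i in range(100)}
        kept = sample_across_constraints(grouped, total)
        assert len(kept) == total
        per = {}
        for m in kept:
            per[m.constraint_id] = per.get(m.constraint_id, 0) + 1
        assert set(per.values()) == {quota}

    def test_largest_remainder_quotas(self):
        grouped = {f"c{i}": dummy_models(f"c{i}", 10) for i in range(3)}
        kept = sample_across_constraints(grouped, 10)
        per = [sum(m.constraint_id == f"c{i}" for m in kept) for i in range(3)]
        assert per == [4, 3, 3]

    def test_total_below_constraint_count_rejected(self):
        grouped = {f"c{i}": dummy_models(f"c{i}", 2) for i in range(5)}
        with pytest.raises(ValueError):
            sample_across_constraints(grouped, 3)

    def test_duplicate_placements_deduplicated_keeping_best(self):
        m1 = dummy_models("c0", 1, score0=50)
        m2 = dummy_models("c1", 1, score0=80)
        # force identical placement keys
        m2[0].lattice_translation = m1[0].lattice_translation
        kept = sample_across_constraints({"c0": m1, "c1": m2}, 2)
        assert len(kept) == 1
        assert kept[0].score == 80
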