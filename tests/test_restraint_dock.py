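"""Tests for flat-bottom restraints, surrogate scoring, docking, and clustering."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from xlms import restraint_dock as rd
from xlms import synthetic_data as sd
from xlms.restraint_dock import DockConfig, Pose, Restraint, Subunit
from xlms.xl_tables import CrossLinkPair


def _line_subunit(sid, n=5, spacing=10.0, offset=(0.0, 0.0, 0.0)):
    coords = np.array([[i * spacing, 0.0, 0.0] for i in range(n)]) + np.asarray(offset)
    return Subunit(sid, np.arange(1, n + 1), coords)


@pytest.fixture(scope="module")
def cc_dimer():
    dimer, truth = sd.gen_coiled_coil_dimer(60, contact=4.5, seed=3)
    rec = Subunit.from_chain(dimer.chains[0], "A")
    mob_true = Subunit.from_chain(dimer.chains[1], "B")
    mob = Subunit.from_chain(dimer.chains[0], "B")  # identical monomer, to be docked
    return dimer, rec, mob, mob_true


class TestRestraintEnergy:
    def test_zero_inside_band(self):
        a = _line_subunit("A")
        b = _line_subunit("B", offset=(0, 20.0, 0))
        r = Restraint(("A", 1), ("B", 1))  # d = 20, band [10, 30]
        assert rd.restraint_energy({"A": a.coords, "B": b.coords}, [r], {"A": a, "B": b}) == 0.0

    def test_quadratic_overshoot(self):
        a = _line_subunit("A")
        b = _line_subunit("B", offset=(0, 31.0, 0))
        r = Restraint(("A", 1), ("B", 1), lower=10, upper=30)
        e = rd.restraint_energy({"A": a.coords, "B": b.coords}, [r], {"A": a, "B": b})
        assert e == pytest.approx(1.0)

    def test_matches_per_term_sum(self):
        rng = np.random.default_rng(3)
        a = Subunit("A", np.arange(1, 11), rng.uniform(0, 30, (10, 3)))
        b = Subunit("B", np.arange(1, 11), rng.uniform(0, 30, (10, 3)))
        restraints = [
            Restraint(("A", int(rng.integers(1, 11))), ("B", int(rng.integers(1, 11))),
                      lower=float(rng.uniform(0, 10)), upper=float(rng.uniform(15, 30)))
            for _ in range(10)
        ]
        total = rd.restraint_energy({"A": a.coords, "B": b.coords}, restraints, {"A": a, "B": b})
        by_hand = 0.0
        for r in restraints:
            d = np.linalg.norm(a.coords[r.site_u[1] - 1] - b.coords[r.site_v[1] - 1])
            if d < r.lower:
                by_hand += (r.lower - d) ** 2
            elif d > r.upper:
                by_hand += (d - r.upper) ** 2
        assert total == pytest.approx(by_hand)

    def test_unresolvable_site_named(self):
        a, b = _line_subunit("A"), _line_subunit("B")
        r = Restraint(("A", 99), ("B", 1))
        with pytest.raises(ValueError, match="99"):
            rd.restraint_energy({"A": a.coords, "B": b.coords}, [r], {"A": a, "B": b})

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Restraint(("A", 1), ("B", 1), lower=30, upper=10)


class TestScorePose:
    def test_distant_subunits_score_restraint_only(self):
        a = _line_subunit("A")
        b = _line_subunit("B", offset=(0, 100.0, 0))
        r = Restraint(("A", 1), ("B", 1))
        scored = rd.score_pose(a, b, [r])
        assert scored.n_clash == 0 and scored.n_contact == 0
        assert scored.total == pytest.approx(scored.e_restraint)
        assert scored.e_restraint > 0

    def test_superposed_subunits_clash_per_residue(self):
        a = _line_subunit("A", n=6)
        b = _line_subunit("B", n=6)
        scored = rd.score_pose(a, b, [])
        assert scored.n_clash == 6  # each site atom clashes with its own copy

    def test_counts_match_pair_scan(self):
        rng = np.random.default_rng(11)
        a = Subunit("A", np.arange(1, 31), rng.uniform(0, 25, (30, 3)))
        b = Subunit("B", np.arange(1, 31), rng.uniform(0, 25, (30, 3)))
        cfg = DockConfig()
        scored = rd.score_pose(a, b, [], cfg)
        d = cdist(a.coords, b.coords)
        assert scored.n_clash == int((d < cfg.clash_cutoff).sum())
        assert scored.n_contact == int(((d >= cfg.clash_cutoff) & (d <= cfg.contact_cutoff)).sum())
        expected = cfg.w_restraint * scored.e_restraint + cfg.w_clash * scored.n_clash - cfg.w_contact * scored.n_contact
        assert scored.total == pytest.approx(expected)

    def test_global_rigid_transform_invariance(self, cc_dimer):
        _, rec, mob, mob_true = cc_dimer
        restraints = [Restraint(("A", 5), ("B", 10)), Restraint(("A", 40), ("B", 45))]
        s0 = rd.score_pose(rec, mob_true, restraints)
        R = Rotation.from_rotvec([1.0, -0.4, 0.7]).as_matrix()
        t = np.array([30.0, -5.0, 12.0])
        rec2 = Subunit("A", rec.resnums, rec.coords @ R.T + t)
        mob2 = Subunit("B", mob_true.resnums, mob_true.coords @ R.T + t)
        s1 = rd.score_pose(rec2, mob2, restraints)
        assert s1.total == pytest.approx(s0.total, abs=1e-6)
        assert s1.e_restraint == pytest.approx(s0.e_restraint, abs=1e-6)


class TestSampleAndMinimize:
    def test_no_cross_restraint_rejected(self, cc_dimer):
        _, rec, mob, _ = cc_dimer
        with pytest.raises(ValueError, match="spans"):
            rd.sample_and_minimize(rec, mob, [Restraint(("A", 1), ("A", 5))], DockConfig(n_init=1, n_refine=1))

    def test_seeded_determinism(self, cc_dimer):
        dimer, rec, mob, _ = cc_dimer
        restraints = sd.restraints_from_assembly(dimer, 4, seed=2, subunit_ids=("A", "B"))
        cfg = DockConfig(n_init=3, n_refine=3, seed=17)
        out1 = rd.sample_and_minimize(rec, mob, restraints, cfg)
        out2 = rd.sample_and_minimize(rec, mob, restraints, cfg)
        for s1, s2 in zip(out1, out2):
            assert s1.poses["B"].quaternion == s2.poses["B"].quaternion
            assert s1.poses["B"].translation == s2.poses["B"].translation
            assert s1.total == s2.total

    def test_returns_sorted_and_satisfies_restraints(self, cc_dimer):
        dimer, rec, mob, _ = cc_dimer
        restraints = sd.restraints_from_assembly(
            dimer, 8, seed=5, subunit_ids=("A", "B"), spread=True
        )
        cfg = DockConfig(n_init=40, n_refine=10, seed=3)
        scored = rd.sample_and_minimize(rec, mob, restraints, cfg)
        assert len(scored) == 10
        totals = [s.total for s in scored]
        assert totals == sorted(totals)
        # restraint-guided search finds a fully satisfying pose
        assert min(s.e_restraint for s in scored) == pytest.approx(0.0, abs=1e-6)

    def test_minimization_never_worse_than_start(self, cc_dimer):
        """The descent guard keeps each pose at least as good (in the minimized
        energy) as its random start; with pathological max_evals=1 the sampler
        must still return valid poses."""
        dimer, rec, mob, _ = cc_dimer
        restraints = sd.restraints_from_assembly(dimer, 4, seed=2, subunit_ids=("A", "B"))
        cfg = DockConfig(n_init=5, n_refine=5, seed=3, max_evals=1)
        scored = rd.sample_and_minimize(rec, mob, restraints, cfg)
        assert len(scored) == 5


class TestClusterPoses:
    def _pose(self, sid, t):
        return Pose(sid, (0.0, 0.0, 0.0, 1.0), tuple(t))

    def _scored(self, t, total):
        return rd.ScoredPose({"B": self._pose("B", t)}, 0.0, 0, 0, total)

    def test_two_separate_clusters(self):
        mob = _line_subunit("B")
        scored = [
            self._scored((0, 0, 0), -1.0),
            self._scored((0.1, 0, 0), -2.0),
            self._scored((40, 0, 0), -5.0),
        ]
        clusters, top = rd.cluster_poses(scored, mob, DockConfig(cluster_rmsd=5))
        assert len(clusters) == 2
        assert clusters[0].representative.total == -5.0  # ordered by representative total

    def test_identical_poses_single_cluster(self):
        mob = _line_subunit("B")
        scored = [self._scored((0, 0, 0), t) for t in (3.0, -1.0, 2.0)]
        clusters, _ = rd.cluster_poses(scored, mob, DockConfig())
        assert len(clusters) == 1
        assert clusters[0].representative.total == -1.0
        assert clusters[0].size == 3

    def test_matches_single_linkage_components(self):
        rng = np.random.default_rng(7)
        mob = _line_subunit("B", n=8)
        scored = [self._scored(rng.uniform(0, 30, 3), float(rng.normal())) for _ in range(20)]
        cfg = DockConfig(cluster_rmsd=5)
        clusters, _ = rd.cluster_poses(scored, mob, cfg)
        # brute-force single linkage at 5 A: union-find over all pairs
        coords = [s.poses["B"].apply(mob.coords) for s in scored]
        parent = list(range(20))
        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i
        for i in range(20):
            for j in range(i + 1, 20):
                rmsd = np.sqrt(((coords[i] - coords[j]) ** 2).sum(1).mean())
                if rmsd <= 5:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(20)})
        assert len(clusters) == n_components
        assert sum(c.size for c in clusters) == 20

    def test_ligand_rmsd_identity_and_shift(self):
        mob = _line_subunit("B")
        p0 = self._pose("B", (0, 0, 0))
        p1 = self._pose("B", (3, 4, 0))
        assert rd.ligand_rmsd(p0, p0, mob.coords) == 0.0
        assert rd.ligand_rmsd(p0, p1, mob.coords) == pytest.approx(5.0)


class TestAssembleSymmetric:
    def test_incompatible_symmetry_rejected(self):
        mono = _line_subunit("A")
        with pytest.raises(ValueError):
            rd.assemble_symmetric(mono, [Restraint(("A", 1), ("A", 2))], 2, "D2")
        with pytest.raises(ValueError):
            rd.assemble_symmetric(mono, [Restraint(("A", 1), ("A", 2))], 3, "C2")
        with pytest.raises(ValueError):
            rd.assemble_symmetric(mono, [], 2, "C2")

    def test_c2_search_satisfies_planted_restraints(self, helix_monomer):
        model, _ = helix_monomer
        dimer, _ = sd.gen_assembly(model, 2, "C2", contact=6.0, seed=4)
        restraints = [
            rd.Restraint(("A", r.site_u[1]), ("A", r.site_v[1]), r.lower, r.upper)
            for r in sd.restraints_from_assembly(dimer, 6, seed=2, max_distance=25.0)
        ]
        mono = Subunit.from_chain(dimer.chains[0], "A")
        cfg = DockConfig(n_init=40, n_refine=10, seed=1)
        out = rd.assemble_symmetric(mono, restraints, 2, "C2", cfg)
        assert out[0].e_restraint == pytest.approx(0.0, abs=1e-6)
        # exact C2: both copies related by a 2-fold rotation
        qa = np.array(out[0].poses["A"].quaternion)
        assert np.allclose(qa, [0, 0, 0, 1])

    def test_sequential_dimer_satisfies_restraints(self, helix_monomer):
        model, _ = helix_monomer
        dimer, _ = sd.gen_assembly(model, 2, "C2", contact=6.0, seed=4)
        restraints = [
            rd.Restraint(("A", r.site_u[1]), ("A", r.site_v[1]), r.lower, r.upper)
            for r in sd.restraints_from_assembly(dimer, 6, seed=2, max_distance=25.0)
        ]
        mono = Subunit.from_chain(dimer.chains[0], "A")
        cfg = DockConfig(n_init=30, n_refine=5, seed=1)
        out = rd.assemble_symmetric(mono, restraints, 2, "none", cfg)
        assert len(out) == 1
        # the ranking score trades small restraint violations for contacts;
        # the selected assembly must still satisfy the restraints to well
        # under 1 A mean violation
        assert out[0].e_restraint / len(restraints) < 0.5


class TestEvaluateAssembly:
    def test_planted_assembly_fully_satisfied(self, helix_monomer):
        model, _ = helix_monomer
        assembly, truth = sd.gen_assembly(model, 2, "C2", contact=6.0, seed=9)
        restraints = sd.restraints_from_assembly(assembly, 10, seed=1, max_distance=25.0)
        pairs = [
            CrossLinkPair.from_sites(("SYNP1", r.site_u[1]), ("SYNP1", r.site_v[1]))
            for r in restraints
        ]
        mapped = rd.evaluate_assembly(assembly, pairs)
        assert all(m.status == "satisfied" for m in mapped)

    def test_monomer_misses_interchain_links(self, helix_monomer):
        model, _ = helix_monomer
        assembly, _ = sd.gen_assembly(model, 2, "C2", contact=6.0, seed=9)
        # self-links demand two chains: unmapped on a monomer-only model
        pairs = [CrossLinkPair.from_sites(("SYNP1", 10), ("SYNP1", 10))]
        mapped = rd.evaluate_assembly(
            rd.assembly_to_structure(model.chains[0], {"A": Pose.identity("A")}, "SYNP1"), pairs
        )
        assert mapped[0].status == "unmapped"

    def test_link_beyond_dmax_violated(self):
        chain = sd.gen_structure(12, "hairpin", seed=1)[0].chains[0]
        coords = np.array([[0, 0, 0], [36.0, 0, 0]])
        sub = Subunit("A", np.array([1, 2]), coords)
        from xlms.structure_map import ChainModel, Residue, StructureModel

        model = StructureModel(
            [ChainModel("A", "P1", [Residue(1, "LYS", {"CB": coords[0]}), Residue(2, "LYS", {"CB": coords[1]})])]
        )
        mapped = rd.evaluate_assembly(model, [CrossLinkPair.from_sites(("P1", 1), ("P1", 2))])
        assert mapped[0].status == "violated"


def test_restraints_tsv_round_trip(tmp_path, cc_dimer):
    dimer, *_ = cc_dimer
    restraints = sd.restraints_from_assembly(dimer, 6, seed=8, subunit_ids=("A", "B"))
    path = tmp_path / "r.tsv"
    rd.write_restraints_tsv(restraints, path)
    back = rd.read_restraints_tsv(path)
    assert [(r.site_u, r.site_v) for r in back] == [(r.site_u, r.site_v) for r in restraints]
    assert all(
        b.lower == pytest.approx(r.lower) and b.upper == pytest.approx(r.upper)
        for b, r in zip(back, restraints)
    )


def test_pose_quaternion_normalized():
    with pytest.raises(ValueError):
        Pose("A", (1.0, 1.0, 0.0, 0.0), (0, 0, 0))
    p = Pose.from_matrix("A", np.eye(3), np.zeros(3))
    assert np.allclose(p.apply(np.eye(3)), np.eye(3))
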