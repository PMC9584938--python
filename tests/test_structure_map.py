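"""Tests for structure loading, numbering alignment, and distance mapping."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xlms import structure_map as sm
from xlms import synthetic_data as sd
from xlms.structure_map import ChainModel, EvalConfig, Residue, StructureModel
from xlms.xl_tables import CrossLinkPair


def _chain(chain_id, coords, accession="P1", start=1, name="LYS"):
    residues = [
        Residue(start + i, name, {"CB": np.asarray(xyz, dtype=float), "CA": np.asarray(xyz, dtype=float) + 0.5})
        for i, xyz in enumerate(coords)
    ]
    return ChainModel(chain_id, accession, residues)


def _identity_maps(structure):
    return {c.chain_id: sm.identity_seqmap(c) for c in structure.chains}


class TestLoadStructure:
    def test_pdb_round_trip_matches_generator(self, tmp_path, helix_monomer):
        model, _ = helix_monomer
        path = tmp_path / "mono.pdb"
        sd.write_pdb(model, path)
        loaded = sm.load_structure(path, chain_map={"A": "SYNP1"})
        assert len(loaded.chains) == 1
        assert len(loaded.chains[0].residues) == len(model.chains[0].residues)
        orig = np.array([r.atoms["CA"] for r in model.chains[0].residues])
        back = np.array([r.atoms["CA"] for r in loaded.chains[0].residues])
        assert np.allclose(orig, back, atol=1e-3)

    def test_mmcif_and_pdb_agree(self, tmp_path, c2_dimer):
        assembly, _ = c2_dimer
        pdb, cif = tmp_path / "asm.pdb", tmp_path / "asm.cif"
        sd.write_pdb(assembly, pdb)
        sd.write_pdb(assembly, cif)
        from_pdb = sm.load_structure(pdb)
        from_cif = sm.load_structure(cif)
        assert [c.chain_id for c in from_pdb.chains] == [c.chain_id for c in from_cif.chains]
        for ca, cb in zip(from_pdb.chains, from_cif.chains):
            xa = np.array([r.atoms["CA"] for r in ca.residues])
            xb = np.array([r.atoms["CA"] for r in cb.residues])
            assert np.allclose(xa, xb, atol=1e-3)

    def test_water_only_file_rejected(self, tmp_path):
        path = tmp_path / "hoh.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="no protein chains"):
            sm.load_structure(path)


class TestAlignNumbering:
    def test_constant_offset_for_identical_sequence(self, helix_monomer):
        model, seq = helix_monomer
        chain = model.chains[0]
        shifted = ChainModel(
            "A", "SYNP1",
            [Residue(r.number + 32, r.name, r.atoms) for r in chain.residues],
        )
        seqmap = sm.align_numbering(shifted, seq)
        assert seqmap.identity == 1.0
        assert all(author - 32 == uni for author, uni in seqmap.mapping.items())

    def test_internal_deletion_skips_missing_positions(self, helix_monomer):
        model, seq = helix_monomer
        chain = model.chains[0]
        kept = [r for r in chain.residues if not (20 <= r.number <= 27)]
        truncated = ChainModel("A", "SYNP1", kept)
        seqmap = sm.align_numbering(truncated, seq)
        mapped_uni = set(seqmap.mapping.values())
        assert mapped_uni == set(range(1, 61)) - set(range(20, 28))
        assert all(seqmap.mapping[r.number] == r.number for r in kept)

    def test_unrelated_sequence_refused(self, helix_monomer):
        model, _ = helix_monomer
        with pytest.raises(ValueError, match="identity"):
            sm.align_numbering(model.chains[0], "W" * 60)

    def test_empty_reference_rejected(self, helix_monomer):
        model, _ = helix_monomer
        with pytest.raises(ValueError):
            sm.align_numbering(model.chains[0], "")


class TestMapLink:
    def test_single_chain_distance(self):
        chain = _chain("A", [(0, 0, 0), (12, 0, 0)])
        structure = StructureModel([chain])
        pair = CrossLinkPair.from_sites(("P1", 1), ("P1", 2))
        link = sm.map_link(pair, structure, _identity_maps(structure))
        assert link.status == "satisfied"
        assert link.distance == pytest.approx(12.0)
        assert not link.requires_interchain

    def test_homodimer_prefers_cross_chain_when_closer(self):
        a = _chain("A", [(0, 0, 0), (48, 0, 0)])
        b = _chain("B", [(0, 22, 0), (48, 22, 0)])
        structure = StructureModel([a, b])
        pair = CrossLinkPair.from_sites(("P1", 1), ("P1", 2))
        link = sm.map_link(pair, structure, _identity_maps(structure))
        # intra-chain 48 A violates; cross-chain sqrt(48^2+22^2) also far...
        # instead use sites aligned so cross-chain is 22 A
        b2 = _chain("B", [(0, 22, 0), (0.0, 22.0, 1.0)])
        structure = StructureModel([a, _chain("B", [(48, 22, 0), (0, 22, 0)])])
        pair = CrossLinkPair.from_sites(("P1", 1), ("P1", 2))
        link = sm.map_link(pair, structure, _identity_maps(structure))
        assert link.status == "satisfied"
        assert link.distance == pytest.approx(22.0)
        assert link.requires_interchain
        assert set(link.best_assignment) == {"A", "B"}

    def test_self_link_needs_two_chains(self):
        chain = _chain("A", [(0, 0, 0), (5, 0, 0)])
        structure = StructureModel([chain])
        pair = CrossLinkPair.from_sites(("P1", 1), ("P1", 1))
        link = sm.map_link(pair, structure, _identity_maps(structure))
        assert link.status == "unmapped"
        assert "no second chain" in link.reason

    def test_self_link_on_dimer_is_interchain(self):
        a = _chain("A", [(0, 0, 0)])
        b = _chain("B", [(10, 0, 0)])
        structure = StructureModel([a, b])
        pair = CrossLinkPair.from_sites(("P1", 1), ("P1", 1))
        link = sm.map_link(pair, structure, _identity_maps(structure))
        assert link.status == "satisfied"
        assert link.distance == pytest.approx(10.0)
        assert link.requires_interchain

    def test_absent_accession_and_residue_unmapped(self):
        chain = _chain("A", [(0, 0, 0)])
        structure = StructureModel([chain])
        maps = _identity_maps(structure)
        link = sm.map_link(CrossLinkPair.from_sites(("P9", 1), ("P1", 1)), structure, maps)
        assert link.status == "unmapped" and "P9" in link.reason
        link = sm.map_link(CrossLinkPair.from_sites(("P1", 1), ("P1", 99)), structure, maps)
        assert link.status == "unmapped" and "99" in link.reason

    def test_glycine_falls_back_to_ca(self):
        res = Residue(1, "GLY", {"CA": np.zeros(3)})
        chain_a = ChainModel("A", "P1", [res])
        chain_b = _chain("B", [(0, 0, 20)], accession="P2")
        structure = StructureModel([chain_a, chain_b])
        pair = CrossLinkPair.from_sites(("P1", 1), ("P2", 1))
        link = sm.map_link(pair, structure, _identity_maps(structure))
        assert link.distance == pytest.approx(20.0)

    def test_matches_exhaustive_assignment_minimum(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n_chains = int(rng.integers(2, 5))
            n_res = 6
            chains = []
            for ci in range(n_chains):
                coords = rng.uniform(0, 50, size=(n_res, 3))
                chains.append(_chain("ABCD"[ci], coords))
            structure = StructureModel(chains)
            maps = _identity_maps(structure)
            ra, rb = int(rng.integers(1, n_res + 1)), int(rng.integers(1, n_res + 1))
            pair = CrossLinkPair.from_sites(("P1", ra), ("P1", rb))
            link = sm.map_link(pair, structure, maps)
            # brute force over all ordered chain assignments
            best = np.inf
            (ua, _), (ub, _) = pair.site_u, pair.site_v
            for ca in chains:
                for cb in chains:
                    if pair.link_class == "self" and ca.chain_id == cb.chain_id:
                        continue
                    d = np.linalg.norm(
                        ca.residue(pair.site_u[1]).atoms["CB"] - cb.residue(pair.site_v[1]).atoms["CB"]
                    )
                    best = min(best, d)
            assert link.distance == pytest.approx(float(best))

    def test_rigid_transform_invariance(self, c2_dimer):
        assembly, _ = c2_dimer
        maps = _identity_maps(assembly)
        pair = CrossLinkPair.from_sites(("SYNP1", 5), ("SYNP1", 40))
        d0 = sm.map_link(pair, assembly, maps).distance
        R = Rotation.from_rotvec([0.3, -1.2, 2.0]).as_matrix()
        t = np.array([12.0, -7.0, 3.0])
        moved = StructureModel(
            [
                ChainModel(
                    c.chain_id, c.accession,
                    [Residue(r.number, r.name, {a: R @ x + t for a, x in r.atoms.items()}) for r in c.residues],
                )
                for c in assembly.chains
            ]
        )
        d1 = sm.map_link(pair, moved, _identity_maps(moved)).distance
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_raising_dmax_never_unsatisfies(self, c2_dimer):
        assembly, _ = c2_dimer
        maps = _identity_maps(assembly)
        rng = np.random.default_rng(2)
        pairs = [
            CrossLinkPair.from_sites(("SYNP1", int(rng.integers(1, 61))), ("SYNP1", int(rng.integers(1, 61))))
            for _ in range(30)
        ]
        tight = {m.pair.key: m.status for m in sm.map_links(pairs, assembly, maps, EvalConfig(d_max=20))}
        loose = {m.pair.key: m.status for m in sm.map_links(pairs, assembly, maps, EvalConfig(d_max=35))}
        for key, status in tight.items():
            if status == "satisfied":
                assert loose[key] == "satisfied"


class TestSummaries:
    def test_threshold_tally(self):
        chain_coords = [(0, 0, 0), (10, 0, 0), (34.9, 0, 0), (35.1, 0, 0)]
        structure = StructureModel([_chain("A", chain_coords)])
        maps = _identity_maps(structure)
        pairs = [
            CrossLinkPair.from_sites(("P1", 1), ("P1", 2)),   # 10
            CrossLinkPair.from_sites(("P1", 1), ("P1", 3)),   # 34.9
            CrossLinkPair.from_sites(("P1", 1), ("P1", 4)),   # 35.1
        ]
        summary = sm.summarize_violations(sm.map_links(pairs, structure, maps))
        assert summary["global"] == {"satisfied": 2, "violated": 1, "unmapped": 0}
        assert summary["violations"][0].distance == pytest.approx(35.1)

    def test_empty_input(self):
        summary = sm.summarize_violations([])
        assert summary["global"] == {"satisfied": 0, "violated": 0, "unmapped": 0}
        assert summary["violations"] == []

    def test_counts_match_brute_force_on_synthetic_links(self, c2_dimer):
        assembly, _ = c2_dimer
        maps = _identity_maps(assembly)
        rng = np.random.default_rng(31)
        pairs = [
            CrossLinkPair.from_sites(("SYNP1", int(rng.integers(1, 61))), ("SYNP1", int(rng.integers(1, 61))))
            for _ in range(50)
        ]
        mapped = sm.map_links(pairs, assembly, maps)
        n_violated = sum(1 for m in mapped if m.distance is not None and m.distance > 35)
        summary = sm.summarize_violations(mapped)
        assert summary["global"]["violated"] == n_violated
        assert sum(summary["global"].values()) == 50


class TestLinkFile:
    def test_round_trip(self, tmp_path, c2_dimer):
        assembly, _ = c2_dimer
        maps = _identity_maps(assembly)
        rng = np.random.default_rng(41)
        pairs = [
            CrossLinkPair.from_sites(("SYNP1", int(rng.integers(1, 61))), ("SYNP1", int(rng.integers(1, 61))))
            for _ in range(20)
        ]
        mapped = sm.map_links(pairs, assembly, maps)
        path = tmp_path / "links.txt"
        omitted = sm.export_link_file(mapped, path)
        parsed = sm.read_link_file(path)
        kept = [m for m in mapped if m.status != "unmapped"]
        assert len(parsed) == len(kept) == len(mapped) - omitted
        for rec, m in zip(parsed, kept):
            assert rec["distance"] == pytest.approx(m.distance, abs=0.01)
            assert rec["status"] == m.status

    def test_satisfied_line_content(self, tmp_path):
        structure = StructureModel([_chain("A", [(0, 0, 0), (12, 0, 0)])])
        mapped = sm.map_links(
            [CrossLinkPair.from_sites(("P1", 1), ("P1", 2))], structure, _identity_maps(structure)
        )
        path = tmp_path / "one.txt"
        sm.export_link_file(mapped, path)
        body = path.read_text()
        assert "satisfied" in body and "12.00" in body

    def test_empty_export_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            sm.export_link_file([], tmp_path / "x.txt")
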