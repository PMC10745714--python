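import numpy as np
import pytest

from glycotree.errors import DegenerateFrameError, TopologyError
from glycotree.geom import measure_dihedral
from glycotree.linkage import (
    LINK_CLASS_PRESETS,
    GlycosidicLinkage,
    OligomerTopology,
    ResidueSpec,
    assemble_oligomer,
    glcnac2_topology,
    man_glcnac_topology,
    nag2man_topology,
    partition_upper_lower,
    pentasaccharide_topology,
    set_linkage_conformation,
    trimannose_topology,
)


class TestAssembleOligomer:
    def test_trimannose_atom_count(self, trimannose_cc):
        assert len(trimannose_cc.structure) == 66  # 3*24 - 2*3

    def test_trisaccharide_atom_count(self, trisaccharide_tt):
        assert len(trisaccharide_tt.structure) == 78  # 24 + 2*30 - 2*3

    def test_pentasaccharide_atom_count(self):
        olig = assemble_oligomer(pentasaccharide_topology())
        assert len(olig.structure) == 120  # 3*24 + 2*30 - 4*3

    def test_single_residue_matches_template(self, mannose):
        topo = OligomerTopology(
            "mono", [ResidueSpec("M", "alpha-D-Man", "", ("OM",))], []
        )
        olig = assemble_oligomer(topo)
        assert np.allclose(olig.structure.positions, mannose.structure.positions)

    def test_linkage_consumes_oh4_sites(self, trisaccharide_tt):
        assert trisaccharide_tt.site("OH4").consumed      # G, holds G′
        assert trisaccharide_tt.site("OH4′").consumed     # G′, holds M
        assert not trisaccharide_tt.site("OH4_M").consumed

    def test_linkage_torsions_at_presets(self, trisaccharide_tt):
        for l in trisaccharide_tt.topology.linkages:
            phi, psi = trisaccharide_tt.measure_linkage(l)
            expect_phi, expect_psi = LINK_CLASS_PRESETS[l.link_class]
            assert phi == pytest.approx(expect_phi, abs=1e-6)
            assert psi == pytest.approx(expect_psi, abs=1e-6)

    def test_position_already_consumed(self):
        topo = nag2man_topology()
        topo.linkages.append(GlycosidicLinkage("M", "G′", 4))
        with pytest.raises(TopologyError):
            assemble_oligomer(topo)

    def test_cyclic_graph_rejected(self):
        topo = OligomerTopology(
            "cycle",
            [
                ResidueSpec("A", "alpha-D-Man", "", ("OA",)),
                ResidueSpec("B", "alpha-D-Man", "'", ("OB",)),
            ],
            [GlycosidicLinkage("A", "B", 4), GlycosidicLinkage("B", "A", 4)],
        )
        with pytest.raises(TopologyError):
            assemble_oligomer(topo)

    def test_rings_stay_chairs(self, trisaccharide_tt, mannose):
        """Ring torsions of every residue equal the free template's."""
        s = trisaccharide_tt.structure
        ring = ("O5", "C1", "C2", "C3", "C4", "C5")
        tpl = mannose.structure
        ref = [
            measure_dihedral(
                tpl,
                tpl.index_of("", ring[i]),
                tpl.index_of("", ring[(i + 1) % 6]),
                tpl.index_of("", ring[(i + 2) % 6]),
                tpl.index_of("", ring[(i + 3) % 6]),
            )
            for i in range(6)
        ]
        got = [
            measure_dihedral(
                s,
                trisaccharide_tt.atom_index("M", ring[i]),
                trisaccharide_tt.atom_index("M", ring[(i + 1) % 6]),
                trisaccharide_tt.atom_index("M", ring[(i + 2) % 6]),
                trisaccharide_tt.atom_index("M", ring[(i + 3) % 6]),
            )
            for i in range(6)
        ]
        assert np.allclose(got, ref, atol=1e-6)


class TestSetLinkageConformation:
    @pytest.mark.parametrize("link_class,phi,psi", [("trans", 50.0, 120.0), ("cis", -80.0, 90.0)])
    def test_presets(self, link_class, phi, psi):
        olig = assemble_oligomer(man_glcnac_topology(link_class))
        got_phi, got_psi = olig.measure_linkage(olig.topology.linkages[0])
        assert got_phi == pytest.approx(phi, abs=1e-6)
        assert got_psi == pytest.approx(psi, abs=1e-6)

    def test_switch_class(self, disaccharide_trans):
        olig = disaccharide_trans.copy_structure()
        link = olig.topology.linkages[0]
        set_linkage_conformation(olig, link, "cis")
        assert olig.measure_linkage(link) == pytest.approx((-80.0, 90.0), abs=1e-6)

    def test_idempotent(self, disaccharide_trans):
        olig = disaccharide_trans.copy_structure()
        link = olig.topology.linkages[0]
        set_linkage_conformation(olig, link, "trans")
        first = olig.structure.positions.copy()
        set_linkage_conformation(olig, link, "trans")
        assert np.allclose(olig.structure.positions, first, atol=1e-6)

    def test_unknown_class(self, disaccharide_trans):
        olig = disaccharide_trans.copy_structure()
        with pytest.raises(TopologyError):
            set_linkage_conformation(olig, olig.topology.linkages[0], "gauche")


class TestPartitionUpperLower:
    def _split_atoms(self, olig, tags):
        return [olig.atom_index(t, "O5") for t in tags]

    def test_hydroxymethyl_sites_upper(self, trisaccharide_tt):
        part = partition_upper_lower(
            trisaccharide_tt, self._split_atoms(trisaccharide_tt, ("M", "G′", "G"))
        )
        assert part["OH6_M"] == "upper"
        assert part["OH6′"] == "upper"
        assert part["OH6"] == "upper"

    def test_lower_chain_sites(self, trisaccharide_tt):
        part = partition_upper_lower(
            trisaccharide_tt, self._split_atoms(trisaccharide_tt, ("M", "G′", "G"))
        )
        assert part["OH3"] == "lower"
        assert part["NHCO"] == "lower"
        assert part["OH3′"] == "lower"
        assert part["NHCO′"] == "lower"
        assert part["OH2_M"] == "lower"
        assert part["OH3_M"] == "lower"

    def test_total_partition(self, trisaccharide_tt):
        part = partition_upper_lower(
            trisaccharide_tt, self._split_atoms(trisaccharide_tt, ("M", "G′", "G"))
        )
        active = {s.label for s in trisaccharide_tt.active_sites()}
        assert set(part) == active
        assert set(part.values()) <= {"upper", "lower"}

    def test_rigid_motion_invariance(self, trisaccharide_tt):
        olig = trisaccharide_tt.copy_structure()
        atoms = self._split_atoms(olig, ("M", "G′", "G"))
        before = partition_upper_lower(olig, atoms)
        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        olig.structure.positions = olig.structure.positions @ q.T + rng.normal(size=3) * 5
        assert partition_upper_lower(olig, atoms) == before

    def test_too_few_oxygens(self, trisaccharide_tt):
        with pytest.raises(DegenerateFrameError):
            partition_upper_lower(trisaccharide_tt, [0, 1])


class TestBuiltinTopologies:
    @pytest.mark.parametrize(
        "factory,n_res,n_link",
        [
            (nag2man_topology, 3, 2),
            (trimannose_topology, 3, 2),
            (pentasaccharide_topology, 5, 4),
            (man_glcnac_topology, 2, 1),
            (glcnac2_topology, 2, 1),
        ],
    )
    def test_shapes(self, factory, n_res, n_link):
        topo = factory()
        assert len(topo.residues) == n_res
        assert len(topo.linkages) == n_link
        topo.validate()

    def test_atom_conservation_all_topologies(self):
        from glycotree.templates import build_template

        sizes = {"alpha-D-Man": 24, "beta-D-GlcNAc": 30}
        for factory in (nag2man_topology, trimannose_topology, pentasaccharide_topology):
            topo = factory()
            olig = assemble_oligomer(topo)
            expected = sum(sizes[r.template] for r in topo.residues) - 3 * len(topo.linkages)
            assert len(olig.structure) == expected
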