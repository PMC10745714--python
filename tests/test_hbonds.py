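import numpy as np
import pytest

from glycotree.errors import (
    ChainNotationError,
    ChainRoleError,
    ChainVocabularyError,
    DoubleDonationError,
    ReversalError,
)
from glycotree.geom import measure_distance, set_dihedral
from glycotree.hbonds import (
    HBondChain,
    HBondCriteria,
    check_conflicts,
    collinear_probe,
    detect_hbonds,
    parse_chain_notation,
    reverse_chain,
    solve_rotamers,
)


class TestParseChainNotation:
    def test_upper_chain_of_group_a(self):
        chain = parse_chain_notation("OH6_M→OH6′→OH6→OG")
        assert len(chain.steps) == 3
        assert chain.terminal_acceptor == "OG"

    def test_single_step(self):
        chain = parse_chain_notation("OH4→O′")
        assert len(chain.steps) == 1

    def test_empty_string(self):
        with pytest.raises(ChainNotationError):
            parse_chain_notation("")

    def test_single_token(self):
        with pytest.raises(ChainNotationError):
            parse_chain_notation("OH6_M")

    def test_ascii_arrows_and_apostrophes(self):
        chain = parse_chain_notation("OH6_M->OH6'->OH6->OG")
        assert chain.tokens == ("OH6_M", "OH6′", "OH6", "OG")

    def test_acceptor_only_site_cannot_donate(self):
        with pytest.raises(ChainRoleError):
            parse_chain_notation("OG→OH6")

    def test_unknown_label_with_vocabulary(self, trisaccharide_tt):
        with pytest.raises(ChainVocabularyError):
            parse_chain_notation("OH6_M→OH9", oligomer=trisaccharide_tt)

    def test_known_labels_with_vocabulary(self, trisaccharide_tt):
        parse_chain_notation("OH4_M→OH3_M→OH2_M→OH3′", oligomer=trisaccharide_tt)


class TestReverseChain:
    def test_upper_chain_reversal(self):
        chain = parse_chain_notation("OH6_M→OH6′→OH6→OG", reversible=True)
        assert reverse_chain(chain).tokens == ("OH6", "OH6′", "OH6_M")

    def test_lower_chain_reversal(self):
        chain = parse_chain_notation("OH4_M→OH3_M→OH2_M→OH3′", reversible=True)
        assert reverse_chain(chain).tokens == ("OH3′", "OH2_M", "OH3_M", "OH4_M")

    def test_double_reversal_identity_on_backbone(self):
        chain = parse_chain_notation("OH4_M→OH3_M→OH2_M→OH3′", reversible=True)
        assert reverse_chain(reverse_chain(chain)).tokens == chain.tokens

    def test_irreversible_chain(self):
        chain = parse_chain_notation("OH6_M→OH6′", reversible=False)
        with pytest.raises(ReversalError):
            reverse_chain(chain)


class TestDetectHbonds:
    def test_below_cutoff(self):
        assert len(detect_hbonds(collinear_probe(2.7))) == 1

    def test_above_cutoff(self):
        assert len(detect_hbonds(collinear_probe(2.9))) == 0

    def test_exactly_at_cutoff_is_excluded(self):
        # the criterion is a strict less-than
        assert len(detect_hbonds(collinear_probe(2.8))) == 0

    def test_observation_fields(self):
        obs = detect_hbonds(collinear_probe(2.5))
        assert len(obs) == 1
        assert obs[0].donor == "OH1"
        assert obs[0].distance == pytest.approx(2.5)
        assert obs[0].dha_angle == pytest.approx(180.0)

    def test_count_monotone_in_cutoff(self, trisaccharide_tt):
        counts = [
            len(detect_hbonds(trisaccharide_tt, HBondCriteria(max_distance=d)))
            for d in (2.0, 2.5, 3.0, 3.5, 4.0)
        ]
        assert counts == sorted(counts)

    def test_rigid_motion_invariance(self, trisaccharide_tt):
        before = [
            (o.donor, o.acceptor, round(o.distance, 9))
            for o in detect_hbonds(trisaccharide_tt)
        ]
        olig = trisaccharide_tt.copy_structure()
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        olig.structure.positions = olig.structure.positions @ q.T + rng.normal(size=3)
        after = [
            (o.donor, o.acceptor, round(o.distance, 9)) for o in detect_hbonds(olig)
        ]
        assert before == after

    def test_angle_filter(self):
        probe = collinear_probe(2.5)
        assert detect_hbonds(probe, HBondCriteria(min_dha_angle=170.0))
        # move the hydrogen off-axis: collinearity broken
        probe.structure.atoms[1].position = np.array([0.3, 0.9, 0.0])
        assert not detect_hbonds(probe, HBondCriteria(min_dha_angle=170.0))


class TestSolveRotamers:
    def test_group_b_realizes_paper_bonds(self, trisaccharide_tt):
        chains = [
            parse_chain_notation(t)
            for t in ("OH6→OG′", "OH6′→OM", "OH6_M→OH4_M")
        ]
        res = solve_rotamers(trisaccharide_tt, chains)
        got = {(o.donor, o.acceptor) for o in res.realized}
        assert {("OH6", "OG′"), ("OH6′", "OM"), ("OH6_M", "OH4_M")} <= got

    def test_single_torsion_matches_grid_oracle(self, trisaccharide_tt):
        """Exhaustive 1-degree scan oracle for a single free hydroxyl."""
        chain = parse_chain_notation("OH2_M→OH3′")
        res = solve_rotamers(trisaccharide_tt, [chain])
        solved = res.oligomer
        inst = solved.site("OH2_M")
        h = inst.donor_h(solved)
        target = solved.site("OH3′").acceptor_atom(solved)
        solved_d = measure_distance(solved.structure, h, target)
        # oracle: independent 1-degree scan on a fresh copy
        work = trisaccharide_tt.copy_structure()
        w_inst = work.site("OH2_M")
        quad = [work.atom_index(w_inst.residue, n) for n in w_inst.site.h_torsion]
        w_target = work.site("OH3′").acceptor_atom(work)
        w_h = w_inst.donor_h(work)
        best = np.inf
        for t in range(-180, 180):
            set_dihedral(work.structure, *quad, float(t), in_place=True)
            best = min(best, measure_distance(work.structure, w_h, w_target))
        assert solved_d <= best + 1e-3

    def test_out_of_range_step_reported_infeasible(self, trisaccharide_tt):
        # OH6_M and O1 (reducing end) are on opposite ends of the molecule
        chain = parse_chain_notation("OH6_M→O1")
        res = solve_rotamers(trisaccharide_tt, [chain])
        assert ("OH6_M", "O1") in {(d, a) for d, a, _ in res.infeasible}
        assert not res.realized

    def test_double_donation_raises(self, trisaccharide_tt):
        chains = [
            parse_chain_notation("OH6_M→OH6′"),
            parse_chain_notation("OH6_M→OH4_M"),
        ]
        with pytest.raises(DoubleDonationError):
            solve_rotamers(trisaccharide_tt, chains)

    def test_self_consistency_with_detection(self, trisaccharide_tt):
        chains = [
            parse_chain_notation("OH6→OG′"),
            parse_chain_notation("OH4_M→OH3_M→OH2_M→OH3′"),
        ]
        res = solve_rotamers(trisaccharide_tt, chains)
        detected = {(o.donor, o.acceptor) for o in detect_hbonds(res.oligomer)}
        assert res.satisfied_steps <= detected

    def test_consumed_donor_reported(self):
        from glycotree.linkage import assemble_oligomer, pentasaccharide_topology

        olig = assemble_oligomer(pentasaccharide_topology())
        chain = HBondChain(("OH6_M", "OH6′"))  # OH6_M consumed by the 1→6 bond
        res = solve_rotamers(olig, [chain])
        assert any("consumed" in reason for _, _, reason in res.infeasible)


class TestCheckConflicts:
    def test_paper_mutual_pointing_case(self, trisaccharide_tt):
        """Upper pinned onto OH4_M while the reversed lower chain terminally
        accepts there."""
        chains = [
            parse_chain_notation("OH6_M→OH4_M"),
            parse_chain_notation("OH3′→OH2_M→OH3_M→OH4_M"),
        ]
        hits = check_conflicts(chains, trisaccharide_tt)
        assert any(
            h.kind == "mutual-pointing" and set(h.sites) == {"OH6_M", "OH4_M"} for h in hits
        )

    def test_disjoint_chains_clean(self, trisaccharide_tt):
        chains = [
            parse_chain_notation("OH6→OG′"),
            parse_chain_notation("OH3→NHCO→O1"),
        ]
        assert check_conflicts(chains, trisaccharide_tt) == []

    def test_double_donation_flagged(self, trisaccharide_tt):
        chains = [
            parse_chain_notation("OH6_M→OH6′"),
            parse_chain_notation("OH6_M→OH4_M"),
        ]
        hits = check_conflicts(chains, trisaccharide_tt)
        assert any(h.kind == "double-donation" for h in hits)

    def test_consumed_site_orientation_clash(self):
        from glycotree.linkage import assemble_oligomer, pentasaccharide_topology

        olig = assemble_oligomer(pentasaccharide_topology())
        chains = [parse_chain_notation("OH6_M→OH6′")]
        hits = check_conflicts(chains, olig)
        assert any(h.kind == "orientation-clash" and "OH6_M" in h.sites for h in hits)

    def test_terminal_donors_targeting_each_other(self, trisaccharide_tt):
        chains = [
            parse_chain_notation("OH3_M→OH2_M"),
            parse_chain_notation("OH2_M→OH3_M"),
        ]
        hits = check_conflicts(chains, trisaccharide_tt)
        assert any(h.kind == "mutual-pointing" for h in hits)
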