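import itertools

import pytest

from glycotree.errors import CatalogError, SelectionError
from glycotree.hbonds import check_conflicts, parse_chain_notation
from glycotree.tree import (
    BuildingBlock,
    MotifCatalog,
    MotifGroup,
    _builtin_blocks,
    builtin_catalog,
    catalog_from_dict,
    combine_blocks,
    enumerate_conformers,
    expand_directions,
)

PAPER_GROUP_COUNTS = {
    "nag2man-trans-trans1": {"A": 3, "B": 1},
    "nag2man-trans-cis1": {"C": 1, "D": 1, "E": 1, "F": 1, "G": 2, "H": 2, "I": 2, "J": 2},
    "nag2man-cis-cis1": {"K": 8, "L": 8, "M": 8, "N": 8, "O": 4},
    "nag2man-cis-trans1": {"P": 2, "Q": 2, "R": 2, "S": 2, "T": 1},
}


class TestBuiltinCatalogs:
    def test_unknown_name(self):
        with pytest.raises(CatalogError):
            builtin_catalog("hexasaccharide")

    def test_aliases(self):
        assert builtin_catalog("trisaccharide-trans-trans1").name == "nag2man-trans-trans1"

    @pytest.mark.parametrize("name,expected", sorted(PAPER_GROUP_COUNTS.items()))
    def test_trisaccharide_group_counts(self, enumerations, name, expected):
        assert enumerations[name].counts_per_group == expected

    def test_trimannose_group_counts(self, enumerations):
        assert enumerations["trimannose"].counts_per_group == {
            "A": 4, "B": 2, "C": 4, "D": 4, "E": 2, "F": 2,
            "G": 1, "H": 1, "I": 1, "J": 2, "K": 2, "L": 1, "M": 1,
        }

    def test_trimannose_fragility_warning_flags(self, catalogs):
        cat = catalogs["trimannose"]
        assert cat.group("C").warning and cat.group("D").warning
        assert cat.group("A").warning is None


class TestExpandDirections:
    def test_group_k_eight_variants(self, catalogs):
        assert len(expand_directions(catalogs["nag2man-cis-cis1"].group("K"))) == 8

    def test_group_o_four_variants(self, catalogs):
        assert len(expand_directions(catalogs["nag2man-cis-cis1"].group("O"))) == 4

    def test_no_reversible_chain_single_variant(self, catalogs):
        assert len(expand_directions(catalogs["trimannose"].group("G"))) == 1

    def test_toy_two_reversible_chains(self):
        data = {
            "name": "toy",
            "molecule": "nag2man",
            "linkage_classes": {"man": "trans", "nag": "trans"},
            "groups": [
                {
                    "label": "X",
                    "chains": [
                        {"steps": "OH6_M→OH6′", "reversible": True},
                        {"steps": "OH3→NHCO→O1", "reversible": True},
                    ],
                }
            ],
        }
        cat = catalog_from_dict(data)
        assert len(expand_directions(cat.group("X"))) == 4

    def test_expected_count_invariant(self, catalogs):
        for cat in catalogs.values():
            for g in cat.groups:
                assert len(expand_directions(g)) == g.expected_count


class TestEnumerationOracle:
    """Brute-force oracle: independently expand every direction assignment and
    filter with the conflict rules plus explicit exclusions."""

    def _oracle_count(self, catalog: MotifCatalog, group: MotifGroup) -> int:
        skel = catalog.skeleton_for(group)
        options = [("fwd", "rev") if c.reversible else ("fwd",) for c in group.chains]
        explicit = set(map(tuple, group.explicit_excluded))
        count = 0
        for combo in itertools.product(*options):
            if combo in explicit:
                continue
            realized = group.realize(combo)
            if check_conflicts(realized, skel):
                continue
            count += 1
        return count

    @pytest.mark.parametrize(
        "name",
        [
            "nag2man-trans-trans1",
            "nag2man-trans-cis1",
            "nag2man-cis-cis1",
            "nag2man-cis-trans1",
            "trimannose",
            "pentasaccharide-strategy1",
            "pentasaccharide-strategy2",
            "pentasaccharide-strategy3",
        ],
    )
    def test_counts_match_oracle(self, catalogs, enumerations, name):
        cat = catalogs[name]
        result = enumerations[name]
        for g in cat.groups:
            assert result.counts_per_group[g.label] == self._oracle_count(cat, g)


class TestEnumerationProperties:
    def test_every_conformer_passes_conflict_check(self, catalogs, enumerations):
        for name, result in enumerations.items():
            cat = catalogs[name]
            for rec in result.conformers:
                g = cat.group(rec.group)
                assert check_conflicts(g.realize(rec.directions), cat.skeleton_for(g)) == []

    def test_no_duplicate_provenance(self, enumerations):
        for result in enumerations.values():
            seen = [(r.group, r.directions) for r in result.conformers]
            assert len(seen) == len(set(seen))

    def test_no_identical_hbond_sets_within_group(self, enumerations):
        for result in enumerations.values():
            by_group: dict[str, list] = {}
            for rec in result.conformers:
                key = frozenset((o.donor, o.acceptor) for o in rec.realized_hbonds)
                by_group.setdefault(rec.group, []).append((rec.directions, key))
            for group, entries in by_group.items():
                keys = [k for _, k in entries]
                # identical realized sets may only occur for distinct direction
                # vectors whose differing chains were entirely infeasible;
                # provenance tuples must still be unique
                assert len(entries) == len({d for d, _ in entries})

    def test_determinism(self, catalogs):
        cat = catalogs["nag2man-trans-trans1"]
        a = enumerate_conformers(cat)
        b = enumerate_conformers(cat)
        assert [r.conformer_id for r in a.conformers] == [r.conformer_id for r in b.conformers]
        for ra, rb in zip(a.conformers, b.conformers):
            assert (ra.structure.positions == rb.structure.positions).all()

    def test_conformer_ids_follow_group_order(self, enumerations):
        res = enumerations["nag2man-trans-trans1"]
        assert [r.conformer_id for r in res.conformers] == ["A1", "A2", "A3", "B1"]

    def test_realized_hbonds_satisfy_criteria(self, catalogs, enumerations):
        for name, result in enumerations.items():
            crit = catalogs[name].criteria
            for rec in result.conformers:
                for obs in rec.realized_hbonds:
                    assert obs.distance < crit.max_distance


class TestCombineBlocks:
    def test_strategy1_six_configurations(self, enumerations):
        assert enumerations["pentasaccharide-strategy1"].total == 6

    def test_strategy2_twelve_configurations(self, enumerations):
        assert enumerations["pentasaccharide-strategy2"].total == 12

    def test_strategy3_four_groups(self, catalogs):
        assert len(catalogs["pentasaccharide-strategy3"].groups) == 4

    def test_strategy1_excludes_om_duality_variant(self, catalogs):
        # the OH2→OM orientation duplicates strategy 2 and must not appear
        for g in catalogs["pentasaccharide-strategy1"].groups:
            for chain in g.chains:
                for donor, acceptor in chain.steps:
                    assert not (donor == "OH2_M" and acceptor == "OM")

    def test_strategy2_crosses_junction_classes(self, catalogs):
        junctions = {g.linkage_classes["junction"] for g in catalogs["pentasaccharide-strategy2"].groups}
        assert junctions == {"cis", "trans"}

    def test_selection_threshold(self):
        blocks = _builtin_blocks()
        with pytest.raises(SelectionError):
            combine_blocks(2, blocks["trimannose"], blocks["glcnac2"], selection_threshold=-1.0)

    def test_tight_threshold_shrinks_catalog(self):
        blocks = _builtin_blocks()
        # only tri-A1 (0.0) and tri-G1 (gibbs 0.0) pass a 1 kJ/mol cut
        cat = combine_blocks(2, blocks["trimannose"], blocks["glcnac2"], selection_threshold=1.0)
        tri_ids = {g.label.split("+")[0] for g in cat.groups}
        assert tri_ids == {"tri-A1", "tri-G1"}

    def test_unknown_strategy(self):
        blocks = _builtin_blocks()
        with pytest.raises(CatalogError):
            combine_blocks(4, blocks["trimannose"], blocks["glcnac2"])

    def test_no_consumed_sites_in_combined_chains(self, catalogs):
        for s in (1, 2, 3):
            cat = catalogs[f"pentasaccharide-strategy{s}"]
            for g in cat.groups:
                skel = cat.skeleton_for(g)
                for chain in g.chains:
                    for token in chain.tokens:
                        assert not skel.site(token).consumed
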