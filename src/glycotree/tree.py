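"""Three-step tree enumeration of conformers.

Region SI of the building tree fixes the glycosidic-linkage classes, region
SII the inter-ring hydrogen-bond motif groups, region SIII the directions of
the cooperative chains.  A catalog is the SII inventory for one molecule;
enumeration expands every group over its reversible-chain directions, prunes
conflicting combinations, builds the 3D structure of each survivor and
realizes its chains.

Catalogs are data (YAML files under ``data/catalogs``), not code; the
built-in set covers the two trisaccharides and the three block-combination
strategies for the core pentasaccharide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import CatalogError, SelectionError
from .hbonds import (
    HBondChain,
    HBondCriteria,
    HBondObservation,
    check_conflicts,
    parse_chain_notation,
    reverse_chain,
    solve_rotamers,
)
from .linkage import (
    AssembledOligomer,
    OligomerTopology,
    assemble_oligomer,
    glcnac2_topology,
    man_glcnac_topology,
    nag2man_topology,
    pentasaccharide_topology,
    trimannose_topology,
)

__all__ = [
    "MotifGroup",
    "MotifCatalog",
    "ConformerRecord",
    "EnumerationResult",
    "BuildingBlock",
    "builtin_catalog",
    "load_catalog",
    "validate_catalog",
    "expand_directions",
    "enumerate_conformers",
    "combine_blocks",
    "BUILTIN_CATALOGS",
]

#: staggered hydroxymethyl rotamers, ω = O6-C6-C5-O5
HYDROXYMETHYL_ROTAMERS = {"gg": -60.0, "gt": 60.0, "tg": 180.0}

_TOPOLOGY_FACTORIES = {
    "nag2man": lambda classes: nag2man_topology(
        classes.get("man", "trans"), classes.get("nag", "trans")
    ),
    "trimannose": lambda classes: trimannose_topology(
        classes.get("m13", "cis"), classes.get("m16", "cis")
    ),
    "pentasaccharide": lambda classes: pentasaccharide_topology(
        classes.get("m13", "cis"),
        classes.get("m16", "cis"),
        classes.get("junction", "trans"),
        classes.get("nag", "trans"),
    ),
    "man-glcnac": lambda classes: man_glcnac_topology(classes.get("man", "trans")),
    "glcnac2": lambda classes: glcnac2_topology(classes.get("nag", "trans")),
}

BUILTIN_CATALOGS = (
    "nag2man-trans-trans1",
    "nag2man-trans-cis1",
    "nag2man-cis-cis1",
    "nag2man-cis-trans1",
    "trimannose",
    "pentasaccharide-strategy1",
    "pentasaccharide-strategy2",
    "pentasaccharide-strategy3",
)

_CATALOG_ALIASES = {
    "trisaccharide-trans-trans1": "nag2man-trans-trans1",
    "trisaccharide-trans-cis1": "nag2man-trans-cis1",
    "trisaccharide-cis-cis1": "nag2man-cis-cis1",
    "trisaccharide-cis-trans1": "nag2man-cis-trans1",
}


@dataclass
class MotifGroup:
    """One SII group: a linkage-class skeleton plus hydrogen-bond chains."""

    label: str
    linkage_classes: dict[str, str]
    chains: list[HBondChain]
    explicit_excluded: list[tuple[str, ...]] = field(default_factory=list)
    hydroxymethyl: dict[str, str] = field(default_factory=dict)
    warning: str | None = None
    #: direction combinations removed (explicit + conflict-derived); filled
    #: when the catalog is materialized against its topology
    excluded_variants: set[tuple[str, ...]] = field(default_factory=set)

    @property
    def n_reversible(self) -> int:
        return sum(1 for c in self.chains if c.reversible)

    @property
    def expected_count(self) -> int:
        return 2**self.n_reversible - len(self.excluded_variants)

    def all_direction_vectors(self) -> list[tuple[str, ...]]:
        """Deterministic order: fwd before rev, earlier chains varying fastest."""
        options = [("fwd", "rev") if c.reversible else ("fwd",) for c in self.chains]
        return [t[::-1] for t in itertools.product(*options[::-1])]

    def realize(self, directions: tuple[str, ...]) -> list[HBondChain]:
        out = []
        for chain, d in zip(self.chains, directions):
            out.append(reverse_chain(chain) if d == "rev" else chain)
        return out


@dataclass
class MotifCatalog:
    name: str
    molecule: str
    groups: list[MotifGroup]
    criteria: HBondCriteria = HBondCriteria()
    default_classes: dict[str, str] = field(default_factory=dict)
    _skeletons: dict = field(default_factory=dict, repr=False)

    def group(self, label: str) -> MotifGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise CatalogError(f"no group {label!r} in catalog {self.name}")

    def classes_for(self, group: MotifGroup) -> dict[str, str]:
        merged = dict(self.default_classes)
        merged.update(group.linkage_classes)
        return merged

    def topology_for(self, group: MotifGroup) -> OligomerTopology:
        try:
            factory = _TOPOLOGY_FACTORIES[self.molecule]
        except KeyError:
            raise CatalogError(f"unknown molecule kind {self.molecule!r}") from None
        return factory(self.classes_for(group))

    def skeleton_for(self, group: MotifGroup) -> AssembledOligomer:
        key = tuple(sorted(self.classes_for(group).items()))
        if key not in self._skeletons:
            self._skeletons[key] = assemble_oligomer(self.topology_for(group))
        return self._skeletons[key]

    def validate(self) -> list[str]:
        problems: list[str] = []
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            problems.append("duplicate group labels")
        for g in self.groups:
            try:
                skel = self.skeleton_for(g)
            except Exception as exc:  # noqa: BLE001 - reported, not raised
                problems.append(f"group {g.label}: cannot build skeleton ({exc})")
                continue
            donors_seen: dict[str, int] = {}
            for ci, chain in enumerate(g.chains):
                for t in chain.tokens:
                    if not skel.has_site(t):
                        problems.append(f"group {g.label}: unknown site {t!r}")
                for d in chain.donors:
                    if d in donors_seen and donors_seen[d] != ci:
                        problems.append(
                            f"group {g.label}: site {d!r} donates in two chains"
                        )
                    donors_seen.setdefault(d, ci)
            for res in g.hydroxymethyl.values():
                if res not in HYDROXYMETHYL_ROTAMERS:
                    problems.append(f"group {g.label}: unknown rotamer {res!r}")
        return problems

    def materialize_exclusions(self) -> None:
        """Fill ``excluded_variants`` for every group: explicit entries plus
        direction combinations rejected by the conflict rules."""
        for g in self.groups:
            skel = self.skeleton_for(g)
            excluded: set[tuple[str, ...]] = set(tuple(e) for e in g.explicit_excluded)
            for directions in g.all_direction_vectors():
                if directions in excluded:
                    continue
                if check_conflicts(g.realize(directions), skel):
                    excluded.add(directions)
            g.excluded_variants = excluded


@dataclass
class ConformerRecord:
    """A built conformer with provenance and realized hydrogen bonds."""

    conformer_id: str
    catalog: str
    group: str
    directions: tuple[str, ...]
    oligomer: AssembledOligomer
    realized_hbonds: list[HBondObservation]
    infeasible: list[tuple[str, str, str]]
    annotations: dict[str, float] = field(default_factory=dict)

    @property
    def structure(self):
        return self.oligomer.structure

    @property
    def provenance(self) -> tuple[str, str, tuple[str, ...]]:
        return (self.catalog, self.group, self.directions)


@dataclass
class EnumerationResult:
    catalog: str
    conformers: list[ConformerRecord]
    counts_per_group: dict[str, int]
    counts_per_class: dict[str, int]
    pruning_log: list[tuple[str, tuple[str, ...], str]]

    @property
    def total(self) -> int:
        return len(self.conformers)


def expand_directions(group: MotifGroup) -> list[tuple[str, ...]]:
    """Surviving direction vectors of a group: the Cartesian product over its
    reversible chains minus the excluded variants."""
    return [d for d in group.all_direction_vectors() if d not in group.excluded_variants]


def enumerate_conformers(
    catalog: MotifCatalog, criteria: HBondCriteria | None = None
) -> EnumerationResult:
    """Expand a catalog into built conformers, deterministically ordered
    (groups in label order, directions lexicographic with fwd before rev)."""
    problems = catalog.validate()
    if problems:
        raise CatalogError(f"catalog {catalog.name} invalid: " + "; ".join(problems))
    crit = criteria if criteria is not None else catalog.criteria
    conformers: list[ConformerRecord] = []
    counts_per_group: dict[str, int] = {}
    counts_per_class: dict[str, int] = {}
    pruning: list[tuple[str, tuple[str, ...], str]] = []
    for group in sorted(catalog.groups, key=lambda g: g.label):
        skel = catalog.skeleton_for(group)
        survivors = []
        for directions in group.all_direction_vectors():
            if tuple(directions) in set(map(tuple, group.explicit_excluded)):
                pruning.append((group.label, directions, "explicitly excluded"))
                continue
            hits = check_conflicts(group.realize(directions), skel)
            if hits:
                reason = "; ".join(f"{h.kind}{h.sites}" for h in hits)
                pruning.append((group.label, directions, reason))
                continue
            survivors.append(directions)
        for k, directions in enumerate(survivors, start=1):
            chains = group.realize(directions)
            working = skel.copy_structure()
            fixed = {
                f"OH6{working.topology.residue(res).site_suffix}": HYDROXYMETHYL_ROTAMERS[rot]
                for res, rot in group.hydroxymethyl.items()
            }
            result = solve_rotamers(working, chains, crit, preset_heavy=fixed)
            conformers.append(
                ConformerRecord(
                    conformer_id=f"{group.label}{k}",
                    catalog=catalog.name,
                    group=group.label,
                    directions=directions,
                    oligomer=result.oligomer,
                    realized_hbonds=result.realized,
                    infeasible=result.infeasible,
                )
            )
        counts_per_group[group.label] = len(survivors)
        class_key = "-".join(v for _, v in sorted(catalog.classes_for(group).items()))
        counts_per_class[class_key] = counts_per_class.get(class_key, 0) + len(survivors)
    return EnumerationResult(catalog.name, conformers, counts_per_group, counts_per_class, pruning)


# ---------------------------------------------------------------------------
# catalog loading
# ---------------------------------------------------------------------------


def _parse_group(raw: dict) -> MotifGroup:
    chains = []
    for c in raw.get("chains", []):
        chains.append(
            parse_chain_notation(
                c["steps"], region=c.get("region"), reversible=bool(c.get("reversible", False))
            )
        )
    excluded = [tuple(e) for e in raw.get("excluded", [])]
    for e in excluded:
        if len(e) != len(chains) or any(d not in ("fwd", "rev") for d in e):
            raise CatalogError(f"group {raw.get('label')}: malformed excluded entry {e}")
    return MotifGroup(
        label=str(raw["label"]),
        linkage_classes=dict(raw.get("linkage_classes", {})),
        chains=chains,
        explicit_excluded=excluded,
        hydroxymethyl=dict(raw.get("hydroxymethyl", {})),
        warning=raw.get("warning"),
    )


def catalog_from_dict(data: dict) -> MotifCatalog:
    crit_raw = data.get("criteria", {})
    criteria = HBondCriteria(
        max_distance=float(crit_raw.get("max_distance", 2.8)),
        min_dha_angle=crit_raw.get("min_dha_angle"),
    )
    cat = MotifCatalog(
        name=str(data["name"]),
        molecule=str(data["molecule"]),
        groups=[_parse_group(g) for g in data.get("groups", [])],
        criteria=criteria,
        default_classes=dict(data.get("linkage_classes", {})),
    )
    problems = cat.validate()
    if problems:
        raise CatalogError(f"catalog {cat.name} invalid: " + "; ".join(problems))
    cat.materialize_exclusions()
    return cat


def load_catalog(path: str | Path) -> MotifCatalog:
    """Load and materialize a catalog from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise CatalogError(f"{path}: not a catalog mapping")
    return catalog_from_dict(data)


def validate_catalog(path_or_catalog) -> list[str]:
    """Problem list for a catalog (empty = valid)."""
    if isinstance(path_or_catalog, MotifCatalog):
        return path_or_catalog.validate()
    with open(path_or_catalog, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        cat = MotifCatalog(
            name=str(data["name"]),
            molecule=str(data["molecule"]),
            groups=[_parse_group(g) for g in data.get("groups", [])],
            default_classes=dict(data.get("linkage_classes", {})),
        )
    except Exception as exc:  # noqa: BLE001
        return [str(exc)]
    return cat.validate()


def _builtin_data(name: str) -> dict:
    path = resources.files("glycotree").joinpath(f"data/catalogs/{name}.yaml")
    return yaml.safe_load(path.read_text(encoding="utf-8"))


def builtin_catalog(name: str) -> MotifCatalog:
    """A built-in motif catalog by name (see :data:`BUILTIN_CATALOGS`)."""
    name = _CATALOG_ALIASES.get(name, name)
    if name.startswith("pentasaccharide-strategy"):
        strategy = int(name.rsplit("strategy", 1)[1])
        blocks = _builtin_blocks()
        if strategy == 1:
            return combine_blocks(1, blocks["trimannose"], blocks["nag2man"])
        if strategy == 2:
            return combine_blocks(2, blocks["trimannose"], blocks["glcnac2"])
        if strategy == 3:
            return combine_blocks(3, blocks["strategy3"], blocks["glcnac2"])
        raise CatalogError(f"unknown strategy {strategy}")
    if name not in BUILTIN_CATALOGS:
        raise CatalogError(f"unknown catalog {name!r}; known: {sorted(BUILTIN_CATALOGS)}")
    return catalog_from_dict(_builtin_data(name))


# ---------------------------------------------------------------------------
# pentasaccharide block combination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BuildingBlock:
    """A low-energy sub-structure used to compose the pentasaccharide.

    ``chains`` are written in the pentasaccharide's site-label space;
    ``linkage_classes`` are the classes the block imposes on the
    pentasaccharide linkages it covers.  Energies are relative (kJ/mol).
    """

    id: str
    linkage_classes: tuple[tuple[str, str], ...]
    chains: tuple[str, ...]
    energy_0k: float = 0.0
    gibbs_298: float = 0.0

    @property
    def classes(self) -> dict[str, str]:
        return dict(self.linkage_classes)


def _block_from_dict(raw: dict) -> BuildingBlock:
    return BuildingBlock(
        id=str(raw["id"]),
        linkage_classes=tuple(sorted(raw.get("linkage_classes", {}).items())),
        chains=tuple(raw.get("chains", [])),
        energy_0k=float(raw.get("energy_0k", 0.0)),
        gibbs_298=float(raw.get("gibbs_298", 0.0)),
    )


def _builtin_blocks() -> dict:
    data = _builtin_data("pentasaccharide-blocks")
    return {
        "trimannose": [_block_from_dict(b) for b in data["trimannose"]],
        "nag2man": [_block_from_dict(b) for b in data["nag2man"]],
        "glcnac2": [_block_from_dict(b) for b in data["glcnac2"]],
        "strategy3": data["strategy3"],
    }


def _select_blocks(blocks: list[BuildingBlock], threshold: float) -> list[BuildingBlock]:
    kept = [b for b in blocks if min(b.energy_0k, b.gibbs_298) <= threshold]
    if not kept:
        raise SelectionError(f"no blocks within {threshold} kJ/mol")
    return kept


def _sanitize_chains(
    chain_texts: list[str], skeleton: AssembledOligomer
) -> tuple[list[str], list[str]]:
    """Drop chain steps that reference sites consumed by the pentasaccharide
    linkages (e.g. OH6_M, lost to the 1→6 bond), splitting chains into the
    remaining valid runs.  Returns (kept chain notations, drop log)."""
    kept: list[str] = []
    log: list[str] = []

    def usable(token: str) -> bool:
        if not skeleton.has_site(token):
            return False
        return not skeleton.site(token).consumed

    for text in chain_texts:
        chain = parse_chain_notation(text)
        run: list[str] = []
        runs: list[list[str]] = []
        for a, b in chain.steps:
            if usable(a) and usable(b):
                if not run:
                    run = [a, b]
                else:
                    run.append(b)
            else:
                bad = a if not usable(a) else b
                log.append(f"dropped step {a}→{b} ({bad} consumed by a linkage)")
                if run:
                    runs.append(run)
                    run = []
        if run:
            runs.append(run)
        for r in runs:
            kept.append("→".join(r))
    return kept, log


def _merge_with_oh2_duality(
    tri_chains: list[str], partner_chains: list[str]
) -> list[tuple[str, list[str]]]:
    """Merge two chain sets over the shared M ring.

    If OH2_M donates on both sides (toward OM in the trimannose block and
    toward a GlcNAc-side acceptor in the partner block), both orientations are
    constructed: the ``om`` variant keeps the trimannose chain, the ``redirect``
    variant splices the partner's continuation onto it.  Returns a list of
    (variant_tag, chains).
    """
    def donor_map(chains: list[str]) -> dict[str, int]:
        out = {}
        for i, text in enumerate(chains):
            for d in parse_chain_notation(text).donors:
                out[d] = i
        return out

    tri_donors = donor_map(tri_chains)
    dup = [d for d in donor_map(partner_chains) if d in tri_donors]
    if not dup:
        return [("", tri_chains + partner_chains)]
    variants: list[tuple[str, list[str]]] = []
    for tag in ("om", "redirect"):
        tri_part = list(tri_chains)
        partner_part = list(partner_chains)
        for d in dup:
            ti = tri_donors[d]
            pchain = next(c for c in partner_part if d in parse_chain_notation(c).donors)
            partner_part.remove(pchain)
            if tag == "redirect":
                t_tokens = list(parse_chain_notation(tri_part[ti]).tokens)
                p_tokens = list(parse_chain_notation(pchain).tokens)
                cut = t_tokens.index(d)
                splice = p_tokens[p_tokens.index(d):]
                tri_part[ti] = "→".join(t_tokens[:cut] + splice)
        variants.append((tag, tri_part + partner_part))
    return variants


def combine_blocks(
    strategy: int,
    blocks_a,
    blocks_b,
    selection_threshold: float = 10.0,
    criteria: HBondCriteria = HBondCriteria(),
) -> MotifCatalog:
    """Compose a pentasaccharide motif catalog from building blocks.

    Strategy 1 joins trimannose and Man-GlcNAc-GlcNAc trisaccharide blocks,
    applying the OH2 duality rule on the shared mannose and discarding the
    OH2→OM orientation as a duplicate of strategy 2.  Strategy 2 crosses
    trimannose blocks with GlcNAc-GlcNAc disaccharide blocks and both
    junction linkage classes.  Strategy 3 combines per-mannose attachment
    options with a disaccharide block into four groups.
    """
    groups: list[MotifGroup] = []

    def skeleton(classes: dict[str, str]) -> AssembledOligomer:
        return assemble_oligomer(_TOPOLOGY_FACTORIES["pentasaccharide"](classes))

    if strategy == 1:
        tri_sel = _select_blocks(list(blocks_a), selection_threshold)
        tris_sel = _select_blocks(list(blocks_b), selection_threshold)
        for tri in tri_sel:
            for tris in tris_sel:
                classes = {**tri.classes, **tris.classes}
                skel = skeleton(classes)
                tri_chains, _ = _sanitize_chains(list(tri.chains), skel)
                tris_chains, _ = _sanitize_chains(list(tris.chains), skel)
                for tag, merged in _merge_with_oh2_duality(tri_chains, tris_chains):
                    if tag == "om":
                        # OH2→OM orientation duplicates the strategy-2 build
                        continue
                    label = f"{tri.id}+{tris.id}"
                    groups.append(
                        MotifGroup(
                            label=label,
                            linkage_classes=classes,
                            chains=[parse_chain_notation(c) for c in merged],
                        )
                    )
    elif strategy == 2:
        tri_sel = _select_blocks(list(blocks_a), selection_threshold)
        di_sel = _select_blocks(list(blocks_b), selection_threshold)
        for tri in tri_sel:
            for di in di_sel:
                for junction in ("cis", "trans"):
                    classes = {**tri.classes, **di.classes, "junction": junction}
                    skel = skeleton(classes)
                    chains, _ = _sanitize_chains(
                        list(tri.chains) + list(di.chains), skel
                    )
                    groups.append(
                        MotifGroup(
                            label=f"{tri.id}+{di.id}-{junction}",
                            linkage_classes=classes,
                            chains=[parse_chain_notation(c) for c in chains],
                        )
                    )
    elif strategy == 3:
        spec = blocks_a  # raw strategy-3 option table
        di_sel = _select_blocks(list(blocks_b), selection_threshold)
        di = di_sel[0]
        base_classes = dict(spec.get("linkage_classes", {}))
        for up in spec["upper_options"]:
            for lo in spec["lower_options"]:
                classes = {**base_classes, **di.classes}
                skel = skeleton(classes)
                chains, _ = _sanitize_chains(
                    list(up["chains"]) + list(lo["chains"]) + list(di.chains), skel
                )
                groups.append(
                    MotifGroup(
                        label=f"{up['id']}+{lo['id']}",
                        linkage_classes=classes,
                        chains=[parse_chain_notation(c) for c in chains],
                    )
                )
    else:
        raise CatalogError(f"unknown strategy {strategy!r} (expected 1, 2 or 3)")

    if not groups:
        raise SelectionError("block combination produced no groups")
    cat = MotifCatalog(
        name=f"pentasaccharide-strategy{strategy}",
        molecule="pentasaccharide",
        groups=groups,
        criteria=criteria,
    )
    problems = cat.validate()
    if problems:
        raise CatalogError(f"combined catalog invalid: " + "; ".join(problems))
    cat.materialize_exclusions()
    return cat
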