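"""Regenerate the residue template internal-coordinate tables.

Run from the repository root:

    python scripts/generate_templates.py

Writes ``src/glycotree/data/templates/<residue>.zmat`` for every built-in
residue from the programmatic construction in ``glycotree.templates``.
"""

from pathlib import Path

from glycotree.geom import cartesian_to_zmatrix
from glycotree.templates import KNOWN_RESIDUES, build_template_from_scratch

OUT = Path(__file__).resolve().parent.parent / "src" / "glycotree" / "data" / "templates"


def format_table(name: str) -> str:
    tpl = build_template_from_scratch(name)
    s = tpl.structure
    rows = cartesian_to_zmatrix(s)
    lines = [
        "# glycotree residue template, format v1",
        f"# residue: {name}",
        f"# anomeric: {tpl.anomeric_config}",
        "# columns: name element bond_ref length(A) angle_ref angle(deg) torsion_ref torsion(deg)",
    ]
    names = [a.name for a in s.atoms]
    tree_bonds = set()
    for i, r in enumerate(rows):
        def fmt_ref(j):
            return names[j] if j is not None else "-"

        def fmt_val(v, nd=6):
            return f"{v:.{nd}f}" if v is not None else "-"

        if r.bond_ref is not None:
            tree_bonds.add(frozenset((i, r.bond_ref)))
        lines.append(
            f"{r.name:<4s} {r.element:<2s} {fmt_ref(r.bond_ref):<4s} {fmt_val(r.length)} "
            f"{fmt_ref(r.angle_ref):<4s} {fmt_val(r.angle)} "
            f"{fmt_ref(r.torsion_ref):<4s} {fmt_val(r.torsion)}"
        )
    for b in sorted(s.bonds, key=sorted):
        if b not in tree_bonds:
            i, j = sorted(b)
            lines.append(f"# closure: {names[i]}-{names[j]}")
    return "\n".join(lines) + "\n"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in KNOWN_RESIDUES:
        path = OUT / f"{name}.zmat"
        path.write_text(format_table(name))
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
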