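"""File formats and external-engine interchange.

Writers: XYZ (standard, 6-decimal Å), PDB (HETATM subset with CONECT records
for inter-residue bonds), quantum-chemistry input decks (route-line text
format), two-column spectra, TSV conformer manifests, and the plain-text
frequency/energy tables that carry results back from an external engine.
Every file the package writes is re-readable by its own readers.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GlycotreeError, TableFormatError
from .geom import AtomRecord, MolecularStructure
from .spectra import SpectrumCurve, VibrationalMode

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "write_qm_input",
    "QM_LEVELS",
    "write_frequency_table",
    "read_frequency_table",
    "write_energy_table",
    "read_energy_table",
    "write_spectrum",
    "read_spectrum",
    "write_manifest",
    "read_manifest",
    "HARTREE_TO_KJ",
]

#: 1 hartree = 627.509474 kcal/mol = 627.509474 x 4.184 kJ/mol
HARTREE_TO_KJ = 627.509474 * 4.184

#: supported level-of-theory tags for input decks
QM_LEVELS = (
    "B3LYP/6-311+G*",
    "B3LYP/6-31G*",
    "MP2/6-311++G**",
    "MP2/6-31++G**",
)

_TASK_KEYWORDS = {"opt": "Opt", "freq": "Freq", "sp": ""}


def _ascii_tag(tag: str) -> str:
    """Normalize prime marks for file names and fixed-width records."""
    return tag.replace("′", "p").replace("″", "pp").replace("'", "p")


def write_xyz(structure: MolecularStructure, path: str | Path, comment: str = "") -> None:
    if len(structure) == 0:
        raise GlycotreeError("refusing to write an empty structure")
    lines = [str(len(structure)), comment.replace("\n", " ")]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> MolecularStructure:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise TableFormatError("empty XYZ file", line=1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise TableFormatError("bad atom count", line=1) from None
    atoms = []
    for i, raw in enumerate(lines[2 : 2 + n]):
        parts = raw.split()
        if len(parts) < 4:
            raise TableFormatError("expected element + 3 coordinates", line=i + 3)
        atoms.append(
            AtomRecord(i, parts[0], parts[0] + str(i), "", np.array(parts[1:4], dtype=float))
        )
    if len(atoms) != n:
        raise TableFormatError(f"expected {n} atoms, found {len(atoms)}", line=len(lines))
    return MolecularStructure(atoms, [])


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    """HETATM records with residue tags mapped to resSeq; CONECT lines record
    the inter-residue (glycosidic) bonds."""
    if len(structure) == 0:
        raise GlycotreeError("refusing to write an empty structure")
    residues = structure.residues
    res_seq = {tag: i + 1 for i, tag in enumerate(residues)}
    lines = []
    for a in structure.atoms:
        name = _ascii_tag(a.name)[:4]
        res = (_ascii_tag(a.residue_id) or "UNK")[:3]
        x, y, z = a.position
        lines.append(
            f"HETATM{a.index + 1:5d} {name:<4s} {res:>3s} A{res_seq.get(a.residue_id, 1):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
        )
    for b in sorted(structure.bonds, key=sorted):
        i, j = sorted(b)
        if structure.atoms[i].residue_id != structure.atoms[j].residue_id:
            lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_qm_input(
    structure: MolecularStructure,
    level: str,
    task: str,
    path: str | Path,
    title: str = "glycotree conformer",
) -> None:
    """A quantum-chemistry input deck: route line, neutral singlet, Cartesian
    block at XYZ precision.  The package only writes these inputs; running
    them is an external engine's job."""
    if level not in QM_LEVELS:
        raise GlycotreeError(f"unknown level tag {level!r}; supported: {QM_LEVELS}")
    if task not in _TASK_KEYWORDS:
        raise GlycotreeError(f"unknown task {task!r}; expected opt|freq|sp")
    if len(structure) == 0:
        raise GlycotreeError("refusing to write an empty structure")
    keyword = _TASK_KEYWORDS[task]
    route = f"#P {level}" + (f" {keyword}" if keyword else "")
    lines = [route, "", title, "", "0 1"]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# plain-text tables
# ---------------------------------------------------------------------------

_FREQ_UNIT_RE = re.compile(r"#\s*units?\s*:\s*cm-?1", re.IGNORECASE)
_ENERGY_UNIT_RE = re.compile(r"#\s*units?\s*:\s*kJ/mol", re.IGNORECASE)


def write_frequency_table(modes: list[VibrationalMode], path: str | Path) -> None:
    lines = ["# units: cm-1", "# columns: wavenumber intensity mode_type label"]
    for m in modes:
        lines.append(f"{m.wavenumber:12.4f} {m.intensity:12.4f} {m.mode_type:<12s} {m.label or '-'}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_frequency_table(path: str | Path) -> list[VibrationalMode]:
    """Parse a whitespace-delimited frequency table.

    The header must declare ``# units: cm-1``; each row is
    ``wavenumber intensity mode_type [label]``.
    """
    lines = Path(path).read_text().splitlines()
    unit_seen = any(_FREQ_UNIT_RE.search(l) for l in lines if l.strip().startswith("#"))
    if not unit_seen:
        raise TableFormatError("missing '# units: cm-1' header", line=1)
    modes = []
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise TableFormatError("expected wavenumber intensity mode_type", line=i)
        try:
            wav = float(parts[0])
            inten = float(parts[1])
        except ValueError:
            raise TableFormatError(f"non-numeric field in {line!r}", line=i) from None
        label = parts[3] if len(parts) > 3 and parts[3] != "-" else ""
        modes.append(VibrationalMode(wav, inten, parts[2], label))
    return modes


def write_energy_table(energies: dict[str, tuple[float, float]], path: str | Path) -> None:
    lines = ["# units: kJ/mol", "# columns: conformer_id energy_0k gibbs_298"]
    for cid, (e0, g298) in energies.items():
        lines.append(f"{_ascii_tag(cid):<16s} {e0:12.4f} {g298:12.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_energy_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Conformer-id → (relative energy at 0 K, Gibbs energy at 298.15 K)."""
    lines = Path(path).read_text().splitlines()
    if not any(_ENERGY_UNIT_RE.search(l) for l in lines if l.strip().startswith("#")):
        raise TableFormatError("missing '# units: kJ/mol' header", line=1)
    out: dict[str, tuple[float, float]] = {}
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise TableFormatError("expected conformer_id energy_0k gibbs_298", line=i)
        try:
            out[parts[0]] = (float(parts[1]), float(parts[2]))
        except ValueError:
            raise TableFormatError(f"non-numeric energy in {line!r}", line=i) from None
    return out


def write_spectrum(curve: SpectrumCurve, path: str | Path) -> None:
    lines = ["# wavenumber(cm-1)  intensity"]
    for x, y in zip(curve.grid, curve.intensity):
        lines.append(f"{x:12.4f} {y:16.8e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> SpectrumCurve:
    data = np.loadtxt(path)
    return SpectrumCurve(data[:, 0], data[:, 1])


# ---------------------------------------------------------------------------
# enumeration manifests
# ---------------------------------------------------------------------------


def write_manifest(result, directory: str | Path, files: dict[str, str] | None = None) -> Path:
    """Write ``manifest.tsv``: one row per conformer (id, group, direction
    vector, structure file, realized hydrogen bonds)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in result.conformers:
        rows.append(
            {
                "conformer_id": rec.conformer_id,
                "group": rec.group,
                "directions": ",".join(rec.directions),
                "file": (files or {}).get(rec.conformer_id, ""),
                "hbonds": ";".join(f"{o.donor}→{o.acceptor}" for o in rec.realized_hbonds),
            }
        )
    df = pd.DataFrame(rows, columns=["conformer_id", "group", "directions", "file", "hbonds"])
    path = directory / "manifest.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
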