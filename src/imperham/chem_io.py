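"""Molecular structure I/O, grouping metadata, and conformer subselection.

Structures are plain multi-frame XYZ or a minimal SDF (V2000) subset.  Net
charge travels on the XYZ comment line as a ``charge=<int>`` token (there is
no standard slot for it in XYZ) or in the ``M  CHG`` block of an SDF record.
Coordinates are Ångström throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Molecule",
    "ConformerGroup",
    "read_structures",
    "write_structures",
    "read_groups_csv",
    "write_groups_csv",
    "select_spanning_conformers",
]

# Periodic table symbols (elements 1-103), used only for validation.
_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr",
}

_ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}


class StructureParseError(ValueError):
    """Raised for malformed structure files; carries the offending line number."""


@dataclass
class Molecule:
    """One structure/conformer: elements, Cartesian coordinates (Å), net charge.

    ``id`` carries identity through featurization; ``spin_multiplicity`` is
    passed through to external engines but never interpreted here.
    """

    id: str
    elements: list[str]
    coordinates: np.ndarray  # (n_atoms, 3), Å
    net_charge: int = 0
    spin_multiplicity: int = 1

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(
                f"molecule {self.id!r}: coordinates must be (n, 3), "
                f"got {self.coordinates.shape}"
            )
        if len(self.elements) != self.coordinates.shape[0]:
            raise ValueError(
                f"molecule {self.id!r}: {len(self.elements)} elements vs "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        if len(self.elements) < 1:
            raise ValueError(f"molecule {self.id!r}: needs at least one atom")
        for sym in self.elements:
            if sym not in _ELEMENTS:
                raise ValueError(
                    f"molecule {self.id!r}: unknown element symbol {sym!r}"
                )
        if self.net_charge != int(self.net_charge):
            raise ValueError(f"molecule {self.id!r}: net_charge must be integer")
        self.net_charge = int(self.net_charge)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atomic_numbers(self) -> np.ndarray:
        return np.array([_ATOMIC_NUMBERS[e] for e in self.elements], dtype=float)


@dataclass
class ConformerGroup:
    """Conformers belonging to one parent system (e.g. one dimer identity)."""

    group_id: str
    members: list[str]
    energies: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.group_id!r}: duplicate member ids")
        if self.energies is not None and len(self.energies) != len(self.members):
            raise ValueError(
                f"group {self.group_id!r}: {len(self.energies)} energies for "
                f"{len(self.members)} members"
            )


_CHARGE_RE = re.compile(r"charge=(-?\d+)")


def read_structures(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read molecules from a multi-frame XYZ or minimal SDF file.

    Format is inferred from the suffix when not given.  XYZ comment lines may
    carry a ``charge=<int>`` token; SDF charge comes from ``M  CHG`` entries
    (summed over atoms).  Ids come from the comment/title line when nonempty,
    else ``<stem>_<index>`` with a 0-based frame index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "sdf":
        return _read_sdf(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _read_xyz(path: Path) -> list[Molecule]:
    lines = path.read_text().splitlines()
    molecules: list[Molecule] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise StructureParseError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        atom_lines = lines[i + 2 : i + 2 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise StructureParseError(
                f"{path}:{i + 1}: frame declares {n_atoms} atoms but file ends"
            )
        elements, coords = [], []
        for j, raw in enumerate(atom_lines):
            parts = raw.split()
            if len(parts) < 4:
                raise StructureParseError(
                    f"{path}:{i + 3 + j}: malformed atom line {raw!r}"
                )
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        m = _CHARGE_RE.search(comment)
        charge = int(m.group(1)) if m else 0
        mol_id = _CHARGE_RE.sub("", comment).strip() or f"{path.stem}_{frame}"
        molecules.append(Molecule(mol_id, elements, np.array(coords), charge))
        i += 2 + n_atoms
        frame += 1
    return molecules


def _read_sdf(path: Path) -> list[Molecule]:
    text = path.read_text()
    molecules: list[Molecule] = []
    for idx, record in enumerate(filter(None, (r.strip("\n") for r in text.split("$$$$")))):
        lines = record.lstrip("\n").splitlines()
        if len(lines) < 4:
            continue
        title = lines[0].strip()
        counts = lines[3]
        try:
            n_atoms = int(counts[0:3])
        except ValueError:
            raise StructureParseError(
                f"{path}: record {idx}: malformed counts line {counts!r}"
            ) from None
        elements, coords = [], []
        for j in range(n_atoms):
            row = lines[4 + j]
            coords.append([float(row[0:10]), float(row[10:20]), float(row[20:30])])
            elements.append(row[31:34].strip())
        charge = 0
        for row in lines[4 + n_atoms :]:
            if row.startswith("M  CHG"):
                fields = row.split()
                n_entries = int(fields[2])
                # entries are (atom index, charge) pairs; net charge is the sum
                charge += sum(int(fields[4 + 2 * k]) for k in range(n_entries))
        mol_id = title or f"{path.stem}_{idx}"
        molecules.append(Molecule(mol_id, elements, np.array(coords), charge))
    return molecules


def write_structures(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as multi-frame XYZ, charge token on the comment line."""
    path = Path(path)
    out = []
    for mol in molecules:
        out.append(str(mol.n_atoms))
        out.append(f"{mol.id} charge={mol.net_charge}")
        for sym, (x, y, z) in zip(mol.elements, mol.coordinates):
            out.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


def read_groups_csv(path: str | Path) -> list[ConformerGroup]:
    """Read group assignments from a ``sample_id,group_id[,conformer_energy]`` CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group_id": str})
    if not {"sample_id", "group_id"} <= set(df.columns):
        raise ValueError(f"{path}: groups CSV needs sample_id and group_id columns")
    has_energy = "conformer_energy" in df.columns
    groups = []
    for gid, sub in df.groupby("group_id", sort=False):
        groups.append(
            ConformerGroup(
                group_id=str(gid),
                members=list(sub["sample_id"]),
                energies=list(sub["conformer_energy"]) if has_energy else None,
            )
        )
    return groups


def write_groups_csv(groups: Sequence[ConformerGroup], path: str | Path) -> None:
    rows = []
    for g in groups:
        for i, mid in enumerate(g.members):
            row = {"sample_id": mid, "group_id": g.group_id}
            if g.energies is not None:
                row["conformer_energy"] = g.energies[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def select_spanning_conformers(group: ConformerGroup, k: int) -> ConformerGroup:
    """Pick ``k`` members whose energies are closest to a linear grid spanning
    the group's energy range.

    Targets are ``k`` energies linearly spaced from min to max inclusive; for
    each target (lowest first) the not-yet-chosen member with the closest
    energy is taken, ties going to the lower original index.  The min- and
    max-energy members are therefore always included.
    """
    if group.energies is None:
        raise ValueError(f"group {group.group_id!r}: energies required for selection")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(group.members):
        raise ValueError(
            f"group {group.group_id!r}: k={k} exceeds {len(group.members)} members"
        )
    energies = np.asarray(group.energies, dtype=float)
    targets = np.linspace(energies.min(), energies.max(), k)
    chosen: list[int] = []
    for t in targets:
        dist = np.abs(energies - t)
        dist[chosen] = np.inf
        chosen.append(int(np.argmin(dist)))  # argmin takes the lower index on ties
    chosen.sort()
    return ConformerGroup(
        group_id=group.group_id,
        members=[group.members[i] for i in chosen],
        energies=[float(energies[i]) for i in chosen],
    )
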