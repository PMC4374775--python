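"""Atomic-coordinate container and PDB text I/O.

A :class:`Structure` is a flat table of atoms (chain, author residue
number, insertion code, residue name, atom name, element, x/y/z in
Angstrom).  Reading goes through Biopython's PDB parser; alternate
locations are resolved to the highest-occupancy conformer (ties -> altloc
'A'), and author 1-based residue numbering is preserved.  Writing emits
standard fixed-width ATOM records (fixtures and trajectories round-trip
through it).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

__all__ = [
    "Structure",
    "DomainDefinition",
    "read_structure",
    "read_structure_file",
    "read_trajectory",
    "to_pdb_text",
    "TPPK_DOMAIN_A",
    "TPPK_DOMAIN_B",
    "PAPK_DOMAIN_A",
    "PAPK_DOMAIN_B",
    "RMPK_DOMAIN_A",
    "RMPK_DOMAIN_B",
]

ATOM_COLUMNS = (
    "chain", "resseq", "icode", "resname", "name", "element", "x", "y", "z"
)


@dataclass
class Structure:
    """Parsed atomic coordinates as a pandas table plus provenance."""

    atoms: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def chains(self) -> list[str]:
        return sorted(self.atoms["chain"].unique())

    def select_chain(self, chain: str) -> "Structure":
        sub = self.atoms[self.atoms["chain"] == chain].reset_index(drop=True)
        return Structure(sub, source=f"{self.source}:{chain}")

    def select_atoms(self, names: Iterable[str]) -> "Structure":
        sub = self.atoms[self.atoms["name"].isin(set(names))]
        return Structure(sub.reset_index(drop=True), source=self.source)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly move the structure: x -> R x + t."""
        new = self.atoms.copy()
        xyz = self.coords @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
        new[["x", "y", "z"]] = xyz
        return Structure(new, source=self.source)


@dataclass(frozen=True)
class DomainDefinition:
    """Named set of inclusive author-numbered residue intervals."""

    name: str
    ranges: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        spans = sorted(self.ranges)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping intervals in domain {self.name!r}")
        for s, e in spans:
            if e < s:
                raise ValueError(f"empty interval ({s}, {e}) in {self.name!r}")

    def contains(self, resseq: int) -> bool:
        return any(s <= resseq <= e for s, e in self.ranges)

    def mask(self, resseq: pd.Series) -> np.ndarray:
        out = np.zeros(len(resseq), dtype=bool)
        arr = resseq.to_numpy()
        for s, e in self.ranges:
            out |= (arr >= s) & (arr <= e)
        return out

    def overlaps(self, other: "DomainDefinition") -> bool:
        return any(
            s1 <= e2 and s2 <= e1
            for s1, e1 in self.ranges
            for s2, e2 in other.ranges
        )


# Published lid (B) / body (A) domain boundaries of the three enzymes.
TPPK_DOMAIN_B = DomainDefinition("B", ((66, 164),))
TPPK_DOMAIN_A = DomainDefinition("A", ((1, 65), (165, 334)))
PAPK_DOMAIN_B = DomainDefinition("B", ((81, 177),))
PAPK_DOMAIN_A = DomainDefinition("A", ((1, 80), (178, 346)))
RMPK_DOMAIN_B = DomainDefinition("B", ((116, 223),))
RMPK_DOMAIN_A = DomainDefinition("A", ((43, 115), (224, 387)))


def _pick_altloc(atom):
    """Highest occupancy wins; ties go to altloc 'A'."""
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def _structure_frames(pdb_text: str, source: str) -> list[pd.DataFrame]:
    parser = PDBParser(QUIET=True)
    handle = io.StringIO(pdb_text)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            biostruct = parser.get_structure(source or "structure", handle)
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"malformed PDB record in {source or 'input'}: {exc}") from exc
    frames = []
    for model in biostruct:
        rows = []
        for chain in model:
            for residue in chain:
                het, resseq, icode = residue.get_id()
                seen = set()
                for atom in residue:
                    atom = _pick_altloc(atom)
                    if atom.get_name() in seen:
                        continue
                    seen.add(atom.get_name())
                    x, y, z = atom.get_coord()
                    rows.append(
                        (
                            chain.id,
                            int(resseq),
                            icode.strip(),
                            residue.get_resname().strip(),
                            atom.get_name(),
                            (atom.element or "").strip().upper(),
                            float(x),
                            float(y),
                            float(z),
                        )
                    )
        frames.append(pd.DataFrame(rows, columns=ATOM_COLUMNS))
    if not frames:
        raise ValueError(f"no coordinates found in {source or 'input'}")
    return frames


def read_structure(pdb_text: str, source: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure` (first MODEL only)."""
    frames = _structure_frames(pdb_text, source)
    return Structure(frames[0], source=source)


def read_structure_file(path: str | Path) -> Structure:
    path = Path(path)
    return read_structure(path.read_text(), source=path.name)


def read_trajectory(pdb_text: str, source: str = "") -> list[Structure]:
    """Parse a multi-MODEL PDB into one :class:`Structure` per frame."""
    frames = _structure_frames(pdb_text, source)
    return [Structure(df, source=f"{source}#{k}") for k, df in enumerate(frames)]


def to_pdb_text(structures: Structure | Sequence[Structure]) -> str:
    """Serialize one structure (or a trajectory of them) as PDB text."""
    if isinstance(structures, Structure):
        frames: Sequence[Structure] = [structures]
        multi = False
    else:
        frames = list(structures)
        multi = len(frames) > 1
    lines: list[str] = []
    for k, s in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        serial = 0
        for row in s.atoms.itertuples(index=False):
            serial += 1
            name = row.name
            # standard PDB column rules: 1-3 char names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            lines.append(
                f"ATOM  {serial:5d} {padded}{'':1s}{row.resname:<3s} "
                f"{row.chain:1s}{row.resseq:4d}{row.icode or '':1s}   "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {row.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
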