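"""Noncovalent interaction detection on protein structures.

Four detectors, each returning :class:`InteractionRecord` rows:

* :func:`pi_pi_pairs` - aromatic pairs by ring-centroid distance and the
  acute angle between least-squares ring planes (stacked ~0 deg,
  edge-to-face ~90 deg);
* :func:`salt_bridges` - basic side-chain nitrogens against carboxylate
  oxygens within a distance cutoff, one record per residue pair;
* :func:`hbonds` - heavy-atom donor/acceptor (N, O, S) pairs within a
  cutoff, excluding intra-residue and peptide-bond neighbours (apo crystal
  structures carry no hydrogens, so the criterion is distance-only);
* :func:`interface_contacts` - inter-domain atom pairs classified Polar
  (both atoms N/O, d <= 3.35 A) or Hydrophobic (a carbon involved,
  d <= 3.90 A), the LigPlot/Dimplot convention.

All distances are Angstrom; geometry is invariant under rigid motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import DomainDefinition, Structure

__all__ = [
    "InteractionRecord",
    "pi_pi_pairs",
    "salt_bridges",
    "hbonds",
    "interface_contacts",
    "records_to_frame",
    "RING_ATOMS",
]


@dataclass(frozen=True)
class InteractionRecord:
    kind: str  # pi_pi | salt_bridge | hbond | interface_contact
    partner_1: str  # "A/PHE122/CZ" or "A/PHE122/ring"
    partner_2: str
    distance: float
    angle: float | None = None
    contact_class: str | None = None  # Polar | Hydrophobic


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Tabular report mirroring the published interaction tables."""
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "partner_1": r.partner_1,
                "partner_2": r.partner_2,
                "distance_A": round(r.distance, 2),
                "angle_deg": None if r.angle is None else round(r.angle, 1),
                "contact_type": r.contact_class,
            }
            for r in records
        ]
    )


def _atom_label(row) -> str:
    return f"{row.chain}/{row.resname}{row.resseq}/{row.name}"


def _residue_label(chain: str, resname: str, resseq: int, tag: str) -> str:
    return f"{chain}/{resname}{resseq}/{tag}"


# ring member atoms used for both the mass centre and the plane fit
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the least-squares plane through coords."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[-1]


def plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle (degrees, in [0, 90]) between two plane normals."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(min(1.0, c))))


def pi_pi_pairs(
    s: Structure,
    residues: Iterable[Tuple[str, int]] | None = None,
    max_centroid_dist: float = 7.0,
) -> list[InteractionRecord]:
    """Aromatic ring pairs within ``max_centroid_dist`` of each other.

    ``residues`` optionally restricts the search to (chain, resseq) pairs;
    by default every Phe/Tyr/Trp/His is considered.  A residue whose ring
    atoms are incomplete is skipped with a warning.  Pairs are reported once,
    ordered by (chain, residue number); the angle is the acute interplane
    angle.
    """
    rings = []
    aromatic = s.atoms[s.atoms["resname"].isin(RING_ATOMS)]
    for (chain, resseq, icode, resname), group in aromatic.groupby(
        ["chain", "resseq", "icode", "resname"], sort=True
    ):
        if residues is not None and (chain, resseq) not in set(residues):
            continue
        wanted = RING_ATOMS[resname]
        sub = group[group["name"].isin(wanted)]
        if len(sub) < len(wanted):
            warnings.warn(
                f"incomplete aromatic ring {chain}/{resname}{resseq}: "
                f"{len(sub)}/{len(wanted)} atoms; skipped"
            )
            continue
        coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
        centroid, normal = _ring_plane(coords)
        rings.append((chain, resseq, resname, centroid, normal))

    records = []
    for k, (c1, r1, n1, cen1, nor1) in enumerate(rings):
        for c2, r2, n2, cen2, nor2 in rings[k + 1 :]:
            d = float(np.linalg.norm(cen1 - cen2))
            if d <= max_centroid_dist:
                records.append(
                    InteractionRecord(
                        "pi_pi",
                        _residue_label(c1, n1, r1, "ring"),
                        _residue_label(c2, n2, r2, "ring"),
                        d,
                        angle=plane_angle(nor1, nor2),
                    )
                )
    return records


_BASIC_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def salt_bridges(s: Structure, cutoff: float = 4.0) -> list[InteractionRecord]:
    """Basic-N to carboxylate-O contacts within ``cutoff`` Angstrom.

    One record per (basic residue, acidic residue) pair, carrying the
    minimum-distance atom pair.  C-terminal OXT oxygens count as acidic.
    """
    atoms = s.atoms
    basic_mask = np.zeros(len(atoms), dtype=bool)
    for resname, names in _BASIC_ATOMS.items():
        basic_mask |= (atoms["resname"] == resname) & atoms["name"].isin(names)
    acidic_mask = atoms["name"] == "OXT"
    for resname, names in _ACIDIC_ATOMS.items():
        acidic_mask |= (atoms["resname"] == resname) & atoms["name"].isin(names)

    basic = atoms[basic_mask]
    acidic = atoms[acidic_mask]
    if basic.empty or acidic.empty:
        return []
    tree = cKDTree(acidic[["x", "y", "z"]].to_numpy(dtype=float))
    best: dict[tuple, tuple[float, object, object]] = {}
    bxyz = basic[["x", "y", "z"]].to_numpy(dtype=float)
    for brow, neighbours in zip(
        basic.itertuples(index=False), tree.query_ball_point(bxyz, cutoff)
    ):
        for j in neighbours:
            arow = acidic.iloc[j]
            d = float(
                np.linalg.norm(
                    np.array([brow.x, brow.y, brow.z])
                    - arow[["x", "y", "z"]].to_numpy(dtype=float)
                )
            )
            key = (brow.chain, brow.resseq, arow["chain"], arow["resseq"])
            if key not in best or d < best[key][0]:
                best[key] = (d, brow, arow)
    records = []
    for d, brow, arow in sorted(best.values(), key=lambda t: t[0]):
        records.append(
            InteractionRecord(
                "salt_bridge",
                _atom_label(brow),
                f"{arow['chain']}/{arow['resname']}{arow['resseq']}/{arow['name']}",
                d,
            )
        )
    return records


_DONOR_ACCEPTOR_ELEMENTS = {"N", "O", "S"}
_BACKBONE = {"N", "C", "O", "OXT"}


def hbonds(
    s: Structure, d_a_cutoff: float = 3.4, d_min: float = 1.8
) -> list[InteractionRecord]:
    """Heavy-atom hydrogen-bond candidates: N/O/S pairs within the cutoff.

    Pairs inside the same residue are excluded, as are backbone-backbone
    pairs of peptide-bonded neighbours (their N...O=C separation sits inside
    any reasonable cutoff without being a hydrogen bond) and anything closer
    than ``d_min`` (covalent).
    """
    cand = s.atoms[s.atoms["element"].isin(_DONOR_ACCEPTOR_ELEMENTS)]
    if cand.empty:
        return []
    xyz = cand[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(d_a_cutoff, output_type="ndarray")
    rows = list(cand.itertuples(index=False))
    records = []
    for i, j in pairs:
        a, b = rows[i], rows[j]
        same_res = (a.chain, a.resseq, a.icode) == (b.chain, b.resseq, b.icode)
        if same_res:
            continue
        adjacent = a.chain == b.chain and abs(a.resseq - b.resseq) == 1
        if adjacent and a.name in _BACKBONE and b.name in _BACKBONE:
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d < d_min:
            continue
        first, second = sorted((a, b), key=lambda r: (r.chain, r.resseq, r.name))
        records.append(
            InteractionRecord("hbond", _atom_label(first), _atom_label(second), d)
        )
    records.sort(key=lambda r: (r.partner_1, r.partner_2))
    return records


def interface_contacts(
    s: Structure,
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
    exclude: Sequence[Tuple[int, int]] = (),
    polar_cutoff: float = 3.35,
    nonpolar_cutoff: float = 3.90,
) -> list[InteractionRecord]:
    """Atom-pair contacts across a domain-domain interface.

    Atoms are assigned to domains by author residue number; residues in the
    ``exclude`` intervals (e.g. hinge regions) are removed before pairing.
    A pair is Polar when both atoms are N or O and at most ``polar_cutoff``
    apart, Hydrophobic when at least one atom is carbon and at most
    ``nonpolar_cutoff`` apart.  One record per qualifying atom pair, the
    domain-A atom first.
    """
    if dom_a.overlaps(dom_b):
        raise ValueError(
            f"domains {dom_a.name!r} and {dom_b.name!r} overlap"
        )
    atoms = s.atoms[s.atoms["element"] != "H"]
    if exclude:
        excl = DomainDefinition("exclude", tuple(exclude))
        atoms = atoms[~excl.mask(atoms["resseq"])]
    part_a = atoms[dom_a.mask(atoms["resseq"])]
    part_b = atoms[dom_b.mask(atoms["resseq"])]
    if part_a.empty or part_b.empty:
        return []
    xyz_a = part_a[["x", "y", "z"]].to_numpy(dtype=float)
    xyz_b = part_b[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(xyz_b)
    max_cut = max(polar_cutoff, nonpolar_cutoff)
    rows_a = list(part_a.itertuples(index=False))
    rows_b = list(part_b.itertuples(index=False))
    records = []
    for ia, neighbours in enumerate(tree.query_ball_point(xyz_a, max_cut)):
        a = rows_a[ia]
        for ib in neighbours:
            b = rows_b[ib]
            d = float(np.linalg.norm(xyz_a[ia] - xyz_b[ib]))
            polar = (
                a.element in ("N", "O")
                and b.element in ("N", "O")
                and d <= polar_cutoff
            )
            hydrophobic = ("C" in (a.element, b.element)) and d <= nonpolar_cutoff
            if polar:
                cls = "Polar"
            elif hydrophobic:
                cls = "Hydrophobic"
            else:
                continue
            records.append(
                InteractionRecord(
                    "interface_contact", _atom_label(a), _atom_label(b), d,
                    contact_class=cls,
                )
            )
    records.sort(key=lambda r: (r.partner_1, r.partner_2))
    return records
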